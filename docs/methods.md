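# Methods

## Model

The pipeline relates two row-aligned data blocks per cohort: a
connectivity domain X (n subjects × p edges) and a phenotype domain Y
(n × 8). Both are modeled with the two-block latent decomposition
X = ΦP + E_X, Y = ΨC + E_Y, where the per-component weight pairs are
chosen to maximize cov(φ, ψ) with φ = Xu, ψ = Yv. Without constraints
the optimum is the leading singular pair of the cross-covariance
M = XᵀY, and the covariance score is the leading singular value.

Sparsity is imposed per domain as the intersection of the unit L2
sphere with an L1 ball of radius λ_D:

    ‖w‖₂ = 1,  ‖w‖₁ ≤ λ_D,   1 ≤ λ_D ≤ |D|.

λ_D = 1 forces one nonzero coefficient (maximal regularization); the
constraint is vacuous for λ_D ≥ √|D| because the L1/L2 ratio of a unit
vector cannot exceed √|D|. This is the standard penalized-SVD
formulation: the maximizer of zᵀw over the feasible set is a
soft-thresholded, renormalized copy of z, with the threshold δ the
smallest value meeting the L1 bound, found by bisection (tolerance
1e-10 on δ). With tied maximal entries and a radius below the reachable
ratio the lowest-index maximal coordinate is kept — a documented,
deterministic tie rule.

### Solver

Each component alternates u ← proj(Mv, λ_C), v ← proj(Mᵀu, λ_P) until
the max-norm weight change falls below 1e-6 (cap 500 iterations;
non-convergence sets a flag and emits a warning, never silently). The
objective is non-convex, so the iterations are multistarted from each
right singular vector of M (up to eight); the start with the highest
covariance wins. The regularization-selection sweeps additionally
warm-start each grid point from the previous grid point's solution.
Both devices are deterministic — there is no randomness anywhere in the
solver, so identical inputs give bit-identical models. Sign
indeterminacy is resolved by jointly flipping (u, v, φ, ψ) so the
largest-magnitude phenotype coefficient is positive.

Later components are fitted on residuals after projection deflation on
each block's own scores, X ← X − φ(φᵀφ)⁻¹φᵀX and likewise for Y. This
choice (among several deflation conventions) guarantees exact
within-domain score orthogonality across components, which is tested.
Covariance percentages are reported relative to component 1 (100 by
definition). Both blocks are column z-scored before fitting by default
(sample SD, n−1); a `scale=False` configuration centers only.

### Regularization selection

* Phenotype: sweep λ_P over 1, 1.1, …, q and keep the largest value for
  which the first component has at most `max_features` (default 3)
  nonzero coefficients — the weakest constraint honoring the cap.
* Connectivity: sweep a log-spaced grid (default 100 points) over
  [1, √p] and keep the λ_C whose first-component nonzero fraction is
  closest to the target density (default 0.5); ties go to the smaller
  λ_C. The selected pair is reused for all components.

A structural note on the feature cap: the exact maximizer fills any L1
slack with small extra coefficients. If the underlying signal
concentrates on two near-equal variables (‖v‖₁ → √2 ≈ 1.414), a radius
of 1.5 leaves slack and one to a few near-zero extras appear; the cap
behaves exactly when the radius binds (e.g. three-variable signals,
‖v‖₁ → √3 ≈ 1.732 > 1.5). The selection rule, which counts nonzeros
per grid point, honors the cap by construction either way.

The nonzero count along the λ_P grid is non-decreasing whenever the
data carry genuine cross-domain signal; on association-free pure-noise
data, near-tied optima across singular directions can produce isolated
single-step dips even for the exact estimator, so the monotonicity
property should be read as a regularity of the method's operating
regime, not a theorem about arbitrary inputs.

## Connectivity domain

Regions are labeled by Yeo-17 subnetwork; SN = Ventral Attention A/B,
FPN = Control A/B/C, DMN = Default A/B/C, everything else excluded.
Label matching is case-insensitive with a synonym table covering atlas
dialects ("SalVentAttnA" ↔ "Ventral Attention Network A"); hemisphere
comes from an LH_/RH_ name prefix or an explicit column. After TNM
restriction, region ids are re-indexed 0-based and contiguous with the
original atlas ids kept as metadata. Edges follow a row-major traversal
of the strict upper triangle; FPN–DMN pairs are excluded by
construction, giving s(s−1)/2 + f(f−1)/2 + d(d−1)/2 + sf + sd edges for
network sizes (s, f, d). Functional connectivity is the raw Pearson
correlation of mean regional time series (no Fisher transform, no
scrubbing — preprocessing is upstream and out of scope); zero-variance
regions and series shorter than 3 time points are rejected with the
offending region named.

## Phenotype domain

Eight z-scored variables: Sex (female = 0, male = 1 before z-scoring;
any affine coding gives the same column up to sign), Age, Education,
FHD, AUD symptom count, and three PCA composites. Family-history
density weights affected parents and full siblings 0.5, affected
grandparents and parents' siblings 0.25, summed and divided by the
number of counted relatives (only the four weighted categories are
counted); the score lies in [0, 0.5] and an empty pedigree is an error.
Drinking variables are transformed by ln(1+x) — chosen because
drinking-days-per-week can be zero and the transform is monotone with
0 ↦ 0 — then z-scored and compressed by PCA on the correlation matrix
with the Kaiser rule (retain eigenvalues > 1); likewise the two urgency
scales and the two alcohol-preference contrasts (work-for-alcohol minus
work-for-water per session condition). Retained components are oriented
so the loading sum is positive; when several eigenvalues exceed 1 only
the first feeds the 8-variable table, with all retained components
exposed for inspection. A group with no eigenvalue above 1 raises an
error rather than guessing. Z-scoring uses the n−1 denominator
throughout.

## Block inference, strengths, circuits

Per component, the edge weights are partitioned into the five TNM
blocks (optionally refined by hemisphere pairs). The block statistic is
the sum of absolute coefficients; the null reassigns coefficients to
edge positions by a uniform global permutation (block memberships
fixed, so each block's null reflects its size), 1,000 draws by default
from a seeded generator recorded in the output. Significance is strict
exceedance of the 99th percentile (linear-interpolation quantile, with
a 1e-9 relative guard so exactly-tied degenerate nulls never flag);
no multiple-testing correction is applied across blocks, deliberately.
Block direction is the sign of the signed coefficient sum — the natural
dual of the absolute-sum statistic. Signed strengths are row sums of
positive and of negative entries of the rebuilt symmetric coefficient
matrix; net strengths over regions sum to exactly twice the sum of edge
coefficients (each edge appears in two rows). Top regions take
k = ceil(fraction × N) (default fraction 0.05) by |net| descending,
ties by region index, alongside the (1 − fraction) quantile of |net|.
Circuit summaries map SN-FPN and SN-DMN blocks to SN→FPN and SN→DMN
arrows — directionality imposed by the TNM, never reversed — and
within-network blocks to self-loops, each labeled increased, decreased
or not-significant.

## Leave-one-out stability

One refit per held-out subject with the regularization fixed at the
full-cohort selection and standardization refit inside each fold (a
flag disables the refit). The solver's determinism makes every fold
bitwise reproducible by an independent fit on the same subset.
Components are matched across folds by index — deflation order is
stable for well-separated factors — with a diagnostic warning when a
fold component correlates more strongly with a different reference
component; signs are aligned to the full-cohort model by flipping
negatively-correlated weight vectors. Summaries are five-number
distributions of phenotype coefficients and per-edge population
(n-denominator) standard deviations.

## Synthetic cohorts

The generator plants K latent factors (standard-normal scores) shared
by both domains. Defaults mirror the target study conditions: 55
subjects, 145 regions split 45/50/50 across SN/FPN/DMN (a configurable
convention — the true atlas split is not public), 616 time points when
the time-series route is on, 5% edge support per factor restricted to
designated blocks and never touching FPN–DMN, and three factors whose
default phenotype supports pair Drinking with Age, FHD with Urgency,
and AlcoholSeeking with Sex.

Phenotype columns supported by a factor receive measurement noise
σ_y (default 0.1); unsupported columns vary idiosyncratically at unit
scale — they are real traits, merely unrelated to the planted factors,
and without that variance integer-valued raw measures would collapse
under rounding. Raw records invert the derivation pipeline: the five
drinking measures are exponentials of affine functions of the planted
Drinking column (log-normal skew); urgency scales are two noisy integer
replicates mapped into the 4–16 instrument range with mid-scale centers
so the bounds rarely truncate; seeking counts are nonnegative integer
pairs built so the alcohol-preference contrast reproduces the planted
column exactly up to rounding; sex thresholds its column at the median
(and the planted Sex target is the coded binary variable itself, since
a dichotomous trait cannot correlate more than ≈0.8 with a continuous
one); AUD symptom counts are rounded affine maps kept clear of the zero
floor. Pedigrees are quantile-matched: each subject has 2 parents and 4
grandparents and the affected counts step monotonically with the
subject's rank on the planted FHD column through the nine achievable
density levels (2a+b)/24 — spanning [0, 1/3], slightly narrower than
the 0–0.42 a variable pedigree could reach. Derived columns correlate
≥ 0.9 with their planted targets at these settings (tested).

Connectivity is X = Z·Pᵀ·α + E_x with iid noise (σ_x default 1). The
loading scale α is calibrated on the realized draw so the leading
singular value of the signal cross-covariance is `snr` (default 3)
times that of the noise cross-covariance — strong enough to recover,
weak enough to be non-trivial. Note that column z-scoring shrinks
high-variance supported edges, so the post-standardization ratio is
lower than the calibrated one; recovery at the default scaling works
once λ_C is selected at the planted support density. The optional
time-series route maps standardized edge values into correlation-scale
deviations (scale 0.08, clipped at ±3 SD) around a base matrix (0.15
within-network, 0.05 between), repairs each subject's matrix to the
nearest positive-definite correlation matrix (eigenvalue floor 1e-6,
diagonal renormalized) and samples multivariate-normal series, so the
Pearson-FC path is exercised end to end. What the generator does not
emulate: BOLD autocorrelation, hemodynamics, motion artifacts, scanner
noise, or realistic marginal FC distributions — passing tests show the
pipeline's statistical machinery is correct, not that the effect sizes
transfer to real cohorts.

Recovery scoring greedily matches fitted components to planted factors
by absolute score correlation and reports sign-agnostic support
precision/recall/F1 per domain, score correlations and loading cosines.

## Problem sizes and runtime choices

Tests and the acceptance script run cohorts of n = 55 at p = 555–792
edges (network sizes 10/15/15 and 13/17/17): large enough that p ≫ q
and the density rule has resolution, small enough for a laptop-scale
run. Null-model calibration uses 500 Monte-Carlo replicates of 1,000
permutations on a 66-edge space. The full suite runs in about a
minute; the acceptance script in seconds.

## Known limitations

* The feature-cap slack behavior above means "at most 3 nonzeros at a
  fixed λ_P = 1.5" is a property of binding constraints, not of the
  radius per se.
* Component matching in LOOCV is by index; strongly overlapping factors
  could swap order between folds (a warning fires, but no re-matching
  is attempted).
* The permutation null shuffles coefficients globally, not within
  blocks; block-size effects are therefore part of the null, which is
  the intended reading of the statistic.
* No out-of-sample prediction or component-count selection: components
  are assessed by covariance percentage and stability only.
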