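"""Leave-one-out stability of sparse PLS components.

Each fold refits the model on all-but-one subject with the
regularization fixed at the full-cohort values; z-scoring is refit
inside each fold by default. Because the solver is deterministic, every
fold is exactly reproducible by an independent fit on the same subset.
Weight vectors carry an arbitrary joint sign, so folds are aligned to
the full-cohort reference (flip when the weight correlation with the
reference component is negative) before coefficient distributions and
per-edge standard deviations are summarized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import RegularizedPLS


@dataclass
class LoocvEnsemble:
    """All leave-one-out refits plus the full-cohort reference model."""

    runs: list  # one fitted RegularizedPLS per held-out subject
    reference: RegularizedPLS
    held_out: np.ndarray  # row index held out in each run
    alignment: np.ndarray | None = field(default=None)  # (n_runs, K) signs
    aligned: bool = False

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def loocv_fit(
    X, Y,
    n_components: int = 4,
    lambda_connectivity: float | None = None,
    lambda_phenotype: float | None = None,
    scale: bool = True,
    **kwargs,
) -> LoocvEnsemble:
    """Fit one model per held-out subject plus the full-cohort reference.

    Regularization is held fixed across folds (select it once on the
    full cohort); standardization is refit within each fold.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for leave-one-out")

    def make():
        return RegularizedPLS(
            n_components=n_components,
            lambda_connectivity=lambda_connectivity,
            lambda_phenotype=lambda_phenotype,
            scale=scale,
            **kwargs,
        )

    reference = make().fit(X, Y)
    runs = []
    for i in range(n):
        keep = np.arange(n) != i
        runs.append(make().fit(X[keep], Y[keep]))
    return LoocvEnsemble(runs=runs, reference=reference,
                         held_out=np.arange(n))


def align_components(ensemble: LoocvEnsemble) -> LoocvEnsemble:
    """Resolve per-fold sign indeterminacy against the reference model.

    Components are matched by index (deflation order is stable for
    well-separated factors); a fold component is negated when the
    correlation of its connectivity weights with the reference is
    negative. A diagnostic warning is raised if some fold component
    correlates more strongly with a different reference component than
    with its own.
    """
    ref_u = ensemble.reference.x_weights_
    K = ref_u.shape[1]
    flips = np.ones((ensemble.n_runs, K))
    for r, run in enumerate(ensemble.runs):
        for k in range(K):
            u = run.x_weights_[:, k]
            if not np.any(u):
                raise ValueError(f"run {r} component {k} has zero weights")
            c_own = _safe_corr(u, ref_u[:, k])
            if c_own < 0:
                flips[r, k] = -1.0
            others = [abs(_safe_corr(u, ref_u[:, j]))
                      for j in range(K) if j != k]
            if others and max(others) > abs(c_own):
                import warnings

                warnings.warn(
                    f"run {r}: component {k} matches another reference "
                    "component more strongly; order may be unstable",
                    UserWarning, stacklevel=2,
                )
        run.x_weights_ = run.x_weights_ * flips[r]
        run.y_weights_ = run.y_weights_ * flips[r]
        run.x_scores_ = run.x_scores_ * flips[r]
        run.y_scores_ = run.y_scores_ * flips[r]
    ensemble.alignment = flips
    ensemble.aligned = True
    return ensemble


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def coefficient_variability(
    ensemble: LoocvEnsemble,
    phenotype_names=None,
):
    """Distribution summaries of fold coefficients.

    Returns, per component, five-number summaries (min, quartiles, max)
    of the phenotype coefficients across folds and the per-edge
    population standard deviation (n-denominator) of the connectivity
    coefficients.

    Returns
    -------
    phenotype_summary : DataFrame
        Indexed by (component, variable) with columns min/q1/median/q3/max/mean.
    edge_sd : ndarray of shape (p, K)
    """
    if not ensemble.aligned:
        raise ValueError("align the ensemble before summarizing variability")
    K = ensemble.reference.x_weights_.shape[1]
    q = ensemble.reference.y_weights_.shape[0]
    names = (list(phenotype_names) if phenotype_names is not None
             else [f"y{i}" for i in range(q)])
    V = np.stack([run.y_weights_ for run in ensemble.runs])  # (runs, q, K)
    U = np.stack([run.x_weights_ for run in ensemble.runs])  # (runs, p, K)
    rows = []
    for k in range(K):
        for j, name in enumerate(names):
            vals = V[:, j, k]
            rows.append(
                {
                    "component": k,
                    "variable": name,
                    "min": vals.min(),
                    "q1": np.percentile(vals, 25),
                    "median": np.median(vals),
                    "q3": np.percentile(vals, 75),
                    "max": vals.max(),
                    "mean": vals.mean(),
                }
            )
    summary = pd.DataFrame(rows).set_index(["component", "variable"])
    edge_sd = U.std(axis=0, ddof=0)  # (p, K)
    return summary, edge_sd
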