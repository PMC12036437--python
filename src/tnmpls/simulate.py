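"""Synthetic cohorts with known cross-domain latent structure.

The generator plants K latent factors shared by the two domains: each
factor loads on a small set (at most 3) of phenotype variables and on a
sparse, block-restricted set of connectivity edges, never touching the
excluded FPN-DMN block. Raw phenotype records are then built so that
the derivation pipeline (log transforms, preference contrasts, FHD
scoring, PCA compression, z-scoring) recovers noisy versions of the
planted columns: drinking measures are log-normal (exponentials of
affine functions of the planted Drinking column), urgency scales are
two noisy integer replicates of the planted Urgency column, seeking
counts are nonnegative trial-count pairs whose contrasts recover
AlcoholSeeking, and pedigrees are quantile-matched so family-history
density tracks the planted FHD column.

Connectivity is produced either directly at the edge level
(``X = Z P^T + noise``) or, optionally, as per-subject BOLD-like time
series drawn from subject-specific correlation matrices (a fixed base
plus the planted edge deviations, repaired to the nearest positive-
definite correlation matrix), so the Pearson-FC path is exercised too.

Effect size is calibrated on the realized draw: the edge loadings are
scaled so the leading singular value of the noiseless cross-covariance
is `snr` (default 3) times that of the noise cross-covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import EdgeIndex, build_edge_index, rebuild_matrix
from .phenotype import PHENOTYPE_COLUMNS
from .regions import make_region_table

#: factor supports mirroring the phenotype pairings the pipeline targets
DEFAULT_FACTOR_SUPPORTS = (
    ("Drinking", "Age"),
    ("FHD", "Urgency"),
    ("AlcoholSeeking", "Sex"),
    ("Education",),
)

_SN_SUBNETS = ("VentAttnA", "VentAttnB")
_FPN_SUBNETS = ("ContA", "ContB", "ContC")
_DMN_SUBNETS = ("DefaultA", "DefaultB", "DefaultC")


def synthetic_region_table(sizes=(45, 50, 50)) -> pd.DataFrame:
    """A TNM-restricted region table with plausible subnetwork labels.

    Synthetic stand-in for an atlas lookup: `sizes` gives the SN, FPN
    and DMN region counts; regions cycle through each network's
    subnetworks and alternate hemispheres.
    """
    s, f, d = sizes
    if min(s, f, d) < 1:
        raise ValueError("every network needs at least one region")
    names, subnets = [], []
    for net_subnets, count, tag in (
        (_SN_SUBNETS, s, "SN"),
        (_FPN_SUBNETS, f, "FPN"),
        (_DMN_SUBNETS, d, "DMN"),
    ):
        for k in range(count):
            sub = net_subnets[k % len(net_subnets)]
            hemi = "LH" if k % 2 == 0 else "RH"
            names.append(f"{hemi}_{sub}_{tag}{k}")
            subnets.append(sub)
    return make_region_table(names, subnets)


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_subjects: int = 55
    network_sizes: tuple = (45, 50, 50)
    n_factors: int = 3
    phenotype_supports: tuple | None = None  # per factor, names from PHENOTYPE_COLUMNS
    edge_support_fraction: float = 0.05
    factor_blocks: tuple | None = None  # per factor, allowed block names
    noise_sd_phenotype: float = 0.1  # sigma_y on the planted 8-column targets
    noise_sd_connectivity: float = 1.0  # sigma_x on the edge domain
    noise_sd_raw: float = 0.1  # extra noise inside raw-record construction
    snr: float = 3.0  # signal-to-noise ratio of leading cross-covariance singular values
    timeseries: bool = False
    n_timepoints: int = 616
    deviation_scale: float = 0.08  # edge-to-correlation deviation (timeseries route)
    seed: int = 0

    def resolved_supports(self):
        if self.phenotype_supports is not None:
            supports = [tuple(s) for s in self.phenotype_supports]
        else:
            if self.n_factors > len(DEFAULT_FACTOR_SUPPORTS):
                raise ValueError(
                    "provide phenotype_supports for more than "
                    f"{len(DEFAULT_FACTOR_SUPPORTS)} factors"
                )
            supports = [DEFAULT_FACTOR_SUPPORTS[k] for k in range(self.n_factors)]
        if len(supports) != self.n_factors:
            raise ValueError("one phenotype support per factor required")
        for sup in supports:
            if not 1 <= len(sup) <= 3:
                raise ValueError("phenotype supports must have 1-3 variables")
            unknown = set(sup) - set(PHENOTYPE_COLUMNS)
            if unknown:
                raise ValueError(f"unknown phenotype variables: {sorted(unknown)}")
        return supports


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort, for recovery scoring."""

    latent: np.ndarray  # (n, K) standard-normal factor scores
    phenotype_loadings: np.ndarray  # (8, K), sparse
    edge_loadings: np.ndarray  # (p, K), sparse, block-restricted
    phenotype_support: list  # per factor, list of column names
    edge_support: list  # per factor, edge position array
    phenotype_targets: np.ndarray  # (n, 8) planted noisy targets
    noise_sd_phenotype: float = 0.1
    noise_sd_connectivity: float = 1.0
    snr: float = 3.0
    signal_scale: float = 1.0


@dataclass
class SimulatedCohort:
    raw_phenotypes: pd.DataFrame
    pedigree: pd.DataFrame
    connectivity: pd.DataFrame  # subjects x edges
    region_table: pd.DataFrame
    edge_index: EdgeIndex
    ground_truth: GroundTruth
    time_series: list | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# raw-record construction

# log-scale location and slope per drinking variable, set to land the raw
# measures near the magnitudes typical of heavy-drinking cohorts
_DRINKING_PARAMS = {
    "tlfb_ddd": (1.6, 0.5),
    "tlfb_ddw": (0.5, 0.5),
    "tlfb_dw": (2.9, 0.8),
    "tlfb_gdd": (2.2, 0.5),
    "ldh_kg": (4.6, 1.0),
}


def _pedigrees_from_targets(t_fhd: np.ndarray, rng) -> tuple[pd.DataFrame, np.ndarray]:
    """Quantile-match pedigrees to the planted FHD column.

    Every subject gets 2 parents and 4 grandparents; the number of
    affected relatives is a monotone step function of the subject's rank
    on the planted column, covering the 9 achievable density levels
    (2a + b)/24 for a affected parents and b affected grandparents.
    """
    n = len(t_fhd)
    ranks = np.argsort(np.argsort(t_fhd, kind="stable"), kind="stable")
    levels = (ranks * 9) // n  # 0..8
    rows = []
    fhd = np.empty(n)
    for i, m in enumerate(levels):
        a = max(0, math.ceil((m - 4) / 2))
        b = int(m - 2 * a)
        for j in range(2):
            rows.append((i, "parent", j < a))
        for j in range(4):
            rows.append((i, "grandparent", j < b))
        fhd[i] = (0.5 * a + 0.25 * b) / 6.0
    pedigree = pd.DataFrame(rows, columns=["subject_id", "relationship", "affected"])
    return pedigree, fhd


def _raw_records(targets: pd.DataFrame, cfg: GeneratorConfig, rng):
    """Invert the derivation pipeline: targets -> raw measures."""
    n = len(targets)
    sraw = cfg.noise_sd_raw
    raw = pd.DataFrame(index=targets.index)

    raw["sex"] = np.where(
        targets["Sex"] >= np.median(targets["Sex"]), "male", "female"
    )
    raw["age"] = np.clip(32.0 + 10.0 * targets["Age"], 18.0, None)
    raw["education"] = np.clip(15.4 + 2.0 * targets["Education"], 8.0, None)
    # centered away from the floor so count truncation stays rare
    raw["aud_symptoms"] = np.clip(
        np.round(3.5 + 1.8 * targets["AUD_Symptoms"]), 0, 11
    ).astype(int)

    pedigree, fhd = _pedigrees_from_targets(targets["FHD"].to_numpy(), rng)

    t_drink = targets["Drinking"].to_numpy()
    for name, (mu, slope) in _DRINKING_PARAMS.items():
        eps = rng.normal(0.0, sraw, n)
        raw[name] = np.exp(mu + slope * (t_drink + eps))

    # mid-scale centers keep the 4..16 instrument bounds from truncating
    t_urg = targets["Urgency"].to_numpy()
    raw["pur"] = np.clip(
        np.round(9.0 + 2.2 * (t_urg + rng.normal(0, sraw, n))), 4, 16
    ).astype(int)
    raw["nur"] = np.clip(
        np.round(10.0 + 2.3 * (t_urg + rng.normal(0, sraw, n))), 4, 16
    ).astype(int)

    t_seek = targets["AlcoholSeeking"].to_numpy()
    for prefix in ("n", "a"):
        base = np.clip(rng.normal(220.0, 60.0, n), 50.0, None)
        eps = rng.normal(0.0, sraw, n)
        half = 27.0 + 60.0 * (t_seek + eps)
        # floor water work at zero but preserve the contrast exactly
        cww = np.clip(base - half, 0, None)
        raw[f"{prefix}_cwa"] = np.round(
            np.clip(cww + 2.0 * half, 0, None)
        ).astype(int)
        raw[f"{prefix}_cww"] = np.round(cww).astype(int)

    return raw, pedigree, fhd


# ---------------------------------------------------------------------------
# connectivity construction


def nearest_pd_correlation(A: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Repair a symmetric matrix into a valid correlation matrix.

    Eigenvalues are clipped at `floor` and the diagonal renormalized to
    one; entries end up in [-1, 1].
    """
    A = (A + A.T) / 2.0
    eigval, eigvec = np.linalg.eigh(A)
    eigval = np.clip(eigval, floor, None)
    B = (eigvec * eigval) @ eigvec.T
    d = np.sqrt(np.diag(B))
    if np.any(d <= 0):
        raise ValueError("positive-definite repair failed")
    B = B / np.outer(d, d)
    B = np.clip((B + B.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(B, 1.0)
    return B


def _base_correlation(edges: EdgeIndex) -> np.ndarray:
    within = 0.15
    between = 0.05
    vals = np.empty(edges.n_edges)
    for k, blk in enumerate(edges.blocks):
        a, b = blk.split("-")
        vals[k] = within if a == b else between
    return rebuild_matrix(vals, edges) + np.eye(edges.n_regions)


def _sample_edge_supports(edges: EdgeIndex, cfg: GeneratorConfig, rng):
    p = edges.n_edges
    n_sup = max(1, round(cfg.edge_support_fraction * p))
    block_idx = edges.block_indices()
    if cfg.factor_blocks is not None:
        factor_blocks = [tuple(b) for b in cfg.factor_blocks]
        if len(factor_blocks) != cfg.n_factors:
            raise ValueError("one block list per factor required")
    else:
        factor_blocks = [tuple(block_idx.keys())] * cfg.n_factors
    used = np.zeros(p, dtype=bool)
    supports = []
    for blocks in factor_blocks:
        unknown = set(blocks) - set(block_idx)
        if unknown:
            raise ValueError(f"unknown blocks: {sorted(unknown)}")
        pool = np.concatenate([block_idx[b] for b in blocks])
        pool = pool[~used[pool]]
        if len(pool) < n_sup:
            raise ValueError(
                f"requested edge support {n_sup} exceeds remaining capacity "
                f"{len(pool)} of blocks {blocks}"
            )
        chosen = rng.choice(pool, size=n_sup, replace=False)
        chosen.sort()
        used[chosen] = True
        supports.append(chosen)
    return supports


# ---------------------------------------------------------------------------
# main entry points


def simulate_cohort(config: GeneratorConfig) -> SimulatedCohort:
    """Generate a cohort with planted cross-domain latent structure."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    supports = cfg.resolved_supports()

    regions = synthetic_region_table(cfg.network_sizes)
    edges = build_edge_index(regions)
    n, p, K = cfg.n_subjects, edges.n_edges, cfg.n_factors

    Z = rng.standard_normal((n, K))

    C = np.zeros((len(PHENOTYPE_COLUMNS), K))
    col_pos = {name: i for i, name in enumerate(PHENOTYPE_COLUMNS)}
    for k, sup in enumerate(supports):
        C[[col_pos[v] for v in sup], k] = 1.0 / math.sqrt(len(sup))

    # factor-supported columns get measurement noise sigma_y; the other
    # traits vary idiosyncratically at unit scale (they are real
    # variables, merely unrelated to the planted factors)
    signal_var = (C ** 2).sum(axis=1)
    col_sd = np.where(signal_var > 0, cfg.noise_sd_phenotype, 1.0)
    targets_arr = Z @ C.T + col_sd * rng.standard_normal((n, 8))
    subject_ids = pd.Index(
        [f"sub-{i + 1:03d}" for i in range(n)], name="subject_id"
    )
    targets = pd.DataFrame(targets_arr, index=subject_ids,
                           columns=list(PHENOTYPE_COLUMNS))

    raw, pedigree, _ = _raw_records(targets, cfg, rng)
    pedigree["subject_id"] = subject_ids[pedigree["subject_id"].to_numpy()]
    # sex is intrinsically dichotomous: the planted target is the coded
    # variable itself, so cross-domain signal flows through what the
    # derivation pipeline can actually see
    targets_arr[:, 0] = (raw["sex"] == "male").to_numpy(float)
    targets["Sex"] = targets_arr[:, 0]

    edge_support = _sample_edge_supports(edges, cfg, rng)
    P0 = np.zeros((p, K))
    for k, sup in enumerate(edge_support):
        P0[sup, k] = 1.0 / math.sqrt(len(sup))

    Ex = cfg.noise_sd_connectivity * rng.standard_normal((n, p))
    X0 = Z @ P0.T
    Tc = targets_arr - targets_arr.mean(axis=0)
    sig_signal = np.linalg.svd(X0.T @ Tc, compute_uv=False)[0]
    sig_noise = np.linalg.svd(Ex.T @ Tc, compute_uv=False)[0]
    if sig_signal == 0:
        raise ValueError("degenerate signal cross-covariance")
    # noiseless edge domain: no calibration needed
    alpha = cfg.snr * sig_noise / sig_signal if sig_noise > 0 else 1.0
    X = alpha * X0 + Ex

    truth = GroundTruth(
        latent=Z,
        phenotype_loadings=C,
        edge_loadings=alpha * P0,
        phenotype_support=[list(s) for s in supports],
        edge_support=edge_support,
        phenotype_targets=targets_arr,
        noise_sd_phenotype=cfg.noise_sd_phenotype,
        noise_sd_connectivity=cfg.noise_sd_connectivity,
        snr=cfg.snr,
        signal_scale=float(alpha),
    )

    time_series = None
    if cfg.timeseries:
        time_series, X = _timeseries_route(X, edges, cfg, rng)

    cols = [f"e{i}_{j}" for i, j in edges.pairs]
    connectivity = pd.DataFrame(X, index=subject_ids, columns=cols)
    return SimulatedCohort(
        raw_phenotypes=raw,
        pedigree=pedigree,
        connectivity=connectivity,
        region_table=regions,
        edge_index=edges,
        ground_truth=truth,
        time_series=time_series,
    )


def _timeseries_route(X, edges, cfg, rng):
    """Per-subject series whose sample FC carries the planted deviations."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = np.clip((X - mean) / sd, -3.0, 3.0)
    base = _base_correlation(edges)
    series = []
    fc_edges = np.empty_like(X)
    for i in range(X.shape[0]):
        target = base + rebuild_matrix(cfg.deviation_scale * Xz[i], edges)
        R = nearest_pd_correlation(target)
        L = np.linalg.cholesky(R)
        ts = rng.standard_normal((cfg.n_timepoints, edges.n_regions)) @ L.T
        series.append(ts)
        fc = np.corrcoef(ts, rowvar=False)
        fc_edges[i] = fc[edges.pairs[:, 0], edges.pairs[:, 1]]
    return series, fc_edges


# ---------------------------------------------------------------------------
# recovery scoring


def _support_prf(pred_nonzero: np.ndarray, true_idx: np.ndarray, size: int):
    pred = np.zeros(size, dtype=bool)
    pred[pred_nonzero] = True
    true = np.zeros(size, dtype=bool)
    true[true_idx] = True
    tp = np.sum(pred & true)
    precision = tp / pred.sum() if pred.sum() else 0.0
    recall = tp / true.sum() if true.sum() else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


def _abs_corr(a, b):
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return abs(float(np.corrcoef(a, b)[0, 1]))


def recovery_report(model, truth: GroundTruth) -> pd.DataFrame:
    """Score a fitted model against the planted structure.

    Factors are greedily matched to fitted components on the absolute
    correlation between fitted latent scores and planted factor scores;
    each matched pair reports support precision/recall/F1 for both
    domains, the score correlation and loading cosines (all
    sign-agnostic).
    """
    S = model.x_scores_
    Z = truth.latent
    K_fit, K_true = S.shape[1], Z.shape[1]
    corr = np.array(
        [[_abs_corr(S[:, k], Z[:, j]) for j in range(K_true)]
         for k in range(K_fit)]
    )
    pairs = []
    used_fit, used_true = set(), set()
    for _ in range(min(K_fit, K_true)):
        masked = corr.copy()
        for k in used_fit:
            masked[k, :] = -1
        for j in used_true:
            masked[:, j] = -1
        k, j = np.unravel_index(np.argmax(masked), masked.shape)
        pairs.append((int(k), int(j)))
        used_fit.add(int(k))
        used_true.add(int(j))

    col_pos = {name: i for i, name in enumerate(PHENOTYPE_COLUMNS)}
    rows = []
    for k, j in pairs:
        u, v = model.x_weights_[:, k], model.y_weights_[:, k]
        ph_true = np.array([col_pos[n] for n in truth.phenotype_support[j]])
        pp, pr, pf = _support_prf(np.flatnonzero(v), ph_true, len(v))
        ep, er, ef = _support_prf(
            np.flatnonzero(u), truth.edge_support[j], len(u)
        )
        pl = truth.phenotype_loadings[:, j]
        el = truth.edge_loadings[:, j]
        rows.append(
            {
                "component": k,
                "factor": j,
                "score_abs_corr": corr[k, j],
                "phenotype_precision": pp,
                "phenotype_recall": pr,
                "phenotype_f1": pf,
                "edge_precision": ep,
                "edge_recall": er,
                "edge_f1": ef,
                "phenotype_cosine": abs(v @ pl)
                / (np.linalg.norm(v) * np.linalg.norm(pl)),
                "edge_cosine": abs(u @ el)
                / (np.linalg.norm(u) * np.linalg.norm(el)),
            }
        )
    return pd.DataFrame(rows)
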