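"""Network-level inference on fitted connectivity coefficients.

A fitted component's edge weights are summarized per network block
(SN-SN, FPN-FPN, DMN-DMN, SN-FPN, SN-DMN). Block significance uses a
coefficient-shuffling null: the observed block statistic is the sum of
absolute coefficients, compared against the 99th percentile of the same
statistic under random reassignment of coefficients to edge positions
(block memberships fixed). Regional substrates come from signed
strengths of the rebuilt symmetric coefficient matrix, and circuit
summaries impose the triple-network-model directionality (SN drives FPN
and DMN).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import BLOCK_NAMES, EdgeIndex, rebuild_matrix  # noqa: F401


def block_partition(
    edges: EdgeIndex, by_hemisphere: bool = False
) -> dict[str, np.ndarray]:
    """Edge positions per network block.

    With ``by_hemisphere=True`` each block is refined by the hemisphere
    pair of its endpoints (e.g. ``SN_L-FPN_R``); the refinement still
    partitions the edge index.
    """
    if not by_hemisphere:
        part = edges.block_indices()
    else:
        if edges.hemispheres is None:
            raise ValueError("edge index carries no hemisphere labels")
        labels = []
        for blk, (hi, hj) in zip(edges.blocks, edges.hemispheres):
            a, b = blk.split("-")
            labels.append(f"{a}_{hi}-{b}_{hj}")
        labels = np.asarray(labels, dtype=object)
        part = {name: np.flatnonzero(labels == name)
                for name in pd.unique(labels)}
    return {k: v for k, v in part.items() if v.size > 0}


def _check_partition(u: np.ndarray, partition: dict) -> None:
    sizes = sum(len(idx) for idx in partition.values())
    all_idx = np.concatenate([np.asarray(idx) for idx in partition.values()])
    if sizes != len(u) or len(np.unique(all_idx)) != len(u):
        raise ValueError("blocks do not partition the edge vector")


def block_contributions(u: np.ndarray, partition: dict) -> pd.DataFrame:
    """Per-block sum of absolute and of signed coefficients.

    Absolute contributions over all blocks sum to ``||u||_1`` exactly.
    """
    u = np.asarray(u, dtype=float)
    _check_partition(u, partition)
    rows = {
        name: (np.abs(u[idx]).sum(), u[idx].sum(), len(idx))
        for name, idx in partition.items()
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["abs_sum", "signed_sum", "n_edges"]
    ).rename_axis("block")


@dataclass
class BlockTestResult:
    """Coefficient-shuffle null test over network blocks."""

    table: pd.DataFrame  # per block: observed, threshold, significant, direction
    null_distributions: pd.DataFrame = field(repr=False)  # n_perm x blocks
    n_permutations: int = 1000
    percentile: float = 99.0
    seed: int | None = None


def permutation_block_test(
    u: np.ndarray,
    partition: dict,
    n_perm: int = 1000,
    percentile: float = 99.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BlockTestResult:
    """Test block contributions against a coefficient-shuffling null.

    For each of `n_perm` draws the coefficients are reassigned to edge
    positions by a uniform random permutation while block memberships
    stay fixed; a block is significant when its observed absolute
    contribution strictly exceeds the chosen percentile
    (linear-interpolation quantile) of its null ensemble. Direction is
    the sign of the observed signed sum.
    """
    u = np.asarray(u, dtype=float)
    _check_partition(u, partition)
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} < 100: the {percentile}th percentile is "
            "unstable", UserWarning, stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    obs = block_contributions(u, partition)
    a = np.abs(u)
    p = len(u)
    names = list(partition.keys())
    indicator = np.zeros((p, len(names)))
    for k, name in enumerate(names):
        indicator[partition[name], k] = 1.0
    # permuting values onto positions == summing a permuted |u| per block
    null = np.empty((n_perm, len(names)))
    for b in range(n_perm):
        null[b] = rng.permutation(a) @ indicator
    thresholds = np.percentile(null, percentile, axis=0)
    table = obs.loc[names].copy()
    table["null_threshold"] = thresholds
    # strict exceedance, with a relative guard against ties that differ
    # only by floating-point summation order
    obs_sums = table["abs_sum"].to_numpy()
    guard = 1e-9 * np.maximum(1.0, np.abs(thresholds))
    table["significant"] = obs_sums > thresholds + guard
    table["direction"] = np.sign(table["signed_sum"]).astype(int)
    return BlockTestResult(
        table=table,
        null_distributions=pd.DataFrame(null, columns=names),
        n_permutations=n_perm,
        percentile=percentile,
        seed=seed,
    )


def signed_strengths(
    W: np.ndarray, regions: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-region positive, negative and net strength.

    For the symmetric coefficient matrix W, positive strength is the sum
    of the positive entries of a region's row, negative strength the sum
    of the negative entries, and net their sum. Net strengths over all
    regions sum to twice the sum of edge coefficients.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("W must be symmetric")
    pos = np.clip(W, 0, None).sum(axis=1)
    neg = np.clip(W, None, 0).sum(axis=1)
    out = pd.DataFrame(
        {"positive": pos, "negative": neg, "net": pos + neg}
    ).rename_axis("region_id")
    if regions is not None:
        out["network"] = regions["tnm_network"].to_numpy()
        out["hemisphere"] = regions["hemisphere"].to_numpy()
        out["name"] = regions["name"].to_numpy()
    return out


def top_regions(
    profile: pd.DataFrame, fraction: float = 0.05
) -> tuple[pd.DataFrame, float]:
    """Top regions by absolute net strength.

    Keeps ``k = ceil(fraction * N)`` regions ranked by ``|net|``
    descending (ties broken by region index) and also returns the
    ``1 - fraction`` quantile of ``|net|`` — the threshold line drawn on
    strength profiles.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    net = profile["net"].to_numpy()
    k = math.ceil(fraction * len(net))
    order = np.lexsort((np.arange(len(net)), -np.abs(net)))
    threshold = float(np.percentile(np.abs(net), 100 * (1 - fraction)))
    return profile.iloc[order[:k]].copy(), threshold


#: circuit elements in the TNM: self-loops plus the two SN-driven arrows
CIRCUIT_EDGES = {
    "SN-SN": ("SN", "SN"),
    "FPN-FPN": ("FPN", "FPN"),
    "DMN-DMN": ("DMN", "DMN"),
    "SN-FPN": ("SN", "FPN"),
    "SN-DMN": ("SN", "DMN"),
}


def circuit_summary(test: BlockTestResult) -> pd.DataFrame:
    """Directed circuit diagram from a block test.

    SN-FPN and SN-DMN blocks become SN->FPN and SN->DMN arrows (the
    directionality is imposed by the triple network model, never
    reversed); within-network blocks become self-loops. Each element is
    labeled ``increased``, ``decreased`` or ``not-significant`` from the
    test's significance flag and signed direction.
    """
    missing = set(CIRCUIT_EDGES) - set(test.table.index)
    if missing:
        raise ValueError(f"block test lacks required blocks: {sorted(missing)}")
    rows = []
    for block, (src, dst) in CIRCUIT_EDGES.items():
        rec = test.table.loc[block]
        if not rec["significant"]:
            state = "not-significant"
        elif rec["direction"] > 0:
            state = "increased"
        else:
            state = "decreased"
        rows.append(
            {
                "source": src,
                "target": dst,
                "block": block,
                "state": state,
                "observed": rec["abs_sum"],
                "threshold": rec["null_threshold"],
            }
        )
    return pd.DataFrame(rows)
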