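"""Connectivity domain: Pearson FC, TNM edge index, vectorization.

The connectivity domain presented to PLS is the vectorized strict upper
triangle of each subject's region-by-region Pearson correlation matrix,
restricted to the couplings the triple network model allows: edges within
SN, FPN and DMN and edges joining SN to FPN and SN to DMN. Direct
FPN-DMN couplings are excluded by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import TNM_NETWORKS

#: canonical block names in a fixed presentation order
BLOCK_NAMES = ("SN-SN", "FPN-FPN", "DMN-DMN", "SN-FPN", "SN-DMN")


def _block_name(net_i: str, net_j: str) -> str | None:
    if net_i == net_j:
        return f"{net_i}-{net_i}"
    pair = {net_i, net_j}
    if pair == {"SN", "FPN"}:
        return "SN-FPN"
    if pair == {"SN", "DMN"}:
        return "SN-DMN"
    return None  # FPN-DMN: excluded by the TNM


@dataclass(frozen=True)
class EdgeIndex:
    """Ordered list of allowed region pairs with network-block labels.

    Pairs follow a row-major traversal of the strict upper triangle of
    the TNM-restricted region ordering, so the edge order is a pure
    function of the region table.
    """

    pairs: np.ndarray  # (p, 2) int, i < j
    blocks: np.ndarray  # (p,) str, one of BLOCK_NAMES
    n_regions: int
    hemispheres: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_edges(self) -> int:
        return len(self.pairs)

    def block_indices(self) -> dict:
        """Edge positions per block, in canonical block order."""
        return {
            name: np.flatnonzero(self.blocks == name) for name in BLOCK_NAMES
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_i": self.pairs[:, 0],
                "region_j": self.pairs[:, 1],
                "block": self.blocks,
            }
        )


def build_edge_index(regions: pd.DataFrame) -> EdgeIndex:
    """Enumerate allowed TNM edges for a restricted region table.

    For network sizes s (SN), f (FPN), d (DMN) the edge count is
    ``s(s-1)/2 + f(f-1)/2 + d(d-1)/2 + s*f + s*d``.

    Raises
    ------
    ValueError
        If any of the three networks has no region.
    """
    nets = regions["tnm_network"].to_numpy()
    for name in TNM_NETWORKS:
        if not (nets == name).any():
            raise ValueError(f"region table has no {name} regions")
    n = len(regions)
    if not np.array_equal(regions["region_id"].to_numpy(), np.arange(n)):
        raise ValueError("region_id must be 0-based and contiguous")
    hemi = regions["hemisphere"].to_numpy() if "hemisphere" in regions else None
    pairs, blocks, pair_hemi = [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            name = _block_name(nets[i], nets[j])
            if name is None:
                continue
            pairs.append((i, j))
            blocks.append(name)
            if hemi is not None:
                pair_hemi.append((hemi[i], hemi[j]))
    return EdgeIndex(
        pairs=np.asarray(pairs, dtype=np.intp),
        blocks=np.asarray(blocks, dtype=object),
        n_regions=n,
        hemispheres=np.asarray(pair_hemi, dtype=object) if hemi is not None else None,
    )


def compute_fc(ts: np.ndarray, region_names=None) -> np.ndarray:
    """Pearson correlation matrix of mean regional time series.

    Parameters
    ----------
    ts : ndarray of shape (T, N)
        Time points by regions.

    Returns
    -------
    ndarray of shape (N, N)
        Symmetric correlation matrix with unit diagonal.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D (T, N) array")
    T, N = ts.shape
    if T < 3:
        raise ValueError(f"need at least 3 time points, got {T}")
    sd = ts.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        label = region_names[bad[0]] if region_names is not None else int(bad[0])
        raise ValueError(f"region {label!r} has zero temporal variance")
    fc = np.corrcoef(ts, rowvar=False)
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return fc


def vectorize_fc(fc: np.ndarray, edges: EdgeIndex) -> np.ndarray:
    """Collect the allowed upper-triangle entries into an edge vector."""
    fc = np.asarray(fc, dtype=float)
    if fc.shape != (edges.n_regions, edges.n_regions):
        raise ValueError(
            f"FC matrix is {fc.shape}, edge index expects "
            f"({edges.n_regions}, {edges.n_regions})"
        )
    return fc[edges.pairs[:, 0], edges.pairs[:, 1]].copy()


def rebuild_matrix(u: np.ndarray, edges: EdgeIndex) -> np.ndarray:
    """Scatter an edge vector back into a symmetric coefficient matrix.

    Diagonal and excluded (FPN-DMN) positions are zero.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (edges.n_edges,):
        raise ValueError(
            f"edge vector has length {u.shape}, expected ({edges.n_edges},)"
        )
    W = np.zeros((edges.n_regions, edges.n_regions))
    W[edges.pairs[:, 0], edges.pairs[:, 1]] = u
    W[edges.pairs[:, 1], edges.pairs[:, 0]] = u
    return W


def stack_cohort(fcs, edges: EdgeIndex, subject_ids) -> pd.DataFrame:
    """Stack per-subject FC matrices into a subjects-by-edges matrix.

    Returns a DataFrame indexed by subject id; column order follows the
    edge index.
    """
    subject_ids = list(subject_ids)
    fcs = list(fcs)
    if len(subject_ids) != len(fcs):
        raise ValueError("one subject id per FC matrix required")
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids")
    X = np.vstack([vectorize_fc(fc, edges) for fc in fcs])
    cols = [f"e{i}_{j}" for i, j in edges.pairs]
    return pd.DataFrame(X, index=pd.Index(subject_ids, name="subject_id"),
                        columns=cols)


def edge_vector_to_frame(u: np.ndarray, edges: EdgeIndex) -> pd.DataFrame:
    """Long-format export of an edge vector (region_i, region_j, block, value)."""
    frame = edges.to_frame()
    frame["value"] = np.asarray(u, dtype=float)
    return frame
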