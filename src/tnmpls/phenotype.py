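"""Phenotype domain: FHD scoring, transforms, and the 8-variable table.

The phenotype domain condenses raw alcohol-use measures into eight
standardized variables: Sex, Age, Education, FHD (family-history
density), AUD symptom count, Drinking (first PC of five log-transformed
drinking measures), Urgency (first PC of positive and negative urgency)
and AlcoholSeeking (first PC of the two alcohol-preference contrasts).

Family-history density weights affected parents and full siblings 0.5,
affected grandparents and parents' siblings 0.25, and divides the summed
weights by the number of counted relatives, giving a score in [0, 0.5].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PHENOTYPE_COLUMNS = (
    "Sex", "Age", "Education", "FHD", "AUD_Symptoms",
    "Drinking", "Urgency", "AlcoholSeeking",
)

DRINKING_VARIABLES = ("tlfb_ddd", "tlfb_ddw", "tlfb_dw", "tlfb_gdd", "ldh_kg")

FHD_WEIGHTS = {
    "parent": 0.5,
    "full_sibling": 0.5,
    "grandparent": 0.25,
    "parent_sibling": 0.25,
}


def compute_fhd(pedigree) -> float:
    """Family-history density of a pedigree.

    Parameters
    ----------
    pedigree : iterable of (relationship, affected)
        Relationship is one of ``parent``, ``full_sibling``,
        ``grandparent``, ``parent_sibling``; affected is boolean.

    Returns
    -------
    float
        Sum of affection weights divided by the number of counted
        relatives; lies in [0, 0.5].
    """
    relatives = list(pedigree)
    if not relatives:
        raise ValueError("empty pedigree: family-history density undefined")
    total = 0.0
    for relationship, affected in relatives:
        if relationship not in FHD_WEIGHTS:
            raise ValueError(f"unknown relationship {relationship!r}")
        if affected:
            total += FHD_WEIGHTS[relationship]
    return total / len(relatives)


def log_transform_drinking(values) -> np.ndarray:
    """Skew-reducing ``ln(1 + x)`` transform for drinking measures."""
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValueError("drinking variables must be nonnegative")
    return np.log1p(values)


def alcohol_preference(cwa, cww) -> np.ndarray:
    """Work-for-alcohol minus work-for-water trial-count contrast."""
    cwa = np.asarray(cwa, dtype=float)
    cww = np.asarray(cww, dtype=float)
    if (cwa < 0).any() or (cww < 0).any():
        raise ValueError("trial counts must be nonnegative")
    return cwa - cww


def zscore(column, name: str = "column") -> np.ndarray:
    """Standardize to mean 0, sample SD 1 (n-1 denominator)."""
    x = np.asarray(column, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"variable {name!r} is constant; cannot z-score")
    return (x - x.mean()) / sd


def pca_compress(columns: np.ndarray):
    """Kaiser-rule PCA of standardized columns.

    Eigendecomposes the m-by-m correlation matrix of the (already
    standardized) input and retains components with eigenvalue > 1.
    Each retained component is oriented so its loading sum is positive.

    Returns
    -------
    scores : ndarray (n, k)
        Subject scores on the retained components.
    eigenvalues : ndarray (m,)
        All eigenvalues, descending.
    loadings : ndarray (m, k)
        Retained eigenvectors as columns.
    """
    Z = np.asarray(columns, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 2:
        raise ValueError("need an n-by-m matrix with m >= 2")
    corr = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > 1.0
    if not keep.any():
        raise ValueError(
            "no eigenvalue exceeds 1; Kaiser rule retains nothing — "
            "inspect the correlation structure or pass the variables through"
        )
    loadings = eigvec[:, keep]
    signs = np.where(loadings.sum(axis=0) >= 0, 1.0, -1.0)
    loadings = loadings * signs
    scores = Z @ loadings
    return scores, eigval, loadings


def _first_pc(raw: pd.DataFrame, names) -> tuple[np.ndarray, dict]:
    Z = np.column_stack([zscore(raw[c], c) for c in names])
    scores, eigval, loadings = pca_compress(Z)
    meta = {
        "variables": list(names),
        "eigenvalues": eigval.tolist(),
        "explained_variance": (eigval / eigval.sum()).tolist(),
        "loadings_pc1": loadings[:, 0].tolist(),
    }
    return scores[:, 0], meta


def fhd_from_pedigree_table(pedigree: pd.DataFrame) -> pd.Series:
    """Per-subject FHD from a long-format pedigree table.

    Expected columns: ``subject_id``, ``relationship``, ``affected``.
    """
    def _one(group):
        return compute_fhd(zip(group["relationship"], group["affected"]))

    return pedigree.groupby("subject_id", sort=False).apply(
        _one, include_groups=False
    )


def assemble_phenotype_table(
    raw: pd.DataFrame,
    pedigree: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Derive the standardized 8-variable phenotype table.

    Parameters
    ----------
    raw : DataFrame
        One row per subject (index = subject id) with columns ``sex``
        ("male"/"female" or 0/1), ``age``, ``education``,
        ``aud_symptoms``, the five drinking variables
        (``tlfb_ddd``, ``tlfb_ddw``, ``tlfb_dw``, ``tlfb_gdd``,
        ``ldh_kg``), ``pur``, ``nur`` and the four seeking counts
        (``n_cwa``, ``n_cww``, ``a_cwa``, ``a_cww``). An ``fhd`` column
        is used directly when present.
    pedigree : DataFrame, optional
        Long-format pedigree (subject_id, relationship, affected);
        required when `raw` has no ``fhd`` column.

    Returns
    -------
    table : DataFrame (n, 8)
        Z-scored phenotype table, column order ``PHENOTYPE_COLUMNS``.
    provenance : dict
        Per-composite eigenvalues, explained variance and loadings,
        plus the coding conventions applied.
    """
    if len(raw) < 3:
        raise ValueError("need at least 3 subjects")
    raw = raw.copy()
    provenance: dict = {"sex_coding": {"female": 0, "male": 1},
                        "log_transform": "ln(1+x)",
                        "zscore_ddof": 1}

    if raw["sex"].dtype == object:
        sex = raw["sex"].str.lower().map({"female": 0.0, "male": 1.0})
        if sex.isna().any():
            bad = raw.loc[sex.isna(), "sex"].unique().tolist()
            raise ValueError(f"unrecognized sex labels: {bad}")
    else:
        sex = raw["sex"].astype(float)

    if "fhd" in raw.columns:
        fhd = raw["fhd"].astype(float)
    else:
        if pedigree is None:
            raise ValueError("need either an 'fhd' column or a pedigree table")
        fhd = fhd_from_pedigree_table(pedigree).reindex(raw.index)
        if fhd.isna().any():
            missing = raw.index[fhd.isna()].tolist()
            raise ValueError(f"no pedigree for subjects: {missing}")

    drinking_log = raw[list(DRINKING_VARIABLES)].apply(
        log_transform_drinking, axis=0
    )
    drinking, meta_d = _first_pc(drinking_log, DRINKING_VARIABLES)
    urgency, meta_u = _first_pc(raw, ("pur", "nur"))

    seeking = pd.DataFrame(
        {
            "neutral_ap": alcohol_preference(raw["n_cwa"], raw["n_cww"]),
            "aversive_ap": alcohol_preference(raw["a_cwa"], raw["a_cww"]),
        },
        index=raw.index,
    )
    alcohol_seeking, meta_s = _first_pc(seeking, ("neutral_ap", "aversive_ap"))

    provenance["Drinking"] = meta_d
    provenance["Urgency"] = meta_u
    provenance["AlcoholSeeking"] = meta_s

    columns = {
        "Sex": sex.to_numpy(),
        "Age": raw["age"].to_numpy(float),
        "Education": raw["education"].to_numpy(float),
        "FHD": fhd.to_numpy(),
        "AUD_Symptoms": raw["aud_symptoms"].to_numpy(float),
        "Drinking": drinking,
        "Urgency": urgency,
        "AlcoholSeeking": alcohol_seeking,
    }
    table = pd.DataFrame(
        {name: zscore(values, name) for name, values in columns.items()},
        index=raw.index,
    )[list(PHENOTYPE_COLUMNS)]
    return table, provenance
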