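"""Parcellation handling and triple-network-model (TNM) region space.

The TNM restricts a whole-brain parcellation to three large-scale
resting-state networks defined on the Yeo 17-network scheme:

* salience network (SN)          = Ventral Attention A + B
* frontoparietal network (FPN)   = Control A + B + C
* default mode network (DMN)     = Default A + B + C

All other subnetworks (visual, somatomotor, limbic, subcortex, ...) are
excluded from the TNM region space.
"""

from __future__ import annotations

import re

import pandas as pd

TNM_NETWORKS = ("SN", "FPN", "DMN")

#: canonical Yeo-17 subnetwork spellings used internally
CANONICAL_SUBNETWORKS = (
    "VisCent", "VisPeri", "SomMotA", "SomMotB", "DorsAttnA", "DorsAttnB",
    "VentAttnA", "VentAttnB", "LimbicA", "LimbicB",
    "ContA", "ContB", "ContC", "DefaultA", "DefaultB", "DefaultC", "TempPar",
)

_SUBNETWORK_TO_TNM = {
    "VentAttnA": "SN",
    "VentAttnB": "SN",
    "ContA": "FPN",
    "ContB": "FPN",
    "ContC": "FPN",
    "DefaultA": "DMN",
    "DefaultB": "DMN",
    "DefaultC": "DMN",
}

# atlas naming dialects -> canonical spelling (keys are lower-case,
# whitespace/underscore stripped)
_SYNONYMS = {
    "salventattna": "VentAttnA",
    "salventattnb": "VentAttnB",
    "ventralattentionnetworka": "VentAttnA",
    "ventralattentionnetworkb": "VentAttnB",
    "ventattna": "VentAttnA",
    "ventattnb": "VentAttnB",
    "controla": "ContA",
    "controlb": "ContB",
    "controlc": "ContC",
    "defaulta": "DefaultA",
    "defaultb": "DefaultB",
    "defaultc": "DefaultC",
    "limbica": "LimbicA",
    "limbicb": "LimbicB",
    "limbicofc": "LimbicA",
    "limbictemppole": "LimbicB",
    # non-cortical / unassigned labels carried in the full region space
    "other": "other",
    "none": "other",
    "subcortex": "other",
    "subcortical": "other",
}
_SYNONYMS.update({name.lower(): name for name in CANONICAL_SUBNETWORKS})


def _normalize_label(label: str) -> str:
    key = re.sub(r"[\s_\-]+", "", str(label)).lower()
    try:
        return _SYNONYMS[key]
    except KeyError:
        raise ValueError(
            f"unrecognized Yeo-17 subnetwork label: {label!r}"
        ) from None


def map_yeo17_to_tnm(label: str) -> str:
    """Map a Yeo-17 subnetwork label to its TNM network.

    Returns ``"SN"``, ``"FPN"`` or ``"DMN"`` for the eight TNM
    subnetworks and ``"excluded"`` for every other recognized label.
    Matching is case-insensitive and accepts both the ``SalVentAttnA``
    atlas spelling and the spelled-out ``Ventral Attention Network A``.

    Raises
    ------
    ValueError
        If `label` is not a recognized subnetwork name.
    """
    canonical = _normalize_label(label)
    return _SUBNETWORK_TO_TNM.get(canonical, "excluded")


def _parse_hemisphere(name: str) -> str:
    m = re.match(r"^\s*(LH|RH|L|R)[_\-]", str(name), flags=re.IGNORECASE)
    if m:
        return m.group(1)[0].upper()
    return "none"


def make_region_table(
    names,
    subnetworks,
    hemispheres=None,
) -> pd.DataFrame:
    """Build a region table from parallel label sequences.

    Returns a DataFrame with columns ``region_id`` (0-based, contiguous),
    ``name``, ``subnetwork17`` (canonical spelling), ``tnm_network`` and
    ``hemisphere``. Hemisphere is parsed from an ``LH_``/``RH_`` name
    prefix when not given explicitly.
    """
    names = list(names)
    sub = [_normalize_label(s) for s in subnetworks]
    if len(sub) != len(names):
        raise ValueError("names and subnetworks must have equal length")
    if hemispheres is None:
        hemi = [_parse_hemisphere(n) for n in names]
    else:
        hemi = [h if h in ("L", "R") else "none" for h in hemispheres]
    table = pd.DataFrame(
        {
            "region_id": range(len(names)),
            "name": names,
            "subnetwork17": sub,
            "tnm_network": [_SUBNETWORK_TO_TNM.get(s, "excluded") for s in sub],
            "hemisphere": hemi,
        }
    )
    if table["name"].duplicated().any():
        dups = table.loc[table["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate region names: {dups}")
    return table


def load_parcellation(path) -> pd.DataFrame:
    """Read a parcellation lookup CSV.

    Expected header: ``region_id,name,subnetwork17[,hemisphere]``.
    """
    raw = pd.read_csv(path)
    required = {"region_id", "name", "subnetwork17"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"parcellation file misses columns: {sorted(missing)}")
    table = make_region_table(
        raw["name"],
        raw["subnetwork17"],
        raw["hemisphere"] if "hemisphere" in raw.columns else None,
    )
    table["atlas_id"] = raw["region_id"].to_numpy()
    return table


def restrict_to_tnm(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only SN/FPN/DMN regions and re-index them contiguously.

    The original ids survive in an ``atlas_id`` column so edge tables can
    be traced back to the full parcellation.
    """
    if "atlas_id" not in table.columns:
        table = table.assign(atlas_id=table["region_id"])
    sub = table[table["tnm_network"].isin(TNM_NETWORKS)].copy()
    if sub.empty:
        raise ValueError("no TNM regions in table")
    sub = sub.reset_index(drop=True)
    sub["region_id"] = range(len(sub))
    return sub


def network_sizes(table: pd.DataFrame) -> dict:
    """Region counts per TNM network for a (restricted) table."""
    counts = table["tnm_network"].value_counts()
    return {net: int(counts.get(net, 0)) for net in TNM_NETWORKS}
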