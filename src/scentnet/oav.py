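"""Odor-activity values and key-volatile screening.

The odor activity value of a compound in a condition is its content divided
by its odor-detection threshold. Contents are in ug·g⁻¹ fresh weight and
thresholds in ng·g⁻¹ (in water), so

    OAV = content_ug_per_g * 1000 / threshold_ng_per_g.

Compounds with OAV strictly greater than 1 are the "key" fragrant volatiles;
those above a much larger cut (default 30000) are the predominant ones.
Compounds lacking a threshold are reported with tier ``no-threshold``, never
silently dropped. Compounds whose literature threshold is a range get an OAV
interval [oav_low, oav_high]; their key/tier calls use the conservative
lower bound.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .quantify import ConcentrationMatrix
from .registry_io import CompoundRegistry

TIER_PREDOMINANT = 30000.0
TIER_HIGH = 5000.0

_TIER_ORDER = ["predominant_high", "high", "key", "sub-threshold", "no-threshold"]


def _tier(oav: float | None) -> str:
    if oav is None or (isinstance(oav, float) and math.isnan(oav)):
        return "no-threshold"
    if oav > TIER_PREDOMINANT:
        return "predominant_high"
    if oav > TIER_HIGH:
        return "high"
    if oav > 1.0:
        return "key"
    return "sub-threshold"


def compute_oav(conc: ConcentrationMatrix, registry: CompoundRegistry) -> pd.DataFrame:
    """OAV per detected (compound, condition) cell, long form.

    Columns: code, condition, content_ug_per_g, threshold_ng_per_g, oav,
    oav_low, oav_high, tier, key_flag. Rows exist only where the compound
    was measured (a measured zero yields OAV 0; a missing cell yields no row).
    """
    unregistered = registry.unregistered(conc.values.index)
    if unregistered:
        raise KeyError(f"unregistered compound codes: {unregistered}")

    rows = []
    for code in conc.values.index:
        compound = registry[code]
        for cond in conc.values.columns:
            content = conc.values.at[code, cond]
            if pd.isna(content):
                continue
            oav = oav_low = oav_high = np.nan
            if compound.threshold is not None:
                oav = content * 1000.0 / compound.threshold
                oav_low = oav_high = oav
            elif compound.threshold_low is not None:
                oav_low = content * 1000.0 / compound.threshold_high
                oav_high = content * 1000.0 / compound.threshold_low
            effective = oav if not np.isnan(oav) else oav_low
            tier = _tier(None if np.isnan(effective) else effective)
            rows.append(
                {
                    "code": code,
                    "condition": cond,
                    "content_ug_per_g": content,
                    "threshold_ng_per_g": compound.threshold,
                    "oav": oav,
                    "oav_low": oav_low,
                    "oav_high": oav_high,
                    "tier": tier,
                    "key_flag": bool(not np.isnan(effective) and effective > 1.0),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "code", "condition", "content_ug_per_g", "threshold_ng_per_g",
            "oav", "oav_low", "oav_high", "tier", "key_flag",
        ],
    )
    return df.sort_values(["condition", "code"]).reset_index(drop=True)


def screen_key_volatiles(oavs: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Key volatiles (OAV > 1) per condition, sorted OAV-descending.

    Ties are broken by compound code ascending, so output order is
    deterministic. Interval-only rows sort by their lower OAV bound.
    """
    out: dict[str, pd.DataFrame] = {}
    for cond, block in oavs.groupby("condition", sort=True):
        keys = block[block["key_flag"]].copy()
        keys["_sort_oav"] = keys["oav"].fillna(keys["oav_low"])
        keys = keys.sort_values(
            ["_sort_oav", "code"], ascending=[False, True]
        ).drop(columns="_sort_oav").reset_index(drop=True)
        out[cond] = keys
    return out


def predominant_volatiles(oavs: pd.DataFrame, tier_cut: float = TIER_PREDOMINANT) -> dict[str, set[str]]:
    """Key volatiles whose OAV exceeds ``tier_cut``, per condition."""
    if not tier_cut > 1.0:
        raise ValueError("tier_cut must be > 1")
    out: dict[str, set[str]] = {}
    for cond, block in oavs.groupby("condition", sort=True):
        eff = block["oav"].fillna(block["oav_low"])
        out[cond] = set(block.loc[block["key_flag"] & (eff > tier_cut), "code"])
    return out


def format_oav(x: float) -> str:
    """Report rendering: scientific notation at 3 significant figures for
    OAV >= 1e4, else 2 decimals."""
    if pd.isna(x):
        return ""
    if x >= 1e4:
        mantissa, exp = f"{x:.2e}".split("e")
        return f"{mantissa}x10^{int(exp)}"
    return f"{x:.2f}"
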