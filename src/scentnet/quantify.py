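"""Internal-standard quantification and peak-area normalization.

Absolute contents follow the single-point internal-standard convention: a
known mass of ethyl decanoate (mg) is spiked into each headspace bottle, and

    content_i [ug/g FW] = (area_i / area_IS) * is_mass_mg * 1000 / fresh_weight_g

with response factors assumed 1.0 for every analyte (semi-quantification).
Relative contents are percentages of the per-sample total over detected
compounds (peak-area normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry_io import IS_CODE, PeakTable, SampleKey, RegistryError


@dataclass
class ConcentrationMatrix:
    """Absolute contents (ug per g fresh weight), compound x sample/condition.

    ``kind`` is ``"sample"`` for per-replicate values and ``"condition_mean"``
    after replicate averaging, in which case ``se`` (standard error of the
    mean), ``n`` (replicate count) and ``partial_missing`` (compound detected
    in some but not all replicates, zero-filled in the mean) are populated.
    """

    values: pd.DataFrame
    kind: str = "sample"
    se: pd.DataFrame | None = None
    n: pd.Series | None = None
    partial_missing: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if (self.values < 0).any().any():
            raise ValueError("concentrations must be non-negative")
        if self.kind not in ("sample", "condition_mean"):
            raise ValueError(f"unknown ConcentrationMatrix kind {self.kind!r}")

    @property
    def codes(self) -> list[str]:
        return list(self.values.index)


@dataclass
class RelativeContentMatrix:
    """Percent-of-sample-total contents (0-100), same shape as the source."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)


def areas_to_concentrations(peaks: PeakTable) -> ConcentrationMatrix:
    """Convert raw peak areas to absolute contents via the internal standard.

    Missing areas stay missing; a measured zero area maps to 0 ug/g. The
    result is linear in each compound's area at fixed IS area and invariant
    to rescaling all of a sample's areas by a constant.
    """
    is_area = peaks.areas.loc[IS_CODE]
    analyte = peaks.areas.drop(index=IS_CODE)
    # mg -> ug conversion gives the factor 1000
    factor = peaks.is_mass * 1000.0 / peaks.fresh_weight
    conc = analyte.div(is_area, axis=1).mul(factor, axis=1)
    return ConcentrationMatrix(values=conc, kind="sample")


def replicate_means(conc: ConcentrationMatrix) -> ConcentrationMatrix:
    """Average replicates per (genotype, stage, organ) condition.

    A compound missing in every replicate stays missing; missing in only
    some replicates is treated as 0 in the mean (and SE) but flagged in
    ``partial_missing``. SE = sd/sqrt(n) with ddof=1; a single replicate has
    no SE.
    """
    if conc.kind != "sample":
        raise ValueError("replicate_means expects per-sample concentrations")
    groups: dict[str, list[str]] = {}
    for col in conc.values.columns:
        groups.setdefault(SampleKey.parse(col).condition, []).append(col)

    means, ses, ns, partial = {}, {}, {}, {}
    for cond, cols in groups.items():
        block = conc.values[cols]
        all_missing = block.isna().all(axis=1)
        any_missing = block.isna().any(axis=1)
        filled = block.fillna(0.0)
        m = filled.mean(axis=1)
        m[all_missing] = np.nan
        if len(cols) > 1:
            s = filled.std(axis=1, ddof=1) / np.sqrt(len(cols))
            s[all_missing] = np.nan
        else:
            s = pd.Series(np.nan, index=block.index)
        means[cond] = m
        ses[cond] = s
        ns[cond] = len(cols)
        partial[cond] = any_missing & ~all_missing

    order = sorted(groups)
    return ConcentrationMatrix(
        values=pd.DataFrame(means)[order],
        kind="condition_mean",
        se=pd.DataFrame(ses)[order],
        n=pd.Series(ns)[order],
        partial_missing=pd.DataFrame(partial)[order],
    )


def to_relative(conc: ConcentrationMatrix) -> RelativeContentMatrix:
    """Peak-area normalization: percent of the per-column detected total."""
    totals = conc.values.sum(axis=0, skipna=True)
    detected = conc.values.notna().any(axis=0)
    bad = [c for c in conc.values.columns if not detected[c] or not totals[c] > 0]
    if bad:
        raise ValueError(f"no detected compounds in sample(s)/condition(s): {bad}")
    return RelativeContentMatrix(values=100.0 * conc.values.div(totals, axis=1))


def round_report(df: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Rounding convention for report output (internal arithmetic stays full precision)."""
    return df.round(decimals)
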