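"""Compound-class composition statistics.

Summarizes a concentration matrix into per-condition totals, class contents
and fractions, detected-species counts, and genotype membership partitions
(shared / pairwise-shared / genotype-unique compounds at a stage).

"Detected" means non-missing and strictly positive after condition-mean
aggregation; the total volatile content of a condition is the sum over its
detected compounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .quantify import ConcentrationMatrix
from .registry_io import CompoundRegistry, CLASS_LABELS, GENOTYPES, parse_condition


@dataclass
class CompositionSummary:
    """Per-condition composition statistics.

    ``totals``: total content (ug/g) per condition; ``class_content`` and
    ``class_fraction``: class x condition content sums and percentages;
    ``species_count``: number of detected compounds; ``detected``: boolean
    compound x condition flags.
    """

    totals: pd.Series
    class_content: pd.DataFrame
    class_fraction: pd.DataFrame
    species_count: pd.Series
    detected: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Flat report table: one row per condition."""
        out = pd.DataFrame({"total_ug_per_g": self.totals, "species_count": self.species_count})
        for cls in self.class_content.index:
            out[f"{cls}_ug_per_g"] = self.class_content.loc[cls]
            out[f"{cls}_pct"] = self.class_fraction.loc[cls]
        return out


def summarize(conc: ConcentrationMatrix, registry: CompoundRegistry) -> CompositionSummary:
    """Totals, class sums/fractions and detection counts per condition."""
    unregistered = registry.unregistered(conc.values.index)
    if unregistered:
        raise KeyError(f"unregistered compound codes: {unregistered}")

    values = conc.values
    detected = values.notna() & (values > 0)
    totals = values.fillna(0.0).sum(axis=0)
    species_count = detected.sum(axis=0)

    classes = pd.Series({code: registry.class_of(code) for code in values.index})
    class_content = (
        values.fillna(0.0).groupby(classes).sum().reindex(list(CLASS_LABELS)).fillna(0.0)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        class_fraction = 100.0 * class_content.div(totals, axis=1)
    class_fraction[totals[totals == 0].index] = np.nan  # empty condition: undefined

    return CompositionSummary(
        totals=totals,
        class_content=class_content,
        class_fraction=class_fraction,
        species_count=species_count,
        detected=detected,
    )


def genotype_ratios(summary: CompositionSummary, reference: str, stage: str) -> pd.DataFrame:
    """Total-content ratios genotype/reference at one stage (whole flowers).

    Returns full-precision ratios plus a 1-decimal report column.
    """
    totals = {}
    for cond, total in summary.totals.items():
        g, s, organ = parse_condition(cond)
        if s == stage and organ == "whole":
            totals[g] = total
    if reference not in totals:
        raise KeyError(f"reference genotype {reference!r} has no total at stage {stage}")
    if not totals[reference] > 0:
        raise ZeroDivisionError(f"reference total for {reference} at {stage} is zero")
    rows = [
        {
            "genotype": g,
            "total_ug_per_g": t,
            "ratio": t / totals[reference],
            "ratio_1dp": round(t / totals[reference], 1),
        }
        for g, t in sorted(totals.items(), key=lambda kv: GENOTYPES.index(kv[0]))
    ]
    return pd.DataFrame(rows).set_index("genotype")


def membership_sets(conc: ConcentrationMatrix, stage: str) -> dict[tuple[str, ...], set[str]]:
    """Partition detected compounds at a stage by the genotype set detecting them.

    Keys are tuples of genotypes in SF/WF/Mr order; every detected compound
    belongs to exactly one cell.
    """
    per_genotype: dict[str, set[str]] = {}
    for cond in conc.values.columns:
        g, s, organ = parse_condition(cond)
        if s != stage or organ != "whole":
            continue
        col = conc.values[cond]
        per_genotype[g] = set(col.index[col.notna() & (col > 0)])
    if len(per_genotype) < 2:
        raise ValueError(f"need >= 2 genotypes at stage {stage} for membership analysis")

    genotypes = [g for g in GENOTYPES if g in per_genotype]
    partition: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(genotypes) + 1):
        for combo in combinations(genotypes, r):
            cell = set.intersection(*(per_genotype[g] for g in combo))
            for g in genotypes:
                if g not in combo:
                    cell -= per_genotype[g]
            partition[combo] = cell
    return partition


def membership_counts(partition: dict[tuple[str, ...], set[str]]) -> pd.DataFrame:
    rows = [
        {"genotypes": "+".join(combo), "n_compounds": len(codes),
         "codes": ",".join(sorted(codes))}
        for combo, codes in sorted(partition.items(), key=lambda kv: (len(kv[0]), kv[0]))
    ]
    return pd.DataFrame(rows)
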