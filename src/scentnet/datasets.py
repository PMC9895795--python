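"""Bundled reference fixtures: the crabapple floral-volatile study tables.

Three small TSVs ship with the package:

* ``compound_registry.tsv`` — the curated compound registry for the three
  genotypes' floral volatiles. Classes are editorial (asterisk-style
  benzene-ring assignments), not inferred from structure. Only the six
  odor thresholds printed in the study's main text are filled (methyl
  benzoate 0.52, leaf acetate 12.10, methyl anthranilate 3.00, benzyl
  alcohol 10000, (E)-3-hexen-1-ol 1550, hexyl alcohol 2500 ng/g in water).
  Methyl octanoate is remapped from the source table's duplicated code v02
  to the free code v67 so codes stay unique.
* ``es_contents.tsv`` — condition-mean volatile contents (ug/g fresh weight,
  mean ± SE of 3 replicates) of SF/WF/Mr whole flowers at the early
  flowering stage.
* ``organ_relative.tsv`` — relative contents (%) in SF petal, stamen,
  pistil, and calyx+bracts at the early flowering stage.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .quantify import ConcentrationMatrix, RelativeContentMatrix
from .registry_io import CompoundRegistry, read_compound_registry


def _data_path(filename: str):
    return resources.files("scentnet.data").joinpath(filename)


def load_registry() -> CompoundRegistry:
    """Curated compound registry with the six main-text odor thresholds."""
    with resources.as_file(_data_path("compound_registry.tsv")) as p:
        return read_compound_registry(p)


def load_es_contents() -> ConcentrationMatrix:
    """Whole-flower ES-stage condition means (ug/g) for SF, WF, and Mr."""
    with resources.as_file(_data_path("es_contents.tsv")) as p:
        long = pd.read_csv(p, sep="\t", dtype={"code": str})
    long["condition"] = long["genotype"] + "_" + long["stage"]
    values = long.pivot(index="code", columns="condition", values="mean_ug_per_g")
    se = long.pivot(index="code", columns="condition", values="se_ug_per_g")
    n = long.groupby("condition")["n"].first()
    order = sorted(values.columns)
    return ConcentrationMatrix(
        values=values[order],
        kind="condition_mean",
        se=se[order],
        n=n[order],
        partial_missing=pd.DataFrame(False, index=values.index, columns=order),
    )


def load_organ_relative() -> tuple[RelativeContentMatrix, pd.DataFrame]:
    """SF floral-organ relative contents (%) and their standard errors."""
    with resources.as_file(_data_path("organ_relative.tsv")) as p:
        long = pd.read_csv(p, sep="\t", dtype={"code": str})
    values = long.pivot(index="code", columns="organ", values="percent")
    se = long.pivot(index="code", columns="organ", values="se")
    order = [c for c in ("petal", "stamen", "pistil", "calyx_bracts") if c in values]
    return RelativeContentMatrix(values=values[order]), se[order]
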