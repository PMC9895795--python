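"""Compound registry and peak-table I/O.

Defines the coordinate and unit conventions used by every downstream
module:

* compounds are identified by short codes (``v01`` ... ``v99``) and carry a
  curated compound class plus an optional odor threshold in ng per gram of
  water;
* samples are identified by ``GENOTYPE_STAGE[_ORGAN]_REP`` strings with
  fixed vocabularies (organ defaults to ``whole``);
* peak tables are wide compound x sample matrices of integrated GC-MS peak
  areas (arbitrary chromatograph units) with one reserved internal-standard
  row and per-sample fresh weight (g) and spiked internal-standard mass (mg).

"Not detected" is an empty cell on disk and ``NaN`` in memory, distinct from
a measured zero.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

CLASS_LABELS = (
    "benzenoid_phenylpropanoid",
    "fatty_acid_derivative",
    "terpenoid",
    "other",
)
GENOTYPES = ("SF", "WF", "Mr")
STAGES = ("EB", "LB", "ES", "LS")
ORGANS = ("whole", "petal", "stamen", "pistil", "calyx_bracts")

#: reserved row label for the internal standard (ethyl decanoate).
IS_CODE = "IS"

#: spiked internal-standard mass per headspace bottle, in mg.
DEFAULT_IS_MASS_MG = 2.59e-5

_CODE_RE = re.compile(r"^v\d{2}$")


class RegistryError(ValueError):
    """Raised for malformed registries or peak tables."""


# ---------------------------------------------------------------------------
# compounds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Compound:
    """One registered volatile.

    ``threshold`` is the odor-detection threshold in ng·g⁻¹ (in water);
    ``threshold_low``/``threshold_high`` optionally give a literature range
    instead of a point value. Missing thresholds are allowed — such
    compounds take part in composition statistics but not in OAV screening.
    """

    name: str
    code: str
    compound_class: str
    threshold: float | None = None
    threshold_low: float | None = None
    threshold_high: float | None = None

    def __post_init__(self) -> None:
        if not _CODE_RE.match(self.code):
            raise RegistryError(f"compound code {self.code!r} does not match v01..v99")
        if self.compound_class not in CLASS_LABELS:
            raise RegistryError(
                f"unknown compound class {self.compound_class!r} for {self.code}; "
                f"expected one of {CLASS_LABELS}"
            )
        for label, value in (
            ("threshold", self.threshold),
            ("threshold_low", self.threshold_low),
            ("threshold_high", self.threshold_high),
        ):
            if value is not None and not value > 0:
                raise RegistryError(f"{label} for {self.code} must be > 0, got {value}")
        if (self.threshold_low is None) != (self.threshold_high is None):
            raise RegistryError(
                f"threshold range for {self.code} needs both low and high bounds"
            )
        if self.threshold_low is not None and self.threshold_low >= self.threshold_high:
            raise RegistryError(f"threshold range for {self.code} must have low < high")

    @property
    def has_threshold(self) -> bool:
        return self.threshold is not None or self.threshold_low is not None


@dataclass
class CompoundRegistry:
    """Validated collection of compounds, unique by code."""

    compounds: dict[str, Compound] = field(default_factory=dict)

    @classmethod
    def from_compounds(cls, compounds: Iterable[Compound]) -> "CompoundRegistry":
        reg = cls()
        for c in compounds:
            reg.add(c)
        return reg

    def add(self, compound: Compound) -> None:
        if compound.code in self.compounds:
            raise RegistryError(f"duplicate compound code {compound.code!r}")
        self.compounds[compound.code] = compound

    def __contains__(self, code: str) -> bool:
        return code in self.compounds

    def __getitem__(self, code: str) -> Compound:
        return self.compounds[code]

    def __len__(self) -> int:
        return len(self.compounds)

    @property
    def codes(self) -> list[str]:
        return sorted(self.compounds)

    def class_of(self, code: str) -> str:
        return self.compounds[code].compound_class

    def unregistered(self, codes: Iterable[str]) -> list[str]:
        """Codes appearing in data but absent from the registry (IS excluded)."""
        return sorted(c for c in set(codes) if c != IS_CODE and c not in self.compounds)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for code in self.codes:
            c = self.compounds[code]
            rows.append(
                {
                    "name": c.name,
                    "code": c.code,
                    "class": c.compound_class,
                    "threshold_ng_per_g": c.threshold,
                    "threshold_low_ng_per_g": c.threshold_low,
                    "threshold_high_ng_per_g": c.threshold_high,
                }
            )
        return pd.DataFrame(rows, columns=[
            "name", "code", "class", "threshold_ng_per_g",
            "threshold_low_ng_per_g", "threshold_high_ng_per_g",
        ])


def _sep_for(path: str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_compound_registry(path) -> CompoundRegistry:
    """Read a registry TSV/CSV with columns name, code, class, threshold_ng_per_g.

    Optional columns ``threshold_low_ng_per_g`` / ``threshold_high_ng_per_g``
    carry literature threshold ranges. Blank thresholds mean "unknown".
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"code": str}, comment=None)
    required = {"name", "code", "class", "threshold_ng_per_g"}
    missing = required - set(df.columns)
    if missing:
        raise RegistryError(f"registry {path} is missing columns {sorted(missing)}")

    def _opt(row, col):
        if col not in df.columns:
            return None
        v = row[col]
        return None if pd.isna(v) else float(v)

    reg = CompoundRegistry()
    for _, row in df.iterrows():
        reg.add(
            Compound(
                name=str(row["name"]).strip(),
                code=str(row["code"]).strip(),
                compound_class=str(row["class"]).strip(),
                threshold=_opt(row, "threshold_ng_per_g"),
                threshold_low=_opt(row, "threshold_low_ng_per_g"),
                threshold_high=_opt(row, "threshold_high_ng_per_g"),
            )
        )
    return reg


def write_compound_registry(registry: CompoundRegistry, path) -> None:
    registry.to_frame().to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# sample keys
# ---------------------------------------------------------------------------


class SampleKey(NamedTuple):
    """Parsed ``GENOTYPE_STAGE[_ORGAN]_REP`` sample identifier."""

    genotype: str
    stage: str
    organ: str
    replicate: int

    @classmethod
    def parse(cls, ident: str) -> "SampleKey":
        tokens = str(ident).split("_")
        if len(tokens) < 3:
            raise RegistryError(f"unparseable sample identifier {ident!r}")
        genotype, stage = tokens[0], tokens[1]
        if genotype not in GENOTYPES:
            raise RegistryError(f"unknown genotype {genotype!r} in sample {ident!r}")
        if stage not in STAGES:
            raise RegistryError(f"unknown stage {stage!r} in sample {ident!r}")
        try:
            replicate = int(tokens[-1])
        except ValueError:
            raise RegistryError(f"replicate token in sample {ident!r} is not an integer")
        if replicate < 1:
            raise RegistryError(f"replicate must be >= 1 in sample {ident!r}")
        organ = "_".join(tokens[2:-1]) or "whole"
        if organ not in ORGANS:
            raise RegistryError(f"unknown organ {organ!r} in sample {ident!r}")
        return cls(genotype, stage, organ, replicate)

    @property
    def condition(self) -> str:
        """Condition key: genotype x stage (x organ when not whole)."""
        if self.organ == "whole":
            return f"{self.genotype}_{self.stage}"
        return f"{self.genotype}_{self.stage}_{self.organ}"

    def __str__(self) -> str:
        return f"{self.condition}_{self.replicate}"


def parse_condition(key: str) -> tuple[str, str, str]:
    """Split a condition key into (genotype, stage, organ)."""
    tokens = key.split("_")
    if len(tokens) < 2 or tokens[0] not in GENOTYPES or tokens[1] not in STAGES:
        raise RegistryError(f"unparseable condition key {key!r}")
    organ = "_".join(tokens[2:]) or "whole"
    if organ not in ORGANS:
        raise RegistryError(f"unknown organ {organ!r} in condition {key!r}")
    return tokens[0], tokens[1], organ


# ---------------------------------------------------------------------------
# peak tables
# ---------------------------------------------------------------------------


@dataclass
class PeakTable:
    """Raw integrated peak areas, compound x sample.

    ``areas`` holds one row per compound code plus the reserved ``IS`` row;
    NaN means "not detected". ``fresh_weight`` (g) and ``is_mass`` (mg) are
    per-sample metadata indexed like the columns.
    """

    areas: pd.DataFrame
    fresh_weight: pd.Series
    is_mass: pd.Series

    def __post_init__(self) -> None:
        self.areas = self.areas.astype(float)
        self.fresh_weight = self.fresh_weight.astype(float)
        self.is_mass = self.is_mass.astype(float)
        self.validate()

    def validate(self) -> None:
        cols = list(self.areas.columns)
        bad = [c for c in cols if not _is_sample_id(c)]
        if bad:
            raise RegistryError(f"unparseable sample identifier column(s): {bad}")
        keys = [SampleKey.parse(c) for c in cols]
        if len(set(keys)) != len(keys):
            raise RegistryError("duplicate sample keys in peak table")
        if self.areas.index.duplicated().any():
            dups = sorted(self.areas.index[self.areas.index.duplicated()])
            raise RegistryError(f"duplicate compound rows in peak table: {dups}")
        if IS_CODE not in self.areas.index:
            raise RegistryError("peak table is missing the internal-standard (IS) row")
        is_row = self.areas.loc[IS_CODE]
        bad_is = [c for c in cols if not (pd.notna(is_row[c]) and is_row[c] > 0)]
        if bad_is:
            raise RegistryError(
                f"internal-standard area missing or non-positive for sample(s): {bad_is}"
            )
        if (self.areas < 0).any().any():
            raise RegistryError("negative peak areas are not allowed")
        for label, series, cond in (
            ("fresh_weight", self.fresh_weight, lambda v: v > 0),
            ("is_mass", self.is_mass, lambda v: v > 0),
        ):
            missing = [c for c in cols if c not in series.index]
            if missing:
                raise RegistryError(f"{label} missing for sample(s): {missing}")
            bad_v = [c for c in cols if not cond(series[c])]
            if bad_v:
                raise RegistryError(f"{label} must be positive for sample(s): {bad_v}")

    @property
    def samples(self) -> list[SampleKey]:
        return [SampleKey.parse(c) for c in self.areas.columns]

    @property
    def codes(self) -> list[str]:
        return [c for c in self.areas.index if c != IS_CODE]


def _is_sample_id(ident: str) -> bool:
    try:
        SampleKey.parse(ident)
        return True
    except RegistryError:
        return False


def read_peak_table(path) -> PeakTable:
    """Read a wide peak-area table.

    Format: optional ``#fresh_weight_g=`` and ``#is_mass_mg=`` metadata lines
    (tab-aligned with the sample columns), then a header line starting with
    ``code`` and one row per compound. Empty cells mean "not detected".
    """
    sep = _sep_for(path)
    meta: dict[str, list[str]] = {}
    body_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, rest = line[1:].partition("=")
                meta[key.strip()] = rest.lstrip(sep).split(sep)
            elif line:
                body_lines.append(line)
    if not body_lines:
        raise RegistryError(f"peak table {path} has no data rows")
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    cols = list(df.columns)
    if "fresh_weight_g" not in meta or "is_mass_mg" not in meta:
        raise RegistryError(
            f"peak table {path} is missing #fresh_weight_g= / #is_mass_mg= metadata"
        )
    for key in ("fresh_weight_g", "is_mass_mg"):
        if len(meta[key]) != len(cols):
            raise RegistryError(
                f"metadata line {key} has {len(meta[key])} values for {len(cols)} samples"
            )
    fw = pd.Series([float(v) for v in meta["fresh_weight_g"]], index=cols)
    ism = pd.Series([float(v) for v in meta["is_mass_mg"]], index=cols)
    return PeakTable(areas=df, fresh_weight=fw, is_mass=ism)


def write_peak_table(table: PeakTable, path) -> None:
    sep = _sep_for(path)
    cols = list(table.areas.columns)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#fresh_weight_g=" + sep + sep.join(repr(float(table.fresh_weight[c])) for c in cols) + "\n")
        fh.write("#is_mass_mg=" + sep + sep.join(repr(float(table.is_mass[c])) for c in cols) + "\n")
        fh.write("code" + sep + sep.join(cols) + "\n")
        for code, row in table.areas.iterrows():
            cells = ["" if pd.isna(v) else repr(float(v)) for v in row.values]
            fh.write(str(code) + sep + sep.join(cells) + "\n")


def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    """Write a generic node x column matrix as TSV (NaN as empty cell)."""
    df.to_csv(path, sep=_sep_for(path), index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    return df
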