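"""Synthetic floral-volatile and expression data with known ground truth.

The generator emulates the statistical structure the pipeline assumes: three
genotypes (SF strongly fragrant, WF weakly fragrant, Mr standard) by four
floral stages (EB, LB, ES, LS) by three biological replicates of volatile
profiles over ~56 compounds in the field's three dominant classes, plus
FPKM matrices at three stages (EB, ES, LS; two replicates) with planted
gene-volatile correlations.

Study conditions baked into the defaults: per-compound true concentrations
are drawn log-normally within class ranges spanning roughly 4-700 ug/g; a
stage profile peaking at ES (EB < LB < ES > LS) scales each genotype; the
SF total at ES is anchored at 4563.15 ug/g with SF:WF = 2.7 and SF:Mr = 3.0
(per-genotype rescaling makes the true totals hit the targets exactly);
some compounds are genotype-unique (zero, hence below the detection floor,
elsewhere). Replicate areas invert the internal-standard quantification
formula exactly, times multiplicative log-normal noise with coefficient of
variation ``noise_cv`` — so with ``noise_cv=0`` the full pipeline returns
the configured truths to floating-point precision.

Expression is simulated at condition-mean level first (replicate noise is
added after), so the network module's condition-averaging convention is
directly testable: each planted gene's condition-mean FPKM is an affine
function of its paired volatile's condition-mean concentration plus Gaussian
noise tuned so the expected condition-level Pearson correlation equals
``true_pcc``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .registry_io import (
    CLASS_LABELS,
    IS_CODE,
    Compound,
    CompoundRegistry,
    PeakTable,
)

#: class-specific true-concentration ranges (ug/g) before rescaling
CLASS_CONC_RANGES = {
    "benzenoid_phenylpropanoid": (10.0, 700.0),
    "fatty_acid_derivative": (5.0, 400.0),
    "terpenoid": (5.0, 250.0),
    "other": (4.0, 100.0),
}

DEFAULT_CLASS_MIXTURE = {
    "benzenoid_phenylpropanoid": 0.35,
    "fatty_acid_derivative": 0.35,
    "terpenoid": 0.20,
    "other": 0.10,
}


@dataclass
class SimConfig:
    """Generator configuration; the seed fully determines all outputs."""

    n_compounds: int = 56
    class_mixture: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE))
    n_genes: int = 2000
    n_planted_pairs: int = 20
    true_pcc: float = 0.95
    noise_cv: float = 0.1
    expr_noise_cv: float = 0.1
    seed: int = 0
    genotypes: tuple = ("SF", "WF", "Mr")
    stages: tuple = ("EB", "LB", "ES", "LS")
    n_reps_volatile: int = 3
    expr_stages: tuple = ("EB", "ES", "LS")
    n_reps_expr: int = 2
    detection_floor: float = 1.0  # ug/g; lower measured values are "not detected"
    is_mass_mg: float = 2.59e-5
    total_es_sf: float = 4563.15  # ug/g anchor for the SF total at ES
    sf_to_wf_ratio: float = 2.7
    sf_to_mr_ratio: float = 3.0
    stage_profile: tuple = (0.35, 0.6, 1.0, 0.75)  # EB, LB, ES, LS multipliers
    jitter_sdlog: float = 0.6  # per compound x condition log-normal spread
    n_unique: tuple = (6, 6, 12)  # genotype-unique compounds per SF, WF, Mr
    threshold_fraction: float = 0.7  # share of compounds with a known odor threshold
    base_fpkm: float = 20.0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mixture.values()) - 1.0) > 1e-12:
            raise ValueError("class_mixture probabilities must sum to 1")
        if set(self.class_mixture) - set(CLASS_LABELS):
            raise ValueError(f"class_mixture keys must be among {CLASS_LABELS}")
        if self.n_planted_pairs > min(self.n_genes, self.n_compounds):
            raise ValueError("n_planted_pairs must be <= min(n_genes, n_compounds)")
        if not 0 < self.true_pcc <= 1:
            raise ValueError("true_pcc must lie in (0, 1]")
        if self.n_compounds > 99:
            raise ValueError("compound codes only span v01..v99")
        if sum(self.n_unique) > self.n_compounds:
            raise ValueError("more genotype-unique compounds than compounds")


@dataclass
class GroundTruth:
    """Recorded truths: per-condition concentrations, detection, planted pairs."""

    true_conc: pd.DataFrame  # compound x condition (GENOTYPE_STAGE), ug/g
    detected: pd.DataFrame  # compound x condition, true concentration >= floor
    class_assignment: pd.Series
    totals: pd.Series  # per condition
    planted_pairs: list = field(default_factory=list)  # (gene_id, code, signed r)

    def save(self, path) -> None:
        payload = {
            "true_conc": {c: self.true_conc[c].round(10).to_dict() for c in self.true_conc},
            "detected": {c: self.detected[c].to_dict() for c in self.detected},
            "class_assignment": self.class_assignment.to_dict(),
            "totals": self.totals.to_dict(),
            "planted_pairs": [
                {"gene": g, "code": c, "true_pcc": r} for g, c, r in self.planted_pairs
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-sigma * sigma / 2.0, sigma, size))


def simulate_volatiles(config: SimConfig) -> tuple[PeakTable, CompoundRegistry, GroundTruth]:
    """Generate a replicate-level peak table plus registry and ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_compounds
    codes = [f"v{i + 1:02d}" for i in range(n)]
    mixture = np.array([config.class_mixture.get(c, 0.0) for c in CLASS_LABELS])
    classes = rng.choice(CLASS_LABELS, size=n, p=mixture)

    has_thr = rng.random(n) < config.threshold_fraction
    thresholds = 10.0 ** rng.uniform(np.log10(0.5), np.log10(5000.0), n)

    lo = np.array([CLASS_CONC_RANGES[c][0] for c in classes])
    hi = np.array([CLASS_CONC_RANGES[c][1] for c in classes])
    base = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi))

    # genotype-unique compounds: zero concentration outside the host genotype
    uniq_idx = rng.choice(n, size=sum(config.n_unique), replace=False)
    host = np.full(n, "", dtype=object)
    offset = 0
    for g, count in zip(config.genotypes, config.n_unique):
        host[uniq_idx[offset:offset + count]] = g
        offset += count

    stage_mult = dict(zip(config.stages, config.stage_profile))
    n_geno, n_stage = len(config.genotypes), len(config.stages)
    jitter = np.exp(rng.normal(0.0, config.jitter_sdlog, size=(n, n_geno, n_stage)))

    raw = np.empty((n, n_geno, n_stage))
    for gi, g in enumerate(config.genotypes):
        for si, s in enumerate(config.stages):
            raw[:, gi, si] = base * stage_mult[s] * jitter[:, gi, si]
            raw[host != "", gi, si] = np.where(
                host[host != ""] == g, raw[host != "", gi, si], 0.0
            )

    # anchor per-genotype ES totals so the true genotype ratios are exact
    es_i = config.stages.index("ES")
    targets = [
        config.total_es_sf,
        config.total_es_sf / config.sf_to_wf_ratio,
        config.total_es_sf / config.sf_to_mr_ratio,
    ]
    for gi in range(n_geno):
        raw[:, gi, :] *= targets[gi] / raw[:, gi, es_i].sum()

    conditions = [f"{g}_{s}" for g in config.genotypes for s in config.stages]
    true_conc = pd.DataFrame(
        raw.reshape(n, n_geno * n_stage), index=codes, columns=conditions
    )
    detected = true_conc >= config.detection_floor
    totals = true_conc.where(detected, 0.0).sum(axis=0)

    registry = CompoundRegistry.from_compounds(
        Compound(
            name=f"synthetic volatile {code}",
            code=code,
            compound_class=cls,
            threshold=float(thr) if ht else None,
        )
        for code, cls, thr, ht in zip(codes, classes, thresholds, has_thr)
    )

    # replicate-level areas inverting the IS quantification formula
    sample_cols, fw_list, isa_list, area_cols = [], [], [], []
    for gi, g in enumerate(config.genotypes):
        for si, s in enumerate(config.stages):
            for r in range(1, config.n_reps_volatile + 1):
                fw = rng.uniform(0.8, 1.2)
                isa = 1e6 * math.exp(rng.normal(0.0, 0.05))
                noise = _lognormal_noise(rng, config.noise_cv, n)
                measured = raw[:, gi, si] * noise
                area = np.where(
                    measured >= config.detection_floor,
                    measured * fw / (config.is_mass_mg * 1000.0) * isa,
                    np.nan,
                )
                sample_cols.append(f"{g}_{s}_{r}")
                fw_list.append(fw)
                isa_list.append(isa)
                area_cols.append(area)

    areas = pd.DataFrame(
        np.column_stack(area_cols), index=codes, columns=sample_cols
    )
    areas.loc[IS_CODE] = np.asarray(isa_list)
    peaks = PeakTable(
        areas=areas,
        fresh_weight=pd.Series(fw_list, index=sample_cols),
        is_mass=pd.Series(config.is_mass_mg, index=sample_cols),
    )
    truth = GroundTruth(
        true_conc=true_conc,
        detected=detected,
        class_assignment=pd.Series(classes, index=codes),
        totals=totals,
    )
    return peaks, registry, truth


def simulate_expression(
    config: SimConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a replicate-level FPKM matrix and a DE summary table.

    Fills ``truth.planted_pairs`` with the (gene, volatile, signed r) triples.
    Background genes are i.i.d. log-normal across the genotype x stage
    conditions; planted genes track their paired volatile's condition-mean
    concentration.
    """
    rng = np.random.default_rng([config.seed, 7919])
    conds = [f"{g}_{s}" for g in config.genotypes for s in config.expr_stages]
    n_cond = len(conds)
    gene_ids = [f"HF{i + 1:05d}" for i in range(config.n_genes)]

    means = np.exp(
        rng.normal(math.log(config.base_fpkm), 1.0, size=(config.n_genes, n_cond))
    )

    # plant on volatiles detected in every expression condition; when the
    # detection floor leaves too few, fall back to the next most reliably
    # detected compounds (highest minimum true concentration)
    variable = [
        c for c in truth.true_conc.index if truth.true_conc.loc[c, conds].std() > 0
    ]
    eligible = [c for c in variable if truth.detected.loc[c, conds].all()]
    if len(eligible) < config.n_planted_pairs:
        rest = sorted(
            (c for c in variable if c not in eligible),
            key=lambda c: -truth.true_conc.loc[c, conds].min(),
        )
        eligible = eligible + rest[: config.n_planted_pairs - len(eligible)]
    if len(eligible) < config.n_planted_pairs:
        raise ValueError(
            f"only {len(eligible)} volatiles vary across the expression "
            f"conditions; cannot plant {config.n_planted_pairs} pairs"
        )
    planted_codes = rng.choice(eligible, size=config.n_planted_pairs, replace=False)
    planted_gene_idx = rng.choice(
        config.n_genes, size=config.n_planted_pairs, replace=False
    )
    signs = rng.choice([-1.0, 1.0], size=config.n_planted_pairs)

    rho = config.true_pcc
    truth.planted_pairs = []
    for code, gi, sign in zip(planted_codes, planted_gene_idx, signs):
        v = truth.true_conc.loc[code, conds].to_numpy()
        z = (v - v.mean()) / v.std()
        e = rng.standard_normal(n_cond)
        g_std = sign * rho * z + math.sqrt(1.0 - rho * rho) * e
        b = config.base_fpkm
        a = b * (max(0.0, -g_std.min()) + 0.5)
        means[gi] = a + b * g_std
        truth.planted_pairs.append((gene_ids[gi], str(code), float(sign * rho)))

    sample_cols, blocks = [], []
    for ci, cond in enumerate(conds):
        for r in range(1, config.n_reps_expr + 1):
            noise = _lognormal_noise(rng, config.expr_noise_cv, config.n_genes)
            blocks.append(means[:, ci] * noise)
            sample_cols.append(f"{cond}_{r}")
    fpkm = pd.DataFrame(np.column_stack(blocks), index=gene_ids, columns=sample_cols)

    deg_table = _deg_table_from_fpkm(fpkm, config)
    return fpkm, deg_table


def _deg_table_from_fpkm(fpkm: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Per-comparison log2 fold changes and raw Welch-t p-values on log scale."""
    cols_of = {
        f"{g}_{s}": [f"{g}_{s}_{r}" for r in range(1, config.n_reps_expr + 1)]
        for g in config.genotypes
        for s in config.expr_stages
    }
    comparisons = []
    for g in config.genotypes:
        pairs = list(zip(config.expr_stages[1:], config.expr_stages[:-1]))
        for s_num, s_den in pairs:
            comparisons.append((f"{g}_{s_num}_vs_{g}_{s_den}", f"{g}_{s_num}", f"{g}_{s_den}"))
    ref = config.genotypes[0]
    for other in config.genotypes[1:]:
        for s in config.expr_stages:
            comparisons.append((f"{ref}_{s}_vs_{other}_{s}", f"{ref}_{s}", f"{other}_{s}"))

    eps = 0.1
    rows = []
    for name, num, den in comparisons:
        x = np.log2(fpkm[cols_of[num]].to_numpy() + eps)
        y = np.log2(fpkm[cols_of[den]].to_numpy() + eps)
        log2fc = x.mean(axis=1) - y.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(x, y, axis=1, equal_var=False)
            p = np.asarray(res.pvalue, dtype=float)
        # degenerate zero-variance replicates (noiseless runs)
        degen = ~np.isfinite(p)
        p[degen & (log2fc != 0)] = 0.0
        p[degen & (log2fc == 0)] = 1.0
        rows.append(
            pd.DataFrame(
                {
                    "gene": fpkm.index,
                    "comparison": name,
                    "log2fc": log2fc,
                    "pvalue": p,
                    "padj": np.nan,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def config_to_json(config: SimConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True, default=list)
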