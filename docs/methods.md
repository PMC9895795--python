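# Methods

## Internal-standard quantification

Contents are computed by single-point internal-standard semi-quantification:
`content_i = (area_i / area_IS) · m_IS · 1000 / FW`, in µg per g fresh weight,
with the spiked ethyl-decanoate mass `m_IS` in mg (default 2.59×10⁻⁵ mg,
exposed as an input rather than hard-coded) and the fresh weight `FW` in g.
Response factors are assumed 1.0 for every analyte — no compound-specific
calibration curves are modelled, so contents are comparable across samples
but are semi-quantitative in the absolute sense. The IS mass is the final
spiked amount; dilution-series screening during method development is not
modelled.

"Not detected" is an empty cell on disk and `NaN` in memory, distinct from a
measured zero. In replicate averaging a compound missing in *some* replicates
is treated as 0 in the mean and SE but flagged (`partial_missing`); a
compound missing in *all* replicates stays missing. SE = sd/√n with ddof 1;
a single replicate has no SE. Detection, used for species counts and
membership partitions, means non-missing and strictly positive after
condition-mean aggregation.

Report rounding is 2 decimals for contents and percentages and scientific
notation at 3 significant figures for OAV ≥ 10⁴; internal arithmetic is full
precision.

## Composition statistics

The total volatile content of a condition is the sum over its detected
compounds; class contents and fractions follow from a curated registry
column, not from structure. Two curation notes: 3-aminophenylacetylene is
classed benzenoid/phenylpropanoid (it carries an aromatic ring, and the
organ-level class fractions are only self-consistent under that assignment),
and pentanoic acid keeps its editorial benzene-ring-type assignment from the
source tables. Stage-trend statements (EB < LB < ES > LS) are report
annotations, not hard checks, because the standard species plateaus between
ES and LS.

One source-table quirk: the fixture remaps methyl octanoate from a
duplicated code to the free code v67 so registry codes stay unique.

## OAV screening

OAV = content × 1000 / threshold converts µg·g⁻¹ contents against ng·g⁻¹
thresholds (in water). The key rule is strict (OAV > 1.0); tier cuts are
OAV > 5000 ("high") and OAV > 30000 ("predominant"). The shipped registry
carries only the six thresholds printed in the study's main text (methyl
benzoate 0.52, leaf acetate 12.10, methyl anthranilate 3.00, benzyl alcohol
10000, (E)-3-hexen-1-ol 1550, hexyl alcohol 2500 ng·g⁻¹); other thresholds
exist only in supplementary material and are not asserted, although
back-calculation (e.g. linalool ≈ 6 ng·g⁻¹) reproduces the published OAVs
and is exercised in tests with explicitly synthetic registries. Compounds
whose literature threshold is a range get an OAV interval; key/tier calls
then use the conservative lower bound. Compounds without thresholds are
reported with tier `no-threshold`, never dropped. Key lists sort by OAV
descending with ties broken by compound code ascending, so output is
deterministic.

## DEG screening

The screen is exactly |log2FC| > 0 and adjusted p < 0.05, both strict, on DE
summary tables computed upstream — the negative-binomial count model itself
is out of scope. When a table carries only raw p-values, Benjamini–Hochberg
adjustment is applied per comparison (delegating to
`statsmodels.stats.multitest`; an O(m²) definitional implementation serves
as the test oracle). Fold-change orientation is log2(A/B) with A and B named
in the comparison string, e.g. `SF_ES_vs_WF_ES`.

## Network inference

Profiles are condition means — replicates are averaged first — because
volatile and RNA replicates are not paired specimens; with three genotypes
and three shared stages this gives n = 9 points per profile. The late
balloon stage, present only in the volatile data, drops out of the
correlation input. Pearson p-values are two-sided from the t transform with
n−2 df and are used raw (an optional BH mode reuses the DEG module);
constant profiles yield an undefined-correlation marker and are excluded
from ranking.

Mutual ranks are computed in a global ranking universe by default: every
node (gene or volatile) is ranked among all other nodes by |r| with average
ranks for ties, so strong negative correlations rank highly and the edge
carries the sign. A `bipartite` switch restricts each node's candidate list
to the opposite class, which removes volatile–volatile edges. Gene–gene
pairs always contribute to the ranking universe but are never emitted as
edges. Edge filters are inclusive: |r| ≥ 0.7, p ≤ 0.05, MR ≤ 10. In the
pipeline orchestration, genes entering the network are restricted to
screened DEGs.

Numerically, ranks use a double argsort (O(N² log N) over the node set) with
exact tie-averaging applied only to rows that contain ties; this matches
`scipy.stats.rankdata(method="average")` exactly while keeping a
2000-gene network build near one second.

## Synthetic data generator

The generator emulates the study design: 3 genotypes × 4 stages × 3
replicates of volatile profiles over 56 compounds, and 3 genotypes × 3
stages × 2 replicates of FPKM over 2000 genes, all driven by a single seed.

Volatiles: per-compound base concentrations are drawn log-uniformly within
class-specific ranges spanning ~4–700 µg·g⁻¹; a stage profile multiplies
them (EB 0.35, LB 0.6, ES 1.0, LS 0.75); per compound × condition
log-normal jitter (σ_log = 0.6) decorrelates compound profiles so that the
network's ranking statistics are non-trivial. Six, six and twelve compounds
are unique to SF, WF and Mr respectively (zero elsewhere), mirroring the
observed membership pattern. Each genotype is rescaled so its true ES total
hits the anchored targets — SF 4563.15 µg·g⁻¹ with SF:WF = 2.7 and
SF:Mr = 3.0 — making the true ratios exact by construction. Replicate peak
areas invert the quantification formula exactly (fresh weight ~ U(0.8, 1.2) g,
IS area log-normal around 10⁶ arbitrary units) times multiplicative
log-normal noise with mean 1 and CV `noise_cv` (default 0.1): areas are
positive and heteroscedastic, like chromatographic integrals. Measured
concentrations below the detection floor (default 1 µg·g⁻¹) are written as
missing. With `noise_cv = 0` the pipeline returns the configured truths to
full floating-point precision (asserted at rtol 1e−12).

Expression: background genes are i.i.d. log-normal (σ_log = 1.0 around 20
FPKM) across the nine conditions. Each planted gene's condition-mean profile
is an affine function of its volatile's standardized true profile plus
orthogonal Gaussian noise scaled so the expected condition-level Pearson
correlation equals `true_pcc` (default 0.95, random sign); affine mapping
back to a positive FPKM scale preserves the correlation exactly. Replicate
noise (CV 0.1) is added afterwards, so condition averaging is itself under
test. The DE table carries log2 fold changes of replicate means and Welch-t
p-values on log2(FPKM + 0.1) for stage contrasts within genotypes and
genotype contrasts per stage.

What the generator does **not** emulate: compositional correlations induced
by shared biosynthetic pathways, count-based mean–variance structure of
RNA-seq (FPKM is simulated directly), batch effects, or missingness that is
informative beyond a hard detection floor. Passing tests therefore
demonstrate correctness of the arithmetic and the statistical behaviour of
the filters under the stated model, not performance on any particular real
dataset.

## Problem sizes and tolerances

Simulation-based checks use 2000 genes, 56 compounds, 20 planted pairs and
100 generator seeds (50 in the acceptance script), which keeps the full
suite under two minutes of simulation time while leaving binomial noise on
the recovery rate well below the margin to the 80%/1% bounds. Fixture
arithmetic is asserted at the printed precision of the source tables
(absolute 0.005–0.05 on 2-decimal values, 0.5% relative on 3-significant-
figure OAVs); two published numbers that disagree with their own table
arithmetic by one unit in the last digit (the WF total and the WF methyl
benzoate OAV) are asserted at the slightly wider tolerances noted in the
tests. Degenerate inputs (all-missing samples, constant profiles, zero
reference totals, absent guide codes) raise errors naming the offending
record.
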