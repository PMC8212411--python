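# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical conventions a reimplementer would need.

## Synthetic data model

`SimulationTruth` fully parameterises one experiment; generation is a pure
function of it (identical truth, including seed, gives bit-identical
output). Sub-streams for each condition and for the secretome are derived
from the master seed with fixed `SeedSequence` spawn keys, so
sub-experiments are independently reproducible.

**Cell types and markers.** Ten murine HSPC compartment labels by default
(LT-HSC, ST-HSC, MPP, MLP, CLP, CMP, GMP, MDP, CDP, MEP). Each type owns a
disjoint block of `markers_per_type = 30` marker genes expressed at
`marker_fold = 8` times the baseline rate; all other non-special genes sit
at the common baseline. Real reference compendia distinguish types through
graded, overlapping programs; disjoint block markers are a deliberately
clean idealisation, which is why annotation accuracy on synthetic data
(~100%) is an upper bound, not a field estimate.

**Counts.** Per cell: a type drawn from the condition's composition
vector, a library size drawn log-normally around `library_size_mean = 5000`
(σ = 0.3), and gene counts drawn negative-binomially around
`library × relative rate` with gene-independent dispersion
`dropout_dispersion = 0.3` (variance μ + 0.3 μ²; Poisson exactly at 0, used
by the exactness tests). The NB is the standard overdispersed noise model
for UMI/plate scRNA-seq counts; no batch effects, doublets, cell-cycle or
UMI chemistry are modelled.

**Mitochondrial content.** Ten `mt-` genes receive a per-cell expression
fraction drawn from a Beta with mean 0.02 and concentration 60, so a
realistic few percent of cells exceed the 5% QC threshold and the filter is
actually exercised.

**Receptor genes.** The receptor genes of the ligand–receptor table are
present in every type at 10× baseline. Receptors must be detectable for
the detection gate (≥ 10% of cells) to be meaningful, and the fold-change
definition below shrinks folds of weakly expressed genes toward 1: at
CP10K mean ≈ 40 a planted 1.21× effect is measured as ≈ 1.20, whereas at
baseline expression it would be damped to ≈ 1.17.

**Planted truth.** Three effects are planted: a composition shift (MDP
10% → 25% and GMP 20% → 10% between the low and high conditions by
default), a receptor up-regulation (`receptor_fold = 1.21` on Il6ra,
applied only to MDP cells in the high condition), and a secretome ratio
(`ligand_ratio = 2.5` on IL-6; all other factors centered on ratio 1, all
with multiplicative log-normal noise, σ = 0.1).

## QC and normalization

Filters run once, in a fixed order, with no iteration to a fixpoint:
(1) non-coding genes (only when an explicit list is supplied — there is no
defensible built-in list); (2) cells with fewer than 1000 detected genes
(strict "less than"); (3) genes detected in fewer than 3 surviving cells;
(4) cells with mitochondrial count fraction above 5%. Order matters —
gene filtering is computed on the cells that survive step 2 — and the
chosen order is the one the idempotence test pins down. Mitochondrial
fraction means counts-fraction, the standard QC reading; genes are
recognised by the `mt-` prefix unless a list is given.

Normalization is natural-log CP10K: `log(1 + c/total × 10⁴)`. Variable
genes are ranked by binned standardized dispersion: dispersion = var/mean
of the de-logged values, genes placed in 20 equal-count bins of log-mean,
log-dispersion z-scored within each bin, ties broken by gene id. This
keeps the selection deterministic and dependency-free; it shares a known
limitation of all mean-binned dispersion statistics — when a bin is
composed almost entirely of marker genes they compete against each other —
which is why the marker-recovery test asserts markers clear the flat
background (top half) rather than an arbitrary tight cut.

## Annotation

Each cell's expression over the scoring genes (variable genes ∩ reference
genes; at least 20 required) is Spearman-correlated (midranks for ties)
against each reference profile; the best-scoring type wins, with ties
broken by lexicographic type order. Confidence: the top score is converted
to a robust z against the other types' scores,
`T = ((max − median(others)) / (1.4826 · MAD(others)))²`, and compared to
the χ²₁ upper tail; cells with `p ≥ 0.05` are pruned. When the MAD of the
other scores is 0, their standard deviation is used; if that is also 0
while the top score still separates from the rest, the dispersion is
floored at 10⁻¹² (so genuine separation over a degenerate background gives
p ≈ 0); with no separation at all T = 0 and p = 1. With only two reference
types there is no peer dispersion to test against, so p is set to 1 and the
cell pruned.

This is a single-profile-per-type simplification of fine-tuning
correlation annotators: no iterative re-scoring over shrinking candidate
sets, no per-type quantile aggregation over replicate reference samples.
The downstream statistics need labels, not a particular third-party
implementation; the planted-truth accuracy test (≥ 95%) gates the
simplification. On real data with closely related progenitor types the
simplification will prune more aggressively — this is the first place to
look if published per-type numbers do not reproduce.

## BCa proportion test

For each type, the membership indicator of every unpruned cell is the
resampling unit. Both conditions are resampled independently with
replacement (B = 10,000 by default; B ≥ 1000 enforced);
θ = mean(high) − mean(low). For 0/1 vectors the bootstrap mean is drawn
directly as Binomial(n, p̂)/n — exactly the resampling distribution,
without materialising B×n index arrays; non-binary inputs fall back to
index resampling. Bias correction `z0 = Φ⁻¹((#{θ* < θ̂} + ½#{θ* = θ̂})/B)`
(half-counting ties, which are common for discrete proportions; the
fraction is clipped to [0.5/B, 1 − 0.5/B]). Acceleration from the pooled
delete-one jackknife: `a = Σd³ / (6 (Σd²)^{3/2})`. Interval endpoints are
BCa-adjusted percentiles of the sorted θ*, with linear interpolation
between order statistics; when the adjustment denominator 1 − a(z0+z) is
non-positive the percentile saturates at 0 or 1.

The one-sided p-value is the smallest α′ at which the one-sided BCa bound
excludes 0, found by bisection over [1/B, 0.5] to tolerance 10⁻⁴; when even
α′ = 0.5 does not exclude 0 the p-value is reported as 1. A degenerate
bootstrap (all replicates identical) is flagged, with p = 1/B when the
observed effect has the tested sign and 1 otherwise. Forcing z0 = a = 0
reduces the interval exactly to the percentile bootstrap (regression-tested).
Measured operating characteristics at the study's scale (n = 300/condition,
p = 0.15 null, B = 2000): one-sided size ≈ 0.04 at α = 0.05 over 500
simulations; power ≈ 1.0 against 0.10 vs 0.25. Types are tested marginally,
mirroring per-population reporting; no cross-type multiplicity correction
is applied by default.

## Differential expression and axis ranking

Within one annotated type, genes are pre-filtered **before** testing:
detection ≥ 10% of cells in either condition, and fold-change ≥ 1.2 in
either direction. Fold-change is computed on de-logged normalized means
with pseudocount 1: `FC = (mean(expm1 x_high) + 1) / (mean(expm1 x_low) + 1)`
— the convention of the mainstream single-cell toolchain; the pseudocount
guards empty denominators and shrinks folds of barely expressed genes
toward 1. The alternative (difference of log-means) is deliberately not
the default. Surviving genes get a two-sided Wilcoxon rank-sum p (exact
enumeration of all rank splits when n ≤ 12 without ties; otherwise normal
approximation with tie-corrected variance and a 0.5 continuity correction),
and Benjamini–Hochberg runs over the tested genes only. Both choices —
filter-then-test, BH over survivors — change the significant-gene count
and are fixed by tests.

Axes are emitted for (ligand, receptor, cell type) where the ligand's
densitometry ratio strictly exceeds 1, the pair is in the ligand–receptor
table (receptor symbols matched case-insensitively; the table is the only
place ligand labels map to gene symbols — no string heuristics), and the
receptor is up (fold > 1) with adjusted p < 0.05 in that type. Ranking is
lexicographic over the three reported keys — descending ligand ratio,
descending receptor fold, ascending adjusted p — rather than a composite
score; with one planted axis and a quiet background the two coincide, and
the lexicographic rule is reproducible without a weighting choice.

## Validation studies and problem sizes

`benchmarks.py` fixes the simulation studies' shapes: BCa size/power at
n = 300 per condition with B = 2000 (500 and 200 simulations); end-to-end
axis recovery on a uniform composition of 10 types × 300 cells per type
per condition (receptor fold 1.5, ligand ratio 2.5; 50 replicate
experiments), where the planted axis ranks first in ~100% of runs and,
with all planted effects set to 1, any axis at all is emitted in ≤ 4% of
runs; annotation accuracy on the default 400 + 400-cell cohort; and the
planted 1.21× receptor fold recovered as a geometric mean over 10
replicates (~1800 target cells in total) because a single replicate has
sampling sd ≈ 0.07 on this quantity.

What passing these studies does **not** show: robustness to overlapping
marker programs, batch structure, ambient contamination, or reference
mismatch — none of which the generator emulates. The planted-truth tests
validate the statistics' wiring and calibration, not the biology-facing
difficulty of real annotation.

## Degenerate inputs and conventions

Zero-total cells are a normalization error (they cannot survive the
detected-genes filter in any realistic configuration). Constant cells have
undefined Spearman correlation and are pruned, not fatal. Empty
ligand–receptor tables and empty gate intersections yield valid empty
rankings with logged per-gate diagnostics. All result tables are TSV with
header rows, `.` for missing values, LF endings; matrices travel as Matrix
Market triplets with `genes.tsv`/`barcodes.tsv`/`cells.tsv` sidecars;
whole-number float counts (`2.0`) are accepted on read, fractional counts
rejected. Reruns with the same configuration are byte-identical, and the
JSON manifest records parameters, seeds and per-stage row counts
sufficient to re-execute a run.
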