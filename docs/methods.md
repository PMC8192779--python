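# Methods

## Cohort model and preprocessing

The pipeline operates on log2-scale expression matrices (genes × samples)
with samples labelled `normal`, `early` or `advanced`. When probe-level
input is supplied, probes mapping to no gene or ambiguously to several
genes are discarded, and each gene's value is the arithmetic mean of its
surviving probes taken directly on the log2 scale (the matrix is assumed
to be normalised and log-transformed upstream; within-array normalisation
such as RMA is out of scope). Missing values are rejected rather than
imputed: every downstream correlation and t-statistic assumes complete
vectors, and microarray matrices of this kind are complete in practice.

## Differential expression and signatures

Each gene is tested in three pairwise stage contrasts with the
pooled-variance two-sample Student t-test (df = n₁ + n₂ − 2, two-sided p).
The equal-variance form was chosen over Welch deliberately: with groups of
6–9 samples the pooled test is the conventional choice and the one the
surrounding literature reports. No multiple-testing correction is applied
to DEG calling (α = 0.01 per contrast); the small cohort sizes this
workflow targets make per-contrast FDR control overly conservative, and
the signature definitions are intersections, which already sharpen
specificity. Degenerate genes (zero pooled variance) return p = 1 when
group means agree and p = 0 with a `degenerate` flag when they differ.

Signatures are set intersections of the per-contrast DEG sets:
pathogenic = DE(1) ∩ DE(2), progression = DE(1) ∩ DE(3) under the default
`methods` rule. A second rule, `results` (DE(2) ∩ DE(3)), is exposed as a
config switch because both variants circulate as definitions of a
stage-transition signature; neither is privileged beyond the default.
Direction consistency across contrasts 1 and 2 is annotated on pathogenic
genes but not enforced — consistency is an empirical observation about
such signatures, not part of their definition.

The rebound detector flags genes with a significant rise from normal to
early stage, a significant fall from early to advanced, and an advanced
mean still above the normal mean; the mirror-image (down-rebound)
trajectory is flagged and labelled separately.

## Co-expression networks

Networks are strictly bipartite: only lncRNA × mRNA pairs are tested.
An edge requires |r| > 0.8 and two-sided Pearson p < 0.01 jointly, with p
obtained from t = r√(n−2)/√(1−r²) on n−2 df. The pathogenic network uses
all disease samples (n = 17 at the default design) and pathogenic-
signature candidates; the early and advanced progression networks use
their stage's samples only (n = 8 and 9) and progression-signature
candidates. Genes constant over a sample subset are skipped with a
warning rather than failing the run. Isolated candidates are excluded
from the node set.

Scale-free diagnostics fit log₁₀(node count) against log₁₀(degree) by
ordinary least squares on the raw (unbinned) degree frequencies, reporting
slope, R² and the regression F-test p-value as the goodness-of-fit
measure; logarithmic binning is available behind a flag for heavy-tailed
degree sequences. Log-log OLS was chosen because it is the convention
that yields an R² for scale-free claims; no specific goodness-of-fit
procedure is canonical here and the F-test is our documented choice.
Hubs are nodes at or above the 95th degree percentile (configurable);
ties in the degree ranking break lexicographically by gene id so output
is deterministic.

## Enrichment, coverage and Sankey tables

Over-representation uses the hypergeometric upper tail P(X ≥ k) for an
overlap k between a query of size n and a set of size K in a universe of
N genes, with Benjamini–Hochberg adjustment across all tested sets and
significance at FDR < 0.05. The universe defaults to all genes in the
loaded annotation/matrix (configurable to the DE-tested subset); set
members are intersected with the universe before testing and empty sets
are dropped. Only over-representation is tested; depletion is out of
scope. Coverage reports, for one gene, the fraction of category sets
(e.g. fibrosis-related collections) containing it; Sankey links enumerate
the (gene, set) membership pairs behind a Sankey diagram.

## Marker correlation

A designated key lncRNA is correlated with a marker panel across disease
samples (early + advanced pooled, n = 17 at the default design). The
default panel is the six airway/epithelial markers KRT5, MUC5AC, MUC5B,
NGFR, SCGB1A1, SPDEF, fully overrideable. Each row reports Pearson r with
its t-transform p and a descriptive OLS line of marker on target. The
patient-level sample set is used because published p-values of this
analysis type are numerically consistent with df = 15, i.e. n = 17
patients.

## Assay formulas

Scratch-closure: rate(%) = (1 − area_t/area_0)·100, unit-free; a widened
wound returns a negative rate with a warning. qPCR relative expression
uses 2^−ΔΔCt against a housekeeping reference (GAPDH in the motivating
assays); this is an interpretation of "calculated from Ct values" — the
standard one — and efficiency correction is deliberately not modelled.
Replicates are computed per-quadruple and summarised afterwards.

## Synthetic cohort generator

The generator emulates a staged cohort of 6 normal / 8 early / 9 advanced
samples over 60 lncRNAs + 600 mRNAs. Gene g in sample j of stage c is

    x_gj = mu_g + delta_{g,c} + beta · z_{m(g),j} · active(m(g), j) + eps_gj

with mu_g ~ N(7, 1), eps ~ N(0, sigma²), sigma = 0.5, and planted effect
delta = 2.0 log2 units (4 residual SDs — strong, clean effects appropriate
for validating recovery machinery rather than stress-testing power).
Pathogenic genes shift ±delta in both disease stages; rebound genes shift
+delta in early and +delta/2 in advanced, reproducing the
up-then-partially-down-but-still-elevated trajectory with a single
parameter. Six latent-factor modules (one lncRNA driver + seven mRNA
partners each; z ~ N(0,1) per sample) cycle through disease-wide,
early-only and advanced-only activity; beta = 1.1 puts the within-module
correlation at beta²/(beta² + sigma²) ≈ 0.83 in active samples, i.e.
straddling the |r| > 0.8 edge threshold so that networks are non-trivial
but not saturated. Six marker genes load with −beta on the first
disease-wide module's factor across disease samples only, making them
anticorrelate with that module's driver — the designated key lncRNA.

Module members additionally carry the stage shift matching their
module's activity window (disease-wide modules the pathogenic pattern,
stage-specific modules the rebound pattern). This is a deliberate
extension of the minimal factor model: network candidates are gated by
the DE signatures, so co-expression modules must themselves be
differentially expressed for the end-to-end pipeline to produce
non-degenerate networks, as real disease modules are. A side effect worth
knowing: the factor inflates within-stage variance for module members,
which realistically lowers their individual DE power relative to
noise-only genes; recovery guarantees are therefore stated for the
pathogenic/rebound classes, which carry no factor. Stage-specific
progression networks built from 8–9 samples are consequently small, and
their degree tables sometimes have a single distinct degree, in which case
the power-law fit for that network is reported as skipped rather than
fabricated.

One global integer seed is expanded into independent substreams
(assignment, baselines, factors, noise, annotation, set assembly), so the
same seed reproduces every artifact bit for bit while substreams stay
stable under partial regeneration.

Gene-set generation plants enrichment: a quarter of 20 fibrosis-category
sets (size 20) are seeded with 10 module mRNAs plus random fillers, the
rest — and a 15-set pathway-category collection — are uniform draws; set
names record the construction so expected hypergeometric overlaps are
computable from the truth table.

What the generator does **not** emulate: batch effects, probe-level
artifacts, heavy-tailed or count-distributed noise, correlated null genes,
and realistic effect-size spectra. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under its stated
model, not field performance on real microarray cohorts.

## Numerical choices and degenerate inputs

- Pearson r is computed by standardised inner product and clipped to
  [−1, 1]; |r| = 1 maps to p = 0.
- Constant vectors raise a zero-variance error in `pearson_test` /
  `linear_fit`; inside network construction the offending gene's pairs are
  skipped with a warning instead.
- BH adjustment is the exact step-up q_(i) = min_{j≥i} p_(j)·m/j, capped
  at 1, returned in input order; ties are handled by stable sort.
- The hypergeometric tail is delegated to scipy's survival function,
  which is numerically stable for the small-N regimes used here; tests
  verify it against exhaustive enumeration for all N ≤ 12.
- Empty networks, empty rebound sets and empty Sankey tables are valid
  outputs, not errors; a power-law fit requires at least two distinct
  degrees and errors otherwise.

## Problem sizes in the test and acceptance runs

Recovery statistics average 50 simulated cohorts at the default design;
null calibration of the t-test uses 10⁵ simulated tests at n = 6 vs 8;
power-law recovery samples 5·10⁵ node degrees from f(d) ∝ d^−1.5 on
degrees 1–50; hypergeometric enumeration covers the complete (k, K, n, N)
grid for N ≤ 12. These sizes give Monte-Carlo error comfortably below the
asserted margins while keeping a full run in the tens of seconds.

## Known limitations

- The pooled t-test is anti-conservative under strong variance
  heterogeneity between stages; module-member genes in the generator
  exhibit exactly this (by design, documented above).
- The log-log OLS slope is a biased estimator of a power-law exponent for
  short, noisy degree tables; it is used here as a descriptive diagnostic,
  matching field convention, not as a maximum-likelihood exponent fit.
- Printed-correlation consistency checks can only be as tight as the
  2-decimal rounding of published r values permits; the checks therefore
  evaluate agreement over the rounding band of r.
- The enrichment universe choice (annotation-wide vs DE-tested) shifts
  p-values; it is recorded in run metadata and configurable.
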