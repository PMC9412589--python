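# Methods

This note records the statistical models, numerical choices and open design
decisions behind `csfpanel`, in the spirit of a methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design emulated

The pipeline targets a two-group (control vs medulloblastoma, "MB"),
four-fraction (total CSF, CPLL-equalized, microvesicles "Mv", exosomes "Ex")
label-free proteomics design with a small number of replicate samples per
group × fraction cell. Intensities live on the log2 scale throughout; a
zero intensity in the input table means "not detected", never "measured
zero".

## Synthetic-data generator

The generator is first-class, tested code: it defines the conditions under
which every downstream stage is verified.

**Model.** Each protein i has a baseline b_i drawn log-uniform over a
10-log2-unit range (default 20–30), emulating the wide dynamic range that
CPLL equalization is meant to compress. For a protein in module m with
latent correlation ρ,

    x_ij = b_i + σ ( √ρ · f_mj + √(1−ρ) · ε_ij ),   f, ε ~ N(0, 1) i.i.d.,

so the population correlation between any two module members is exactly ρ
(one-factor model); background proteins drop the factor term. A module may
be *trait-driven*: its factor is a·z_j + √(1−a²)·h_j, where z is the
standardized 0/1 indicator of a clinical group and a defaults to 0.95,
which yields a module-eigengene/trait Spearman correlation around 0.87 at
24 samples — comparable to the strong module–trait correlations such
studies report. Discriminant proteins add a fixed log2 fold change to the
MB samples of their affected fractions. Group/fraction-exclusive proteins
are forced detected in exactly one cell. Detection elsewhere follows a
logistic missing-not-at-random rule, P(detected) = 1/(1+e^{−s(x−m)}), with
midpoint m = 19 and steepness s = 0.8 by default, giving roughly 7%
missingness concentrated in low-abundance proteins so that the 70% presence
filter is exercised.

**Defaults.** 500 proteins; 3 samples per cell (24 samples); modules of
50/40/30 at ρ = 0.8 with the first trait-driven; 20 discriminant proteins
at log2 FC = 2 in the total and Ex fractions; residual noise σ = 0.5
(so the planted standardized effect is d = 4); 5 + 5 exclusive proteins.
The demo raises replication to 6 per cell (48 samples; a 6-vs-6 comparison
per fraction). All randomness flows from one master seed through named
substreams; identical configs give bit-identical data.

**What it does not emulate.** No peptide/spectrum level, no retention time
or m/z, no batch effects, no heteroscedastic or correlated noise beyond the
module factors, no fraction-specific abundance shifts. Within-group
variance is homoscedastic — the underlying study reports nothing about
per-group variance, so the simplest assumption is used. Consequently,
passing tests show that the algorithms recover structure of this idealized
kind at these sizes; they do not certify performance on real CSF data.

## Per-stage notes

**Normalization** is per-sample median centering of detected log2 values to
the grand median (optionally per fraction). It is monotone, leaves the
detection mask untouched, and is idempotent; the absolute level is set by
the grand median, so equality across runs is up to an additive constant.

**Overlap accounting** exposes the rounding policy (half-up "round" vs
"truncate", via exact decimal arithmetic) because published Venn
percentages mix both conventions; percentages always recompute exactly from
the stored counts.

**MDS screen.** Torgerson classical scaling (double-centered Gram
eigendecomposition) rather than stress-minimizing variants: deterministic
and checkable against a distance-preservation oracle. Axes are oriented so
the largest-magnitude coordinate is positive. Outliers: a sample is flagged
when its median Spearman correlation to all others falls more than 3
consistency-scaled MADs (×1.4826) below the cohort median of that
statistic. k-means uses k-means++ with 50 restarts under a fixed seed.

**Soft threshold.** For each candidate power the connectivity distribution
is binned (10 equal-width bins) and R² of the log-frequency vs log-degree
regression is taken as the scale-free fit. β is the smallest candidate with
R² ≥ 0.8 whose regression slope lies in (−3, 0) *and* whose fit is
sustained at the next candidate power. Both guards exist because the
compressed, unimodal degree distribution at very low powers can produce a
spuriously high binned R² (with a very steep slope) that collapses one
power later; genuine scale-free structure strengthens as the power rises.
If no candidate qualifies, the conventional sample-size default power
(9 / 8 / 7 / 6 for < 20 / < 30 / < 40 / ≥ 40 samples) is used and logged.
A single-candidate list is honored as given.

**Network and modules.** Unsigned adjacency |cor|^β on pairwise-complete
Pearson correlations of log2 values (a signed variant is available by
flag). Proteins detected in fewer than half the samples are excluded
before network construction: their pairwise-complete correlations rest on a
handful of shared observations and inject spurious structure (the usual
good-genes screen). TOM uses the standard formula with unit diagonal.
Modules come from average-linkage clustering of 1 − TOM with a *static*
cut: the default height is the midpoint of the largest gap in the upper
half of the dendrogram's merge heights, which separates within-module
merges from the tight band of background merges regardless of the TOM
scale set by β; an explicit cut height can be supplied. After cutting,
weakly attached members (mean within-module TOM below half the module
median) are moved to the background iteratively, and clusters below the
20-protein minimum size dissolve into the background ("grey"). An
all-equal TOM therefore yields a single module (tie rule). Dynamic
tree cut is deliberately out of scope. Module eigengenes are the first
principal component of the standardized within-module expression
(per-protein mean imputation inside the standardization only), unit-norm,
oriented to correlate positively with members on average. Module–trait
association uses Spearman ρ against six 0/1 indicators (control, MB,
total, CPLL, Mv, Ex), BH-adjusted over all pairs, flagged at |ρ| > 0.7 and
q ≤ 0.05.

**Differential expression.** Welch t by default (Student by flag) on
detected values only; missing values are never imputed here — detection
enters through the presence filter. "70% identity in one of two
conditions" is read as detection frequency. Fold change ≥ 2 is evaluated
as |log2 FC| ≥ 1 on group means. Per-protein AUC is the Mann–Whitney rank
statistic, reported orientation-free. Post-hoc power is the noncentral-t
power of the two-sided two-sample test at the observed pooled-SD effect;
where scipy's noncentral t loses precision at large noncentrality the
negligible wrong-side mass is set to 0 and the main tail uses its normal
limit. Zero pooled variance maps to power 1 (nonzero mean difference) or 0.
Whether the original 80% power was an a-priori design choice or a post-hoc
filter is unknowable from the text; the post-hoc value gates by default.
The volcano curve's constants default to x₀ = 1 with c calibrated so the
curve passes through (2, −log10 0.05); a point exactly on the curve is not
flagged.

**Ranking.** Features are standardized; missing values are imputed as half
the protein's minimum detected intensity (min − 1 on the log2 scale), the
standard low-abundance convention for classifiers. PLS-DA is NIPALS
regression of the centered 0/1 class vector with components capped at the
numerical rank of X (components past the rank are deflation noise and
break VIP symmetry for duplicated features); weights follow a
largest-|weight|-positive sign convention. VIP uses per-component explained
class variance SSY_a = q_a²‖t_a‖², giving Σ VIP² = p identically. The SVM
side uses a linear soft-margin SVM (C = 1): a stratified 65/35 split and
fourfold CV estimate accuracy, while recursive elimination of the smallest
squared weight — run on all samples of the fraction so ranks do not depend
on the accuracy split — defines the ranking. Ranking runs per fraction on
that fraction's significant proteins and panels pool by protein id (best
order across fractions), because a protein differing in only some fractions
would otherwise be crowded out by globally discriminant proteins. The
consensus is VIP > 1 ∩ SVM rank ≤ k with k defaulting to the VIP-selected
count; concordance between the two orderings is reported, not asserted.

**Enrichment.** Over-representation is one-sided hypergeometric against
the universe of proteins tested in the relevant comparison, BH-adjusted
across terms. The bounded rank value s = sign(oriented mean log2 FC) ·
√(k/K) · (1 − q), clipped to [−1, 1], is one concrete instantiation of a
score that grows with coverage, follows the fold-change direction, and is
shrunk by the FDR-adjusted p; the functional form is a package choice, not
an established statistic, and is isolated in a single function
(`enrichment.rank_value`) so alternatives can be swapped. With a single
shared coverage k the two group scores are antisymmetric whenever the mean
fold change is nonzero. The scatter distance d = (s_MB − s_control)/√2 is
the signed perpendicular distance from the x = y diagonal.

**Validation.** ROC is empirical over all thresholds; AUC by trapezoid
(provably identical to the rank statistic). The CI is a stratified
percentile bootstrap (2000 resamples by default); DeLong is available by
flag. AUC bins are upper-inclusive at the boundaries, so 0.9 is
"excellent" and exactly 0.5 is "not discriminant". The Youden cutoff
scans all observed scores ("positive" = score ≥ cutoff), ties resolving to
the lower cutoff; sensitivity/specificity carry Clopper–Pearson intervals;
LR+ = sens/(1 − spec) with an infinity sentinel at specificity 1.
Kruskal–Wallis is tie-corrected; Dunn z-statistics use the tie-corrected
rank variance with BH adjustment; quantiles use linear interpolation
(type-7). Dunn's test is implemented here directly as no installed package
provides it.

**Pipeline.** One YAML-serializable configuration carries every stage
parameter with the design's stated defaults (minimum module size 20, fit
target 0.8, |ρ| 0.7, α 0.05, FC 2, presence 0.7, AUC 0.7, power 0.8,
65/35 split, 4 folds) plus the master seed; validation rejects
out-of-range values before any stage runs. Every stage writes
self-describing TSV; `manifest.json` records version, parameters and
SHA-256 checksums per output, making byte-level reproducibility checkable.
The demo's gene sets are built from the generator truth (one term holding
the planted discriminant proteins plus seeded random terms), and its
ELISA-like validation data are log-normal four-group analyte values whose
medians and group sizes (0.46 / 1.4 / 0.5 / 0.56 RU/mL at n = 24/12/16/9)
mirror the magnitudes such assays report.

## Problem sizes used in the checks

Module recovery runs at the generator defaults (500 proteins, 24 samples);
differential-expression operating characteristics use 1000 proteins at
6-vs-6 (50 null simulations in the test suite; 25 in the acceptance
script); oracle identities use 200 random matrices (TOM), 500 instances
(AUC) and 200 (Youden); the end-to-end demo uses 500 proteins × 48
samples. These sizes make every check a desk-scale computation while
keeping the planted-recovery statistics stable across seeds.

## Known limitations

* The module cut is a static rule; very unequal module tightness or
  overlapping modules would favor dynamic tree cut, which is out of scope.
* The enrichment rank value is a constrained invention (see above); its
  absolute values are not comparable across datasets.
* Post-hoc power at the observed effect is known to be a monotone transform
  of the p-value; it is kept because the compound criterion specifies it.
* The generator's homoscedastic, factor-model structure is idealized;
  recovery rates on real label-free data will be lower.
* Percentages of the overlap accounting reproduce printed values only under
  the caller-chosen rounding policy, since published tables mix truncation
  and rounding.
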