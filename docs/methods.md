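# Methods

## The score

The GBV of an animal is a deterministic function of its genotypes at the
17-marker panel. Per marker, carriers of the CHD-associated (mutant) allele
receive that marker's published weight — the homozygous weight `w_hom` for
mutant homozygotes, the heterozygous weight `w_het` for heterozygotes — and
wild-type homozygotes receive `-w_hom`. The GBV is the sum over markers.
GBV(S) subtracts the analysis-cohort mean and divides by the analysis-cohort
range, so its width is exactly 1 and its end points are (−0.5, +0.5) only
for a symmetric GBV distribution. The standardization constants (mean, min,
max) are computed over, and only over, the animals entering the current
analysis, and are recorded in the report so GBV(S) values are reproducible.

Missing genotypes: the default policy `exclude` leaves the GBV of any
animal with a missing call undefined (conservative; the deposited study
data are expected complete); policy `zero` lets missing markers contribute
nothing and records how many were skipped. Every exclusion is logged.

## Panel model

A marker is a single-base substitution described by its wild-type and
mutant alleles and two bracketed sequence contexts that must differ at
exactly the bracketed base; contexts are stored on the reference-assembly
(CanFam3.1) leading strand, with `reverse_complement` provided for markers
reported on the opposite strand. Validation rejects identical context
pairs — the defect present in the original patent description of two panel
markers — as well as multi-base differences and non-nucleotide characters.
TiHo1 is modelled as an A/G substitution, not an indel. For TiHo19 and
TiHo35 the experimentally revised context table (wild [C]→mutant [T] and
wild [G]→mutant [C] respectively) is followed where it disagrees with the
allele directions quoted from the patent's own tables.

The bundled panel file is a **synthetic stand-in**: the four revised
contexts and the CHD-associated alleles of TiHo12/TiHo25/TiHo26 are the
published values; the remaining contexts, alleles and *all* numerical
weights are fixed placeholders chosen once (positive, 0.18–0.73, giving a
right-shifted GBV like the study's), because the patented weight table is
not in the public record shipped here. Reproduction of the published
cohort statistics therefore requires the user-supplied supplementary
tables (`caninegbv.reproduce`).

## Statistical procedures

All implemented from their definitions, matching the semantics of the
software the original analysis used:

* **Kruskal–Wallis**: midranks; H divided by the tie correction
  `1 − Σ(t³−t)/(N³−N)`; χ² reference with k−1 df. All-identical values are
  an error (correction factor 0).
* **Logistic MLE**: IRLS/Newton–Raphson on the log-likelihood; convergence
  when the relative log-likelihood change drops below 1e−10, max 50
  iterations; covariance is the inverse Fisher information at the MLE.
  Separation is detected as a diverging standardized coefficient
  (|β|·sd > 15) and raised, never silently returned; singular information
  raises a collinearity error.
* **Score test**: Rao statistic `U²/V` at the restricted MLE, 1 df. A
  constant candidate is reported as χ²=0 (it carries no information beyond
  the intercept); a candidate collinear with non-trivial model terms is an
  error.
* **Stepwise selection**: enter the smallest-p score-test candidate while
  p ≤ SLENTRY (0.05), then repeatedly remove the worst Wald-p term while
  p > SLSTAY (0.05); additive and dominance columns of one marker are
  independent candidates (the published final models mix them); revisiting
  a model state flags the trace as cycled and stops.
* **AUC**: Mann–Whitney concordance from midranks,
  `P(case > control) + ½P(tie)`; model AUCs are computed on fitted
  probabilities, so a protective predictor still yields AUC > 0.5.
* **OR / RR**: cross-product ratio and risk ratio with Woolf/Katz
  log-method intervals (`z` from the normal quantile at the requested
  level). Zero cells are errors — no silent continuity correction.
* **Quantiles**: medians/IQRs use linear interpolation between order
  statistics by default; the empirical-CDF-with-averaging convention is
  selectable (`quantile_convention`) because the original analysis
  software's default differs and the published IQRs do not identify the
  convention. The convention used is recorded in every report.
* Severe CHD means class 5 vs all others — the dichotomy under which the
  published genotype denominators (21 + 660 + 254 = 935) reconcile.
  Heterozygote relative risks pool both homozygote classes as the
  unexposed group.

The validation report runs each section independently; a failing section
(e.g. no affected animals) records an error entry without aborting the
rest. Reports are plain JSON and byte-identical across runs on identical
inputs.

## Synthetic cohorts

The generator's defaults are the study's observed margins: n = 935; CHD
class probabilities (657, 179, 53, 21, 25)/935; CED (714, 70, 39, 68,
37)/928; CHD–CED log-odds association ln 1.73; TiHo12 mutant-allele
frequency 0.842 (from the printed genotype counts); other allele
frequencies fixed once in 0.08–0.55. Genotypes are Hardy–Weinberg with
linkage equilibrium between markers. Affection follows a logistic model
`logit P = α + Σ(βₐ·dosage + β_d·het)` whose intercept is solved (Brent)
so the realized-cohort mean probability matches the configured margin;
severity among affected animals is assigned independently of genotype from
the conditional class distribution. `effect_target="severe"` instead puts
the genetic effects on class-5 membership, with classes 1–4 genotype-free
— the structure needed to exercise the severe-CHD dominance analysis. CED
affection is drawn with the configured log-odds ratio to CHD affection
while preserving the CED margin, and is otherwise marker-independent.
Missing calls are masked after phenotype assignment. All effects default
to zero.

What the generator does **not** emulate: pedigree relatedness and the
selection pressure of an active breeding program, linkage disequilibrium
between panel markers (a pairwise-LD extension was considered and left
out: no published LD information exists for the panel), polygenic
background beyond the 17 markers, and genotyping-error structure. Passing
tests on synthetic data therefore demonstrate that the *machinery* is
correct and calibrated (type-I error, CI coverage, null AUC), not that any
conclusion transfers to a particular real population.

## Problem sizes and numerical choices

The test suite uses cohorts of 80–10,000 animals: 935 (the study shape)
for pipeline determinism and section coverage, 10,000 for margin
calibration (3-SE binomial bounds), 5,000 × 500 seeds for confidence-
interval coverage of a planted per-allele log-OR of ln 2, and 2,000
replicates of n = 200 for score-test type-I error (accepted band
0.04–0.06). Exhaustive-permutation checks of the rank test use n ≤ 8.
The acceptance script runs one 935-animal null battery and one 5,000-animal
planted-effect fit per invocation.

Ties in stepwise entry are broken toward the larger χ²; group summaries
sort group labels; JSON serialization sorts keys — together these make
every pipeline output deterministic. Degenerate inputs (constant outcome,
zero-range GBV, empty groups, zero cells) raise typed errors that the
report layer converts to per-section error entries.

## Known limitations

* The bundled weights are placeholders; absolute GBV values from the
  bundled panel are not comparable to published GBVs. All published-value
  reproduction is gated on the user-supplied supplementary tables.
* Logistic inference is asymptotic Wald/score; no exact or penalized
  (Firth) alternatives, no ordinal modelling of the 5-class phenotype, and
  no multiple-testing adjustment — matching the original analysis.
* The patent's reference-curve risk lookup and offspring (mating-pair)
  risk prediction are out of scope.
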