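# Methods

## Setting and model

The package analyses a two-cohort (control vs case) expression study on the
log2 scale, together with a secreted-cytokine panel and a candidate eQTL
SNP.  Its core is a per-individual outlier statistic: for each retained
probe, each case value is standardized against the control cohort's sample
mean and SD and referred to the standard normal, with a call requiring both
`p < 0.005` (two-sided, strict) and an absolute log2 deviation `> 1`
(strict).  Recurrently aberrant probes across cases define patient
subgroups.

Model assumptions, stated explicitly:

- **Normality on the log2 scale.** Probe intensities are treated as
  normal within cohort.  The synthetic generator draws from exactly this
  model, so null calibration is analytically checkable; real array data
  have heavier tails, which inflates outlier rates relative to the normal
  reference (see *What the simulations do not show*).
- **Normal rather than t reference.** The standardized deviation is
  compared with N(0,1), not t(n−1).  With a finite control group the
  plug-in mean/SD make the realized per-test level exceed the nominal one:
  at n = 42 controls the measured null pass rate is ≈ 0.008 against a
  nominal 0.005 (the test suite asserts agreement with a brute-force
  Monte-Carlo oracle, not with the nominal level).
- **Controls only as reference.** Case samples never contribute to the
  reference mean/SD, so one grossly aberrant case cannot mask itself, and
  carriers of a shared defect cannot dilute each other.
- **No multiple-testing correction across outlier tests.** The procedure
  uses fixed per-test thresholds by design; the fold-change criterion, not
  the p-value, is what controls the flood of calls on low-variance probes.

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| outlier p threshold | 0.005 | probability | significance criterion (strict) |
| fold-change threshold | 1.0 | log2 | minimum deviation from control mean (strict) |
| detection threshold | 0.01 | probability | per-cell detection call (strict) |
| detection fraction | 0.5 | fraction | probe kept if detected in ≥ this share (ties kept) |
| min_carriers | 3 | count | recurrence cut for subgroup tables |
| edge alpha | 0.05 | probability | cytokine network edge significance |

Which criterion binds depends on the probe's control SD σ: the p criterion
needs |Δ| > z₀.₀₀₂₅·σ̂ ≈ 2.81σ̂, the fold-change criterion |Δ| > 1.  For
σ < ~0.36 the fold-change dominates (pass rate collapses toward
P(|Z| > 1/σ)); for σ > ~0.36 the p criterion dominates and the rate sits
near the (inflated) per-test level.

## The synthetic generator

`default_paper_scenario()` encodes the study conditions: 42 controls vs 58
cases over 10 468 probes; one planted probe under-expressed by 1.5 log2
units in 7 randomly chosen cases at probe SD 0.25; one additive eQTL probe
(Hardy–Weinberg dosages at MAF 0.183, slope −0.78 log2 per minor allele,
residual SD 0.253 chosen so the population dosage–expression r² is 0.74);
cytokine panels of 39 controls / 43 cases drawn from multivariate normals
on the log2 pg/ml scale with cohort-specific correlation targets
(control: TNF–IFN-γ 0.64, TNF–IL-6 0.67, IFN-γ–IL-6 0.60, IL-6–IL-10
−0.39; case: 0.15, 0.47, 0.33, 0.02; all unreported pairs 0, since only
those values are known).  Case cytokine means are shifted −0.8 (TNF) and
−1.2 (IFN-γ) log2 so the cohort comparison has signal to find.  Viability
absorbance is normal(1.0, 0.05) truncated positive.  Baseline probe means
are uniform on (6, 12) and probe SDs uniform on (0.1, 0.35) — the range
typical of across-donor variability for expressed probes on bead arrays;
with the dual thresholds this yields a few percent of probes carrying at
least one passing call in a 58-case null cohort, the order observed in
real studies of this design.  Per-cell detection P-values are < 0.01
except for a 2% dropout fraction.

All draws flow from the scenario seed (identical seeds ⇒ byte-identical
cohorts), and planted truth (carrier ids, dosages, targets) is recorded
for scoring.

### What the simulations do and do not show

The generator reproduces the *statistical geometry* the pipeline assumes:
normal probes, exact correlation targets, Hardy–Weinberg genotypes,
independent cells for detection dropout.  It does not model probe
cross-hybridization, intensity-dependent variance, heavy-tailed biological
outliers unrelated to disease, correlated detection failures, or linkage
between the eQTL and the planted subgroup (in the motivating study the
under-expressing subgroup *is* enriched for minor-allele homozygotes; here
the two are planted on separate probes so each stage is scored cleanly).
Passing tests therefore demonstrate correctness of the procedures under
their stated model, not performance on raw array data.

### Sampling arithmetic worth knowing

Two consequences of the planted parameters recur in the test suite:

- A carrier's realized deviation is Δ ~ N(−1.5, 0.25²·(1+1/42)), so the
  probability of clearing the strict |Δ| > 1 cut is Φ(0.5/0.253) ≈ 0.976
  per carrier — but only ≈ 0.976⁷ ≈ 0.84 for *all seven* carriers of a
  subgroup simultaneously.  Per-carrier sensitivity is high; complete
  subgroup recovery in a single draw is not guaranteed.
- A sample correlation at n = 39 around r = 0.64 has SD ≈ (1−r²)/√(n−1) ≈
  0.096, so it falls within ±0.15 of target in only ≈ 88% of draws, even
  though the edge is *detected* (p < 0.05) in > 99% of them.

## Design choices

- **Batch adjustment** is a per-probe additive batch + cohort least-squares
  fit (sum-to-zero batch coding); estimated batch effects are subtracted
  and residual deviations are rescaled per batch to the pooled residual SD,
  around batch×cohort cell means so neither the zero per-batch means nor
  the realized cohort contrast move.  No empirical-Bayes shrinkage of batch
  parameters is applied — with tens of samples per batch the per-probe
  estimates are adequate and the behavior is exactly testable; the output
  manifest records this.  Designs where every batch contains a single
  cohort are rejected as aliased.
- **Differential expression** uses per-probe pooled-variance Student t
  without cross-probe variance moderation, BH-adjusted across retained
  probes.  Fold change is case − control on log2.  At 42/58 samples the
  moderated and plain t are close; p-values from moderated pipelines will
  differ slightly, fold changes will not.
- **BH adjustment** is the step-up rule (delegated to statsmodels).  Note
  it is *not* idempotent: re-adjusting an adjusted vector can raise values
  further (e.g. [0.1, 0.3, 0.4] → [0.3, 0.4, 0.4] → [0.4, 0.4, 0.4]); the
  tested invariants are order preservation, adjp ≥ p, and the cap at 1.
- **Cytokine analysis** works on log2(x + 1 pg/ml) so zero concentrations
  are admissible; viability normalization multiplies by
  reference/absorbance (ratio to the mean well, preserving units).  Cohort
  mean comparison defaults to the same log2 scale (raw scale behind a
  flag).  The Fisher-z edge-difference test is a quantitative extension of
  the qualitative "edge present/absent" comparison and is labelled as such
  in outputs.
- **ΔΔCt** assumes amplification efficiency exactly 2 and averages
  replicate Ct values (triplicates) before ΔCt.
- **eQTL** uses additive dosage coding with per-cohort fits; r² is the
  squared dosage–expression correlation.  Genotypes are accepted as a
  dosage table, biallelic calls ("T/G"), or a minimal GT-only VCF.
- **Outlier calls are a DataFrame** (one row per probe×case test) rather
  than a list of objects: a study-sized run is ~600k tests.  The scalar
  `zscore_outlier` returns a single typed record.

## Numerical notes and degenerate inputs

Zero control SD, < 3 controls, zero pooled variance, zero-variance paired
differences, monomorphic dosage vectors, |r| = 1 in the Fisher transform,
non-finite Ct values and absorbance ≤ 0 are all rejected with explicit
errors rather than propagating NaN.  Batch residual rescaling guards
against near-zero per-batch SDs (scale clamped to 1).  Detection and
threshold comparisons are strict inequalities throughout; probes detected
in exactly the minimum fraction are retained.  Recurrence tables sort by
carrier counts with a stable sort so equal-count probes keep id order.

## Problem sizes used in the checks

The bundled statistical checks run at the study's own dimensions where
that is cheap (42/58 samples, cytokine panels 39/43, MAF 0.183) and use
~10⁶ probe×case tests for null calibration, 100 study-scale replicates for
subgroup recovery, and 200–400 replicates for correlation and eQTL
recovery — sizes at which the binomial error of the measured rates is well
below the margins being asserted.

## Known limitations

- The normal-reference outlier p-values are nominal, not exact; all
  calibration statements are relative to the matched Monte-Carlo oracle.
- The batch model is location/scale only; it will not remove
  probe-specific nonlinear batch distortions.
- Correlation targets for unreported cytokine pairs default to 0 — the
  true values in the motivating data are unknown.
- The pipeline assumes input matrices are already background-corrected and
  spline-normalized; no low-level array processing is re-implemented.
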