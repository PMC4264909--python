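# cytodet

Outlier-subgroup discovery for case/control transcriptomic cohorts, with the
surrounding cohort statistics: per-individual z-score outlier detection on
log2 expression matrices, recurrence aggregation into patient subgroups,
differential expression with Benjamini–Hochberg control, cytokine
co-secretion correlation networks compared between cohorts, comparative-Ct
(ΔΔCt) qPCR quantification, and single-SNP additive eQTL regression.  A
synthetic-cohort generator with planted ground truth makes every stage
testable end to end without external data.

## The problem

In genetically heterogeneous diseases, a case cohort may show **no**
differential expression against controls at the cohort level, while distinct
*subgroups* of patients each carry a gross abnormality in a different gene.
The motivating setting is monocyte-derived macrophages from Crohn's disease
patients: attenuated pro-inflammatory cytokine secretion with a normal
cohort-level transcriptome, explained in a ~12% subgroup by strong
under-expression of a single gene that is also under additive genetic
control (an eQTL).

## The statistic

For probe $g$ with healthy-control values $x_{g1},\dots,x_{gn}$ (log2 scale)
and a test (case) value $y_g$:

$$z_g = \frac{y_g - \bar{x}_g}{s_g}, \qquad \Delta_g = y_g - \bar{x}_g,$$

with $\bar x_g$, $s_g$ the control sample mean and SD ($n-1$ denominator).
A call is an outlier when **both** thresholds are met strictly:
two-sided normal tail probability $P(|Z|>|z_g|) < 0.005$ **and**
$|\Delta_g| > 1$ log2 unit.  Case samples never enter the reference
statistics.  Probes whose passing calls recur in ≥ `min_carriers` cases (per
direction) define candidate subgroups.  The normal reference makes the
per-test level approximate at finite control n; the inflation is quantified
against a Monte-Carlo oracle in the test suite.

Around this core: detection-P filtering (probe kept if detected at
P < 0.01 in ≥ 50% of samples), a covariate-protected location/scale batch
adjustment, per-probe pooled-variance t differential expression with BH
adjustment, per-cohort Pearson networks over all 10 cytokine pairs on log2
secretion (edge at p < 0.05) with Fisher-z edge comparison, 2^(−ΔΔCt)
relative quantification, and OLS regression of expression on minor-allele
dosage (0/1/2).

## Worked example

```sh
python examples/01_simulate_and_discover_subgroups.py
```

```
probes retained by detection filter: 2000
probes flagged in >=1 case: 73 (3.6% of expressed)
probes recurrent in >=3 cases: 2
planted probe: 7 under-expression carriers (12% of cases): ['CD007', 'CD012', 'CD013', 'CD019', 'CD042', 'CD050', 'CD055']
truth: ['CD007', 'CD012', 'CD013', 'CD019', 'CD042', 'CD050', 'CD055']
```

The generator planted one probe shifted −1.5 log2 in 7 of 58 cases; the
dual-threshold caller recovers exactly that subgroup (12% of the case
cohort), while ~3.6% of probes carry at least one passing call anywhere —
the expected background of the per-individual test at this cohort size.
The other examples cover the cytokine networks (`02`), eQTL regression
(`03`), differential expression + ΔΔCt (`04`) and batch adjustment (`05`),
each printing a few annotated numbers.

The same stages are scriptable from the shell:

```sh
cytodet simulate --seed 42 --out cohort/
cytodet outliers --expr cohort/expression.tsv --meta cohort/metadata.tsv \
    --p 0.005 --fc 1.0 --min-carriers 3 --out results/
cytodet run --config pipeline.yaml   # end-to-end with manifest + digests
```

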