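"""Covariate-protected batch adjustment on a cohort with a planted shift.

Two processing batches, the second shifted +0.8 log2 on every probe,
with cohorts spread across both.  The location/scale adjustment removes
the batch component (checked as per-probe variance explained by batch)
without touching the case/control contrast.
"""

from cytodet import (
    BatchSpec,
    SimScenario,
    adjust_batches,
    batch_variance_check,
    differential_expression,
    simulate_expression,
)

scenario = SimScenario(
    n_control=42, n_case=58, n_probes=1000,
    batches=[BatchSpec("run1", 50), BatchSpec("run2", 50, shift=0.8)],
    planted_outliers=[], eqtl=None, seed=13,
)
cohort = simulate_expression(scenario)

adjusted = adjust_batches(cohort.expression, cohort.metadata)
report = batch_variance_check(cohort.expression, adjusted, cohort.metadata)
print(f"mean variance fraction explained by batch: "
      f"{report['mean_r2_before']:.3f} before -> {report['mean_r2_after']:.5f} after")

de_before = differential_expression(cohort.expression, cohort.metadata)
de_after = differential_expression(adjusted, cohort.metadata)
drift = (de_after.set_index("probe_id")["fold_change"]
         - de_before.set_index("probe_id")["fold_change"]).abs().max()
print(f"max |change| in cohort fold change due to adjustment: {drift:.2e}")
# Batch variance drops to ~0.  Fold changes move only slightly; because
# the two cohorts are not spread perfectly evenly over the batches, part
# of the batch shift leaks into the raw cohort contrast, and removing it
# is exactly what the covariate-protected fit is for.  On a perfectly
# balanced design the contrast is preserved to machine precision.
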