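"""Single-SNP additive eQTL regression of one probe, per cohort.

The generator plants an additive eQTL (minor allele frequency 0.183,
beta -0.78 log2 per allele) on one probe; the regression recovers the
slope, r-squared and genotype-class counts in each cohort separately.
Also shows dosage conversion from raw biallelic calls.
"""

from cytodet import (
    cohort_eqtl,
    default_paper_scenario,
    genotype_from_calls,
    simulate_expression,
)

scenario = default_paper_scenario(seed=5)
scenario.n_probes = 200
scenario.__post_init__()
cohort = simulate_expression(scenario)

results = cohort_eqtl(cohort.expression, cohort.metadata, "PROBE_000001",
                      snp_id="rs12415716")
for name, res in results.items():
    n0, n1, n2 = res.n_by_genotype
    print(f"{name:>7}: beta={res.beta:+.2f} log2/allele  r2={res.r_squared:.2f}  "
          f"p={res.p:.1e}  genotypes 0/1/2 = {n0}/{n1}/{n2}")

dosages = genotype_from_calls(["T/T", "T/G", "G/G", "G/G"], minor_allele="G")
print(f"dosages from calls T/T, T/G, G/G, G/G: {[int(d) for d in dosages]}")
# A slope near -0.78 with r2 ~0.7 in each cohort: minor-allele carriers
# express the probe at progressively lower levels.
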