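"""Cytokine co-secretion networks, compared between cohorts.

Simulates secretion panels for 39 controls and 43 cases (five cytokines,
cohort-specific correlation targets), normalizes by well viability,
builds the per-cohort Pearson networks on log2 values and compares them
edge by edge with the Fisher z test.
"""

from cytodet import (
    build_network,
    compare_networks,
    compare_secretion,
    default_paper_scenario,
    normalize_by_viability,
    simulate_cytokines,
)

table = simulate_cytokines(default_paper_scenario(seed=7))
table = normalize_by_viability(table)  # rescale to mean well viability

hc = build_network(table, "control")
cd = build_network(table, "case")
print("control-network significant edges (p<0.05):")
for pair in sorted(map(sorted, hc.significant_pairs)):
    edge = hc.edge(*pair)
    print(f"  {pair[0]:>6} - {pair[1]:<6} r={edge['r']:+.2f} p={edge['p']:.1e}")

tnf_ifng = cd.edge("TNF", "IFN-g")
print(f"case cohort TNF-IFN-g: r={tnf_ifng['r']:+.2f} p={tnf_ifng['p']:.2f} "
      f"(edge lost: {not tnf_ifng['significant']})")

cmp = compare_networks(hc, cd).set_index(["cytokine_a", "cytokine_b"])
row = cmp.loc[[p for p in cmp.index if set(p) == {"TNF", "IFN-g"}][0]]
print(f"Fisher z difference for TNF-IFN-g: z={row['z_diff']:.2f} p={row['p_diff']:.3f}")

levels = compare_secretion(table).set_index("cytokine")
print("per-cytokine control-vs-case t-test (log2 pg/ml):")
print(levels[["t", "p"]].round(4).to_string())
# The case cohort loses the TNF-IFN-g co-secretion edge and IFN-g
# secretion is clearly attenuated; the smaller planted TNF shift may sit
# within sampling noise at n~40 per cohort, as in this draw.
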