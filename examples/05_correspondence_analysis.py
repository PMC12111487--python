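"""Correspondence analysis of the per-gene RSCU matrix with Axis-1 follow-up.

Builds the genes x 59 RSCU matrix for a mixed-bias genome, decomposes it,
and correlates Axis 1 with composition and index variables.
"""

import pandas as pd

from cubkit import (
    SyntheticSpec,
    axis1_correlations,
    build_codon_space,
    correspondence_analysis,
    default_at_planted,
    enc,
    filter_cds,
    composition_stats,
    generate_genome,
    orient_axes,
    rscu,
)

space = build_codon_space()
spec = SyntheticSpec(
    seed=8, n_genes=44, length_range=(900, 1500), gc3_target=0.30,
    gc12_target=0.40, gc12_spread=0.12, class_mixture=0.2, bias_strength=4.0,
    planted_optimal=default_at_planted(space), genome_id="demo",
)
genes, _ = generate_genome(spec, space)
records, _ = filter_cds(genes, space, "demo")

matrix = pd.DataFrame(
    {g.gene_id: rscu(g.codon_counts, space).rscu for g in records}
).T.reindex(columns=list(space.analysis_codons))
ca = correspondence_analysis(matrix)

per_gene = pd.DataFrame(
    {
        g.gene_id: {
            "GC3": composition_stats(g.codon_counts, space).gc3,
            "GC3s": composition_stats(g.codon_counts, space).gc3s,
            "ENC": enc(g.codon_counts, space).enc_obs,
            "L_aa": g.L_aa,
        }
        for g in records
    }
).T
ca = orient_axes(ca, per_gene["GC3s"].to_numpy())

print(f"{ca.n_axes} axes; Axis 1 explains {ca.inertia_pct[0]:.2f}% of the "
      f"inertia, Axis 2 {ca.inertia_pct[1]:.2f}%")
report = axis1_correlations(ca, per_gene, method="spearman")
ax_rows = report[report.variable_a == "Axis1"]
for row in ax_rows.itertuples(index=False):
    print(f"  Axis1 ~ {row.variable_b}: rho={row.coefficient:+.3f} "
          f"p={row.p_value:.2e} (BH-adjusted {row.p_adj_bh:.2e})")
print("With a high-bias gene class present, Axis 1 separates it and")
print("correlates with ENC; sign conventions are pinned to GC3s >= 0.")
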