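"""Composition statistics and codon-usage indices for one genome.

Computes the composition table row (third-position base fractions and
positional GC), pooled RSCU with its high-frequency codons, and the
per-gene effective number of codons.
"""

import numpy as np

from cubkit import (
    SyntheticSpec,
    build_codon_space,
    enc,
    filter_cds,
    generate_genome,
    genome_composition,
    high_frequency_codons,
    pooled_counts,
    rscu,
    to_rna,
)

space = build_codon_space()
genes, _ = generate_genome(SyntheticSpec(seed=1, genome_id="demo"), space)
records, _ = filter_cds(genes, space, "demo")

comp = genome_composition(records, space, "demo")
print("genome composition (pooled over filtered CDSs):")
print(f"  A3={comp.a3:.2%} T3={comp.t3:.2%} C3={comp.c3:.2%} G3={comp.g3:.2%}")
print(f"  GC={comp.gc_all:.2%} GC1={comp.gc1:.2%} GC2={comp.gc2:.2%} "
      f"GC3={comp.gc3:.2%} GC3s={comp.gc3s:.2%}")
print("T3 > A3 >> C3, G3 and GC3 < 50% signal a preference for A/T-ending codons.")

table = rscu(pooled_counts(records), space, "demo")
hf = sorted(high_frequency_codons(table))
print(f"\n{len(hf)} high-frequency codons (pooled RSCU > 1); all end A/T:",
      all(c[2] in "AT" for c in hf))
top = sorted(table.rscu.items(), key=lambda kv: -kv[1])[:5]
print("top RSCU:", ", ".join(f"{to_rna(c)}={v:.2f}" for c, v in top))

encs = [enc(g.codon_counts, space).enc_obs for g in records]
print(f"\nper-gene ENC: mean {np.mean(encs):.2f}, range "
      f"{min(encs):.2f}-{max(encs):.2f} (20 = extreme bias, 61 = uniform)")
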