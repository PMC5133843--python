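"""Audit a mitogenome annotation table.

Loads the bundled camellia spiny whitefly annotation (coordinates, codons
and anticodons as published) and recomputes the bookkeeping a genome
report states: junction gaps/overlaps, the gene inventory against the
37-gene animal complement, and protein-coding totals.
"""

import mitoglyph as mg

ann = mg.datasets.camelliae_annotation()
adj = mg.adjacency_report(ann)
inv = mg.inventory(ann)
cod = mg.codon_audit(ann)

print(f"genome length: {ann.genome_length} bp")
print(f"overlaps: {adj.total_overlap_bp} bp at {adj.n_overlap_junctions} "
      f"gene junctions")
print(f"intergenic (control region excluded): {adj.total_intergenic_bp} bp "
      f"at {adj.n_intergenic_locations} locations, "
      f"longest {adj.longest_intergenic[0]} bp between "
      f"{adj.longest_intergenic[1][0]} and {adj.longest_intergenic[1][1]}")
print(f"inventory: {inv.n_pcg} PCGs, {inv.n_trna} tRNAs, {inv.n_rrna} rRNAs;"
      f" absent from the canonical 37: {sorted(inv.absent)}")
print(f"PCG total: {cod.pcg_total_bp} bp = {cod.pcg_fraction_pct}% of the "
      f"genome; {cod.complete_codons} complete codons "
      f"({cod.n_incomplete_stops} genes end in a single-T incomplete stop)")
print()
print("A circular annotation is internally consistent when gene lengths,")
print("overlaps and gaps close the circle: residual =",
      adj.conservation_residual(ann), "bp")
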