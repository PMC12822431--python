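"""Build a pan-TE map from simulated TE annotations and SV bubbles.

Generates interval layouts with known TE<->SV links, attaches population
genotypes to the SVs, links each TE to the SV allele covering more than
half of it, merges linked-SV genotypes, and summarizes fixation.
"""

from pantemap import (build_pante_map, conservation_summary,
                      simulate_genotypes, simulate_intervals)

genes, tes, svs, truth = simulate_intervals(
    n_genes=20, n_tes=120, n_svs=60,
    contig_lengths={"chr1": 500_000, "chr2": 500_000}, seed=7)
sv_gm, _ = simulate_genotypes(n_accessions=200, n_tes=len(svs),
                              fixed_fraction=0.3, missing_rate=0.02,
                              seed=7, inbreeding=0.9)
for sv, vid in zip(svs, sv_gm.variants):
    sv.genotypes = sv_gm.dosages.loc[vid]

loci = build_pante_map(tes, svs)
summary = conservation_summary(loci)

print(f"TEs annotated: {len(tes)}, SV bubbles: {len(svs)}")
print(f"TEs linked to an SV (true links planted: {len(truth.te_sv_links)}): "
      f"{len(loci)}")
print(f"fixed fraction:       {summary['fixed_fraction']:.3f}")
print(f"polymorphic fraction: {summary['polymorphic_fraction']:.3f}")
# Only TEs sitting on an SV allele get population genotypes; the two
# fractions say how many of those loci segregate in the panel.
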