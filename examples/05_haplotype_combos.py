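"""Haplotype combinations of three focal TE insertions.

Accessions are partitioned by joint presence/absence of the focal
variants; each combination's phenotype mean and ecotype make-up is
summarized, plus how many focal variants each accession carries.
"""

from pantemap import (build_combos, combo_summary, simulate_genotypes,
                      simulate_phenotype)

gm, _ = simulate_genotypes(n_accessions=500, n_tes=3, fixed_fraction=0.0,
                           maf_law=("constant", 0.4), inbreeding=1.0,
                           seed=9)
focal = list(gm.variants)
pheno, _ = simulate_phenotype(gm, {t: -5.0 for t in focal},
                              heritability=0.8, seed=9,
                              trait="flowering_days")

combos, states = build_combos(gm, focal, min_freq=0.05)
summary = combo_summary(combos, states, pheno, "flowering_days")

print(f"classifiable accessions: {len(states)} of {gm.n_accessions}")
print(summary["per_combo"][["n", "frequency", "retained",
                            "trait_mean"]].round(3))
print("carriage % by ecotype (truncated integers):")
for eco, pct in summary["ecotype_carriage_pct"].items():
    print(f"  {eco}: {pct}")
# Negative planted betas mean more insertions -> earlier flowering, so
# combination means decrease with the number of '+' states.
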