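"""Simulate a genotype panel and run the composite-genotype association.

Builds a small synthetic panel (400 bulls, 8 candidate genes, one gene
carrying 15% of the APR trait variance), encodes each gene's SNP set as a
composite-genotype factor, and backward-eliminates the joint model.
"""

import genosets as g

config = g.SimConfig(
    n_animals=400,
    n_candidate_genes=8,
    n_background_loci=200,
    genome=(("chr1", 80_000_000), ("chr2", 80_000_000)),
    seed=42,
    trait_names=("APR",),
    causal_genes={"APR": {"SOCS2": 0.15}},
)
bundle = g.simulate_panel(config)
report = g.summarize_assignment(bundle["gene_sets"])
print(f"panel: {len(bundle['genotypes'])} animals, "
      f"{report.n_distinct_snps} SNPs over {len(bundle['gene_sets'])} genes")

recoded, alleles = g.determine_minor_alleles(bundle["genotypes"],
                                             bundle["snp_map"])
encodings = g.encode_gene_sets(recoded, bundle["gene_sets"], min_level_count=5)
trace = g.backward_eliminate(bundle["traits"]["APR"], encodings,
                             threshold=0.05, trait_name="APR")

fit = trace.final
print(f"\nremoved {len(trace.steps)} genes; retained: "
      f"{' + '.join(fit.genes) or '(none)'}")
print(fit.gene_tests.to_string(index=False))
print(f"R2 = {fit.r2:.4f}, adjusted R2 = {fit.adj_r2:.4f}")

summary = g.estimate_combination_effects(fit)
print(f"effect signs: {summary.n_positive} positive, "
      f"{summary.n_negative} negative")
print("\nEvery retained gene has a drop-one F-test P <= 0.05; the causal "
      "gene SOCS2 should head the list, with adjusted R2 near the "
      "simulated 15% variance fraction.")
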