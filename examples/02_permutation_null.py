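"""Benchmark an observed association against the random-locus null.

Re-runs the whole pipeline (collate SNPs in a 500 kb window, build
composites, backward-eliminate) on 200 sets of randomly chosen loci and
locates the observed candidate-gene result in the resulting null
distributions of adjusted R2 and minimum gene P.
"""

import genosets as g

config = g.SimConfig(
    n_animals=500,
    n_candidate_genes=8,
    n_background_loci=800,
    genome=tuple((f"chr{i}", 60_000_000) for i in range(1, 5)),
    seed=7,
    trait_names=("APR",),
    causal_genes={"APR": {"SOCS1": 0.12}},
)
bundle = g.simulate_panel(config)
recoded, _ = g.determine_minor_alleles(bundle["genotypes"])
encodings = g.encode_gene_sets(recoded, bundle["gene_sets"], 5)
observed = g.backward_eliminate(bundle["traits"]["APR"], encodings,
                                trait_name="APR").final
print(f"observed: {' + '.join(observed.genes)} "
      f"(adjusted R2 = {observed.adj_r2:.4f})")

nulls = g.run_permutations(
    recoded, bundle["traits"][["APR"]], bundle["snp_map"],
    bundle["regions"], b=200, n_loci=8, threshold=0.05, seed=11)
null = nulls["APR"]
tail = g.summarize_tail(observed, null)

print(f"null adjusted R2: median = {null.table['adj_r2'].median():.4f}, "
      f"95th pct = {null.table['adj_r2'].quantile(0.95):.4f}")
print(f"upper-tail probability of observed adjusted R2: "
      f"{tail.tail_adj_r2:.4f}")
print(f"permutations retaining >= k loci: {tail.retained_tail}")
print("\nA tail probability near 1/(B+1) means no random locus set came "
      "close to the candidate genes' variance explained — the signature "
      "of a real candidate-specific signal.")
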