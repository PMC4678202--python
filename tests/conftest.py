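import numpy as np
import pandas as pd
import pytest

import genosets as g


@pytest.fixture(scope="session")
def small_config():
    return g.SimConfig(
        n_animals=200,
        n_candidate_genes=4,
        n_background_loci=100,
        genome=(("chr1", 30_000_000), ("chr2", 30_000_000)),
        seed=7,
        causal_genes={"APR": {"SOCS1": 0.15}},
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return g.simulate_panel(small_config)


@pytest.fixture(scope="session")
def small_encodings(small_panel):
    recoded, _ = g.determine_minor_alleles(small_panel["genotypes"])
    return g.encode_gene_sets(recoded, small_panel["gene_sets"], 5)


def random_encoding(rng, n, n_snps=2, maf=0.3, gene="G", min_count=5):
    """A FactorEncoding from fresh random genotypes (helper, not a fixture)."""
    geno = rng.binomial(2, maf, size=(n, n_snps)).astype(float)
    animals = pd.Index([f"a{i}" for i in range(n)])
    cols = [f"{gene}_s{j}" for j in range(n_snps)]
    frame = pd.DataFrame(geno, index=animals, columns=cols)
    gs = g.GeneSnpSet(gene=gene, snp_ids=tuple(cols))
    comp = g.build_composite(frame, gs)
    return g.encode_factor(comp, min_count)
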