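import numpy as np
import pandas as pd
import pytest

from xenostroma import expression as ex
from xenostroma import synthetic as syn


@pytest.fixture(scope="session")
def small_refs():
    """Two small references with 0.85-identity homolog pairs."""
    return syn.make_references(12, 12, 6, 0.85, seed=0, n_decoys=3)


@pytest.fixture(scope="session")
def default_stroma_sim():
    """The default two-model stroma simulation with planted C1-C4 truth."""
    design = syn.default_design()
    genes_m = syn.gene_universe(2133, "MMU_G")
    genes_h = syn.gene_universe(200, "HSA_G")
    truth = syn.default_truth(genes_m, design, seed=0)
    human, mouse, mixed = syn.simulate_counts(genes_h, genes_m, design, truth)
    return {"design": design, "truth": truth, "human": human,
            "mouse": mouse, "mixed": mixed}


@pytest.fixture(scope="session")
def c1_target_sim():
    """Single-model stroma matrix with only the 50 C1 genes planted.

    2000 background genes, log2 effect +3 in intact, dispersion 0.1,
    library 2e6, the default 3/4/3 replicate design.
    """
    design = syn.default_design(("BM18like",))
    genes_m = syn.gene_universe(2050, "MMU_G")
    truth = syn.default_truth(
        genes_m, design, seed=0, cluster_sizes={"C1": 50}, library_size=2_000_000,
        stroma_fraction={("BM18like", c): 1.0
                         for c in ("intact", "castrated", "replaced")})
    _, mouse, _ = syn.simulate_counts([], genes_m, design, truth)
    return {"design": design, "truth": truth, "mouse": mouse}


@pytest.fixture(scope="session")
def null_count_matrix():
    """2000 NB genes, no group effect, 3-vs-4 design, phi = 0.1."""
    rng = np.random.default_rng(0)
    n_genes, phi = 2000, 0.1
    rel = rng.lognormal(0, 1, n_genes)
    rel /= rel.sum()
    mu = np.tile((2_000_000 * rel)[:, None], (1, 7))
    r = 1 / phi
    counts = rng.negative_binomial(r, r / (r + mu))
    cols = [f"s{i}" for i in range(7)]
    frame = pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)], columns=cols)
    groups = pd.Series(["A"] * 3 + ["B"] * 4, index=cols)
    return frame, groups


@pytest.fixture(scope="session")
def null_de(null_count_matrix):
    frame, groups = null_count_matrix
    return ex.nb_ql_test(frame, ex.tmm_factors(frame), groups, ("B", "A"))
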