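import numpy as np
import pytest

import fsttrace as ft
from fsttrace.genepop import AlleleFreqTable


TOY_GENEPOP = """two populations, two loci
Loc1
Loc2
pop
ind1_1 , 0101 0102
ind1_2 , 0102 0202
pop
ind2_1 , 0202 0101
ind2_2 , 0201 0000
"""


@pytest.fixture
def toy_genepop(tmp_path):
    path = tmp_path / "toy.gen"
    path.write_text(TOY_GENEPOP)
    return path


def make_af(counts, het=None):
    """AlleleFreqTable from a (loci, pops, alleles) count array."""
    counts = np.asarray(counts, dtype=np.int64)
    L, K, U = counts.shape
    return AlleleFreqTable(
        [f"p{i + 1}" for i in range(K)],
        [f"L{l + 1}" for l in range(L)],
        np.arange(1, U + 1),
        counts,
        counts.sum(axis=2) // 2,
        het,
    )


def random_af(rng, max_loci=6, max_pops=5, max_alleles=4, max_n=12):
    """Small random allele-count instance for oracle comparisons."""
    L = int(rng.integers(1, max_loci))
    K = int(rng.integers(2, max_pops))
    U = int(rng.integers(2, max_alleles))
    counts = np.zeros((L, K, U), dtype=np.int64)
    for l in range(L):
        for k in range(K):
            n = int(rng.integers(2, max_n))
            counts[l, k] = rng.multinomial(2 * n, rng.dirichlet(np.ones(U)))
    return make_af(counts)


@pytest.fixture(scope="session")
def cheap_chain_runs():
    """Fifty reduced-scale one-directional replicates, shared by the
    Monte Carlo checks (jackknife calibration, serial-founder effect,
    tree/MDS ordering, GLS founding-order signal)."""
    runs = []
    for seed in range(50):
        cfg = ft.reduced_scale_config("one_directional", seed=seed)
        gt, truth = ft.run_simulation(cfg)
        af = ft.allele_frequencies(gt)
        runs.append((af, truth, ft.popspecific_fst_wg(af)))
    return runs
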