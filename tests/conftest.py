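import numpy as np
import pytest

from genescape.popgen import Haplotype, PopulationSample, SpeciesDataset


def make_haplotypes(k: int = 4, length: int = 20, seed: int = 0) -> list[Haplotype]:
    """Small pool of aligned haplotypes differing by random substitutions."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    root = rng.choice(bases, size=length)
    haps = [Haplotype("h1", "".join(root))]
    for i in range(1, k):
        seq = root.copy()
        for s in rng.choice(length, size=rng.integers(1, 4), replace=False):
            seq[s] = rng.choice(bases[bases != seq[s]])
        haps.append(Haplotype(f"h{i + 1}", "".join(seq)))
    return haps


def random_population(
    rng: np.random.Generator, hap_ids: list[str], n_max: int = 8, pop_id: str = "p"
) -> PopulationSample:
    n = int(rng.integers(2, n_max + 1))
    k = int(rng.integers(1, len(hap_ids) + 1))
    chosen = rng.choice(hap_ids, size=k, replace=False)
    counts_vec = rng.multinomial(n, np.ones(k) / k)
    counts = {h: int(c) for h, c in zip(chosen, counts_vec) if c > 0}
    if not counts:
        counts = {chosen[0]: n}
    return PopulationSample(pop_id, float(rng.uniform(-10, 10)), float(rng.uniform(-10, 10)), counts)


@pytest.fixture
def small_pool() -> list[Haplotype]:
    return make_haplotypes(k=5, length=30, seed=1)


@pytest.fixture
def two_pop_dataset(small_pool) -> SpeciesDataset:
    pops = [
        PopulationSample("p1", 100.0, 25.0, {"h1": 4, "h2": 3}),
        PopulationSample("p2", 101.0, 26.0, {"h2": 2, "h3": 5}),
    ]
    return SpeciesDataset("sp", small_pool, pops)
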