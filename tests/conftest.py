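import numpy as np
import pytest

from msatabc import GenotypeDataset, LocusSpec, load_default_scenarios


@pytest.fixture(scope="session")
def scenario_set():
    return load_default_scenarios()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_dataset(pop_alleles, loci=None, populations=None):
    """Build a GenotypeDataset from explicit per-population genotype arrays.

    ``pop_alleles`` is a list (one entry per population) of arrays with
    shape (n_individuals, n_loci, 2) of allele sizes (repeat units).
    """
    blocks = [np.asarray(b, dtype=np.int16) for b in pop_alleles]
    n_loci = blocks[0].shape[1]
    if loci is None:
        hi = max(int(b[b >= 0].max()) for b in blocks if b.size)
        span = max(40, hi + 2)
        center = span // 2 + 1
        loci = [
            LocusSpec(f"L{i + 1}", ancestral_size=center, allowed_states=span)
            for i in range(n_loci)
        ]
    if populations is None:
        populations = [f"P{i + 1}" for i in range(len(blocks))]
    return GenotypeDataset(
        populations=populations,
        pop_sizes=np.array([b.shape[0] for b in blocks]),
        loci=loci,
        genotypes=np.concatenate(blocks, axis=0),
    )


@pytest.fixture(scope="session")
def paper_dataset(scenario_set):
    """One dataset simulated under the five-population study design."""
    from msatabc import sample_draw, simulate_dataset

    rng = np.random.default_rng(99)
    sc = scenario_set.get(1)
    draw = sample_draw(scenario_set.priors, sc, rng, n_loci=len(scenario_set.loci))
    return simulate_dataset(sc, draw, scenario_set.loci, rng)
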