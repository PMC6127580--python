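
import pytest

from pedgibbs.simulate import SimConfig, TraitSpec, simulate_study
from pedgibbs.pedigree import renumber_and_sort


def small_sim_config(seed=0, n_recorded=200, **kw):
    """A scaled-down study: ~310-animal pedigree, one ordinal + one continuous
    trait, used where full-size simulation would be wasteful."""
    traits = kw.pop(
        "traits",
        [
            TraitSpec("score", h2=0.3, mean=1.2, n_categories=5),
            TraitSpec("anchor", h2=0.4, mean=10.0, phenotypic_var=4.0),
        ],
    )
    return SimConfig(
        n_founders=40,
        n_generations=3,
        n_per_generation=90,
        n_recorded=n_recorded,
        traits=traits,
        genetic_corr=kw.pop("genetic_corr", {("score", "anchor"): 0.5}),
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_sim_config(seed=42))


@pytest.fixture(scope="session")
def default_study():
    """The full-size default: 793-animal pedigree, 385 records, 7 traits."""
    return simulate_study(seed=7)


def random_pedigree(rng, n_founders=8, n_generations=3, per_gen=10):
    """Random valid pedigree triplets (may include inbreeding)."""
    trip = [(i, 0, 0) for i in range(1, n_founders + 1)]
    pool = list(range(1, n_founders + 1))
    nid = n_founders
    for _ in range(n_generations):
        new = []
        for _ in range(per_gen):
            nid += 1
            s, d = rng.choice(pool, 2, replace=False)
            trip.append((nid, int(s), int(d)))
            new.append(nid)
        pool = new + pool[: max(2, len(pool) // 2)]
    return renumber_and_sort(trip)
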