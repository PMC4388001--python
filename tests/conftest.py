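import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_gmap():
    from coansel import GenomeMap

    return GenomeMap(n_chromosomes=2, loci_per_chromosome=100)


@pytest.fixture
def small_base(small_gmap, rng):
    from coansel import init_base

    return init_base(small_gmap, 40, rng)


def make_full_sib_pedigree():
    """Two unknown-parent founders and two full-sib offspring."""
    from coansel import Pedigree

    return Pedigree(
        ids=[1, 2, 3, 4],
        sire=[0, 0, 1, 1],
        dam=[0, 0, 2, 2],
        sex=[0, 1, 0, 1],
        generation=[0, 0, 1, 1],
    )


def make_full_sib_mating_pedigree():
    """Founder pair, two full sibs, and their (inbred) offspring."""
    from coansel import Pedigree

    return Pedigree(
        ids=[1, 2, 3, 4, 5],
        sire=[0, 0, 1, 1, 3],
        dam=[0, 0, 2, 2, 4],
        sex=[0, 1, 0, 1, 0],
        generation=[0, 0, 1, 1, 2],
    )


def random_pedigree(rng, n_founders=4, n_extra=4):
    """A random valid pedigree: founders then offspring of earlier pairs."""
    from coansel import Pedigree

    ids = list(range(1, n_founders + 1))
    sire = [0] * n_founders
    dam = [0] * n_founders
    sex = [i % 2 for i in range(n_founders)]
    gen = [0] * n_founders
    for k in range(n_extra):
        ident = n_founders + k + 1
        males = [i for i, s in zip(ids, sex) if s == 0]
        females = [i for i, s in zip(ids, sex) if s == 1]
        s = int(rng.choice(males))
        d = int(rng.choice(females))
        ids.append(ident)
        sire.append(s)
        dam.append(d)
        sex.append(int(rng.integers(2)))
        gen.append(max(gen[ids.index(s)], gen[ids.index(d)]) + 1)
    return Pedigree(ids, sire, dam, sex, gen)
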