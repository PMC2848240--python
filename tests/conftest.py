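import numpy as np
import pytest

import hbdkit as hk
from hbdkit.genotypes import FrequencySource


@pytest.fixture(scope="session")
def small_map():
    """500 markers on 5 chromosomes, 0.8 cM spacing."""
    return hk.make_sim_map(n_markers=500, spacing_morgans=0.008, n_chromosomes=5,
                           seed=np.random.SeedSequence(11))


@pytest.fixture(scope="session")
def default_map():
    """The canonical simulation map: 4,849 markers / 22 chromosomes / 0.8 cM."""
    return hk.make_sim_map(seed=np.random.SeedSequence(0).spawn(1)[0])


@pytest.fixture
def provided_freqs(small_map):
    return FrequencySource("provided", small_map.markers.freq_a1)


@pytest.fixture
def toy_ped_map(tmp_path):
    """2 individuals x 3 markers; calls [[het, hom_a1, missing], [hom_a2, het, hom_a1]].

    Allele 1 per marker is the first allele seen in the PED (A, G, T here).
    """
    map_path = tmp_path / "toy.map"
    map_path.write_text(
        "1 m1 0.8 800000\n"
        "1 m2 1.6 1600000\n"
        "2 m3 0.0 1000\n"
    )
    ped_path = tmp_path / "toy.ped"
    ped_path.write_text(
        "fam1 ind1 0 0 1 -9 A C G G 0 0\n"
        "fam1 ind2 0 0 2 -9 C C G A T T\n"
    )
    return ped_path, map_path


def hwe_genotypes(rng, p, n, f=0.0):
    """Independent-locus genotypes at frequencies p with HBD probability f."""
    p = np.asarray(p)
    hbd = rng.random(n) < f
    a = rng.random(n) < p
    b = np.where(hbd, a, rng.random(n) < p)
    return np.where(a & b, hk.HOM_A1, np.where(a | b, hk.HET, hk.HOM_A2)).astype(np.int8)
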