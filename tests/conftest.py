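import numpy as np
import pytest

import sweepscan as ss


@pytest.fixture
def toy_pedmap(tmp_path):
    """2 samples x 3 markers with one missing genotype; map unsorted on
    purpose (marker m2 before m1)."""
    map_path = tmp_path / "toy.map"
    ped_path = tmp_path / "toy.ped"
    map_path.write_text(
        "1\tm2\t0\t2000\n"
        "1\tm1\t0\t1000\n"
        "2\tm3\t0\t500\n")
    # columns follow the map file order: m2, m1, m3
    ped_path.write_text(
        "f1 s1 0 0 0 -9 A G A A C C\n"
        "f2 s2 0 0 0 -9 G G A A 0 0\n")
    return ped_path, map_path


@pytest.fixture
def small_dataset():
    cfg = ss.SimulationConfig(n_per_pop=25, n_chrom=2,
                              markers_per_chrom=250, seed=11)
    marker_map, haps, genos = ss.simulate_dataset(cfg)
    return cfg, marker_map, haps, genos


def random_genotype_matrix(rng, n_a=6, n_b=5, n_markers=40,
                           missing_rate=0.1):
    dos = rng.integers(0, 3, size=(n_a + n_b, n_markers)).astype(np.int8)
    dos[rng.random(dos.shape) < missing_rate] = -1
    return ss.GenotypeMatrix(
        dos, [f"s{i}" for i in range(n_a + n_b)],
        np.array(["A"] * n_a + ["B"] * n_b, dtype=object))
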