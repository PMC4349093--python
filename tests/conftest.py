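import numpy as np
import pytest

from wcrmap.simcross import CrossConfig, FitnessModel, SimGroup, SimMap


def tiny_map(n_autosomal=4, autosome_cm=60.0, n_x=2, x_cm=30.0):
    """One autosome + X, small enough for thousands of simulated families."""
    return SimMap([
        SimGroup("LG1", False, [f"A{i}" for i in range(n_autosomal)],
                 np.linspace(0.0, autosome_cm, n_autosomal), [("A", "G")] * n_autosomal),
        SimGroup("X", True, [f"X{i}" for i in range(n_x)],
                 np.linspace(0.0, x_cm, n_x), [("C", "T")] * n_x),
    ])


def two_autosome_map(markers_per_group=8, group_cm=140.0):
    """Two autosomes + X: enough structure for scans with unlinked loci."""
    groups = [
        SimGroup(f"LG{k + 1}", False, [f"L{k + 1}_{i}" for i in range(markers_per_group)],
                 np.linspace(0.0, group_cm, markers_per_group),
                 [("A", "G")] * markers_per_group)
        for k in range(2)
    ]
    groups.append(SimGroup("X", True, [f"X{i}" for i in range(4)],
                           np.linspace(0.0, 60.0, 4), [("C", "T")] * 4))
    return SimMap(groups)


@pytest.fixture
def small_map():
    return tiny_map()


@pytest.fixture
def clean_config():
    """No genotyping noise: Mendelian-exact families."""
    return CrossConfig(n_families=1, n_f1=40, n_f2_treatment=300, n_f2_control=300,
                       genotyping_error_rate=0.0, missing_rate=0.0, seed=7)


@pytest.fixture
def recessive_fitness():
    return FitnessModel(w_ss=0.0, w_rs=0.036, resistance_marker_id="A2")


def simulate_coded_intercross(positions_cm, n, rng):
    """Directly simulate F2-intercross genotype codes for one linkage group.

    Each individual receives two independent gametes from coupling-phase
    double heterozygotes; the code is the count of the second founder allele.
    """
    from wcrmap.simcross import _gametes_from_pairs
    haps = np.broadcast_to(np.array([[0], [1]], dtype=np.int8),
                           (n, 2, len(positions_cm))).copy()
    g1 = _gametes_from_pairs(haps, np.asarray(positions_cm, float), rng)
    g2 = _gametes_from_pairs(haps, np.asarray(positions_cm, float), rng)
    return (g1 + g2).astype(np.int8)


def simulate_coded_backcross(positions_cm, n, rng):
    """Directly simulate backcross codes (0/1 transmitted haplotype)."""
    from wcrmap.simcross import _gametes_from_pairs
    haps = np.broadcast_to(np.array([[0], [1]], dtype=np.int8),
                           (n, 2, len(positions_cm))).copy()
    return _gametes_from_pairs(haps, np.asarray(positions_cm, float), rng).astype(np.int8)
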