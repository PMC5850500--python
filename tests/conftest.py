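"""Shared fixtures: small simulated datasets and helper trees.

Everything is generated programmatically at test time; seeds are fixed so
the suite is deterministic.
"""

import numpy as np
import pytest

from duplicability import genetics, syntree
from duplicability.treeclass import GeneFamilyTree

SINGLETON_NEWICK = (
    "(((((human|h1:0.0168,chimp|c1:0.0168):0.0084,gorilla|g1:0.0252):0.0196,"
    "orangutan|o1:0.0448):0.0112,gibbon|b1:0.056):0.014,macaque|m1:0.07);"
)

#: minimal duplication topology used for LRT calibration/power checks:
#: two chimp paralogs, gibbon and macaque
CAL_NEWICK = ("((chimp|c1:0.02,chimp|c2:0.02):0.05,"
              "(gibbon|b1:0.056,macaque|m1:0.084):0.0);")


@pytest.fixture(scope="session")
def uniform_pi():
    return genetics.f3x4_from_position_freqs(np.full((3, 4), 0.25))


@pytest.fixture(scope="session")
def codonish_pi():
    """Mildly skewed, mammal-like position frequencies."""
    return genetics.f3x4_from_position_freqs(np.array([
        [0.27, 0.23, 0.32, 0.18],
        [0.31, 0.23, 0.19, 0.27],
        [0.22, 0.28, 0.28, 0.22],
    ]))


@pytest.fixture(scope="session")
def singleton_tree():
    return GeneFamilyTree.from_newick(SINGLETON_NEWICK, "sing")


@pytest.fixture(scope="session")
def cal_tree():
    return GeneFamilyTree.from_newick(CAL_NEWICK, "cal")


@pytest.fixture(scope="session")
def small_dataset():
    """30 families, ~3 duplicable, default parameters otherwise."""
    cfg = syntree.SimulationConfig(n_families=30, fraction_duplicable=0.1, seed=5)
    return syntree.simulate_dataset(cfg)


def simulate_pair(tree_or_newick, n_codons, kappa, omega, pi, seed,
                  omega_overrides=None):
    """Convenience wrapper: evolve an alignment along a tree."""
    gft = (tree_or_newick if isinstance(tree_or_newick, GeneFamilyTree)
           else GeneFamilyTree.from_newick(tree_or_newick))
    rng = np.random.default_rng(seed)
    return syntree.evolve_alignment(gft, n_codons, kappa, omega, pi, rng,
                                    omega_overrides=omega_overrides)
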