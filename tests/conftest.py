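import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from kinspector import simulate as sim
from kinspector.offtarget import GuideSpec

# the knock-in assay guide (protospacer of the 23-mer target
# AAGAAGGAGCCCTAGTTCAA + GGG PAM)
MMP9_PROTOSPACER = "AAGAAGGAGCCCTAGTTCAA"


@pytest.fixture(scope="session")
def mmp9_guide() -> GuideSpec:
    return GuideSpec("Mmp9-Cr1", MMP9_PROTOSPACER)


@pytest.fixture(scope="session")
def sim_config() -> sim.SimConfig:
    return sim.SimConfig(seed=11)


@pytest.fixture(scope="session")
def toy(sim_config):
    return sim.build_toy_genome(sim_config)


@pytest.fixture(scope="session")
def cassette_and_guides():
    return sim.make_cassette(seed=7)


def random_seq(seed: int, length: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


@pytest.fixture(scope="session")
def planted_library(toy, cassette_and_guides, sim_config):
    """Toy genome with a 12-site mismatch ladder and its digest library."""
    _, guide_l, _ = cassette_and_guides
    sites = [
        sim.PlantedSite("chr1", 3000 + 2500 * i, "+" if i % 2 == 0 else "-", i % 7)
        for i in range(12)
    ]
    genome, truth = sim.plant_guide_sites(toy.genome, guide_l, sites, seed=11)
    lib = sim.simulate_circle_library(
        genome,
        [guide_l],
        sim_config,
        min_pairs_per_site=6,
        cuts=sim.cuts_from_planted(sites),
    )
    return genome, guide_l, truth, lib
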