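import numpy as np
import pytest

from paraconv.seq_io import Alignment, RegionMap
from paraconv.simulate import MYR, ConversionEvent, SimConfig, simulate_history


@pytest.fixture
def small_alignment():
    return Alignment(
        ["a", "b", "c"],
        ["ACGTACGTAC", "ACGTACGTAT", "ACGTAC-TAC"],
    )


@pytest.fixture
def random_pair():
    """Two diverged 600-bp sequences with a few gaps."""
    rng = np.random.default_rng(42)
    base = rng.choice(list("ACGT"), 600)
    other = base.copy()
    mut = rng.random(600) < 0.08
    other[mut] = [rng.choice([b for b in "ACGT" if b != x]) for x in other[mut]]
    gap = rng.random(600) < 0.02
    other[gap] = "-"
    return Alignment(["s1", "s2"], ["".join(base), "".join(other)])


@pytest.fixture
def simulated_six_taxon():
    """Three species x two loci, one recent conversion in species B."""
    cfg = SimConfig(
        species_tree="((A:7000000,B:7000000):8000000,C:15000000);",
        duplication_time=40 * MYR,
        site_layout=[("noncoding", 2400)],
        conversion_events=[ConversionEvent("B", 2 * MYR, "S16", "S11", (400, 2000))],
        seed=7,
    )
    aln, truth = simulate_history(cfg)
    return cfg, aln, truth


@pytest.fixture
def flat_regions():
    return RegionMap([("left", 0, 4), ("right", 4, 8), ("all", 0, 8)])
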