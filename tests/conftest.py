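import numpy as np
import pytest

import oxloh as ox


@pytest.fixture(scope="session")
def full_genome() -> ox.GenomeMap:
    """Full-size default genome: 16 chromosomes, ~12 Mb, 15 000 markers."""
    return ox.build_genome("default", seed=1)


@pytest.fixture(scope="session")
def small_genome() -> ox.GenomeMap:
    """Two-chromosome toy genome for fast unit tests."""
    return ox.build_genome(
        {
            "chromosomes": [("chrA", 1000.0, 300.0), ("chrB", 600.0, 200.0)],
            "markers_per_chrom": 500,
        },
        seed=7,
    )


def plant_call_classify(genome, spec, noise_sd, seed):
    """Round-trip helper: plant -> render both daughters -> call -> classify."""
    d1, d2 = ox.plant_event(genome, spec, seed=seed)
    s1 = ox.call_pipeline(ox.render_profile(d1, noise_sd, seed=2 * seed + 1), genome)[2]
    s2 = ox.call_pipeline(ox.render_profile(d2, noise_sd, seed=2 * seed + 2), genome)[2]
    return ox.classify_sector_pair(ox.SectorPair(s1, s2, genome))
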