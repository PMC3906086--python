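import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "cfbias",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("cfbias")


@pytest.fixture(scope="session")
def small_sim():
    """A 2.3 Mb three-chromosome simulation with repeats and a duplication.

    Shared by module tests that need a realistic, fully annotated dataset
    (genome, mappability track, repeat annotation, fragments, truth).
    """
    from cfbias.reference import compute_unique_positions
    from cfbias.simulate import (
        Duplication,
        FragmentSampler,
        SimulationConfig,
        simulate_genome,
        simulate_repeats,
    )

    config = SimulationConfig(
        chrom_lengths={"chr1": 1_000_000, "chr2": 800_000, "chr21": 500_000},
        n_fragments=100_000,
        seed=11,
        repeat_fraction=0.25,
        duplications=[Duplication("chr1", 100_000, 140_000, "chr2", 200_000)],
    )
    genome = simulate_genome(config)
    track = compute_unique_positions(genome, 50)
    repeats = simulate_repeats(config)
    sampler = FragmentSampler(genome, config, mappability=track)
    frags, truth = sampler.sample(seed=5)
    return {
        "config": config,
        "genome": genome,
        "track": track,
        "repeats": repeats,
        "sampler": sampler,
        "frags": frags,
        "truth": truth,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
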