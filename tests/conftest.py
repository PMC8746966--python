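import pytest

from ncats.synth import (
    LocusSpec,
    SimulationConfig,
    make_reference,
    simulate_dataset,
    simulate_meth_calls,
    simulate_reads,
)


def small_sim_config(seed: int = 11, **overrides) -> SimulationConfig:
    """Scaled-down study conditions: same architecture, 1 Mb background."""
    kwargs = dict(
        seed=seed,
        genome_size=1_000_000,
        loci=[
            LocusSpec(name="gene1", start=200_000, length=3_400, target_depth=5.0),
            LocusSpec(name="gene2", start=500_000, length=5_100, target_depth=8.0),
            LocusSpec(name="gene3", start=800_000, length=3_600, target_depth=15.0),
        ],
        background_yield=30_000,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def sim_config():
    return small_sim_config()


@pytest.fixture(scope="session")
def sim_memory(sim_config):
    """(reference, truth, reads, calls) generated once per session."""
    reference, truth = make_reference(sim_config)
    reads = simulate_reads(sim_config, reference, truth)
    calls = simulate_meth_calls(sim_config, reference, reads, truth)
    return reference, truth, reads, calls


@pytest.fixture(scope="session")
def sim_files(sim_config, tmp_path_factory):
    """Full on-disk dataset: (paths dict, truth)."""
    outdir = tmp_path_factory.mktemp("simdata")
    return simulate_dataset(sim_config, outdir)
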