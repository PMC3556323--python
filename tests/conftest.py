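import numpy as np
import pytest

from nrcistrome.simulate import (
    ExpressionSimConfig,
    SimulationConfig,
    simulate_expression,
    simulate_genome,
    simulate_tags,
)


def small_sim_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A fast two-chromosome configuration for unit tests."""
    defaults = dict(
        seed=seed,
        n_chroms=2,
        chrom_len_bp=400_000,
        n_genes=30,
        n_planted_sites=20,
        n_direct_targets=14,
        n_null_artifact_sites=6,
        expression=ExpressionSimConfig(genes_per_type=2),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_genome():
    """(sequences, genes, mappability, manifest) for a small fixed-seed genome."""
    return simulate_genome(small_sim_config())


@pytest.fixture(scope="session")
def small_tracks(small_genome):
    """ChIP/input/null tag tracks for the small genome."""
    _, _, mappability, manifest = small_genome
    return {
        cond: simulate_tags(mappability, manifest, cond)
        for cond in ("chip_wt_veh", "chip_null_veh", "input_wt")
    }


@pytest.fixture(scope="session")
def recovery_panel():
    """Manifest + expression matrix at the recovery benchmark conditions."""
    from nrcistrome.benchmarks import response_recovery_config

    config = response_recovery_config(seed=3)
    _, _, _, manifest = simulate_genome(config, with_sequence=False)
    matrix = simulate_expression(manifest, config)
    return manifest, matrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
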