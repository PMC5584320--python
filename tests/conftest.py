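import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from homeoclust.simulate import SimConfig, simulate_transcriptome


@pytest.fixture(scope="session")
def small_sim():
    """A small default-condition transcriptome shared across test modules."""
    config = SimConfig(n_genes=30, seed=7)
    contigs, proteins, truth = simulate_transcriptome(config)
    return config, contigs, proteins, truth


@pytest.fixture(scope="session")
def exact_sim():
    """Zero-divergence, full-length, no-dropout hexaploid limit (tiny)."""
    config = SimConfig(n_genes=12, homeolog_divergence=0.0, indel_rate=0.0,
                       fragment_profile=(1.0, 0.0, 0.0), missing_homeolog_prob=0.0,
                       cds_length_range=(250, 400), seed=3)
    contigs, proteins, truth = simulate_transcriptome(config)
    return config, contigs, proteins, truth
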