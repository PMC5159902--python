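import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from chickdiv.simulate import (
    PanelConfig,
    demo_config,
    neutral_config,
    simulate_genome,
    simulate_panel,
)


@pytest.fixture(scope="session")
def demo():
    """Structured demo panel with one planted feature of each kind."""
    cfg = demo_config(seed=3)
    genome = simulate_genome(cfg)
    panel, track, truth = simulate_panel(genome, cfg)
    return {"config": cfg, "genome": genome, "panel": panel, "track": track, "truth": truth}


@pytest.fixture(scope="session")
def neutral_small():
    """Small single-population neutral panel for estimator checks."""
    cfg = neutral_config(theta=0.002, n_samples=10, length=100_000, seed=7)
    genome = simulate_genome(cfg)
    panel, track, truth = simulate_panel(genome, cfg)
    return {"config": cfg, "genome": genome, "panel": panel, "track": track, "truth": truth}


@pytest.fixture(scope="session")
def gene_genome():
    """Gene-dense toy genome for annotation tests."""
    cfg = PanelConfig(chromosomes=[("Ca1", 100_000)], cds_fraction=0.4, seed=5)
    return simulate_genome(cfg)
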