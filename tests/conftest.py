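import warnings

import numpy as np
import pytest

from boearch.synthetic import (
    SimulationConfig,
    TfEffect,
    default_tf_effects,
    simulate_dataset,
)

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def small_truth():
    """A modest dataset with all three regulatory logics planted.

    Sparsity is relaxed relative to the full-scale conditions so the
    zero/empty targets stay feasible at 10 TFs.
    """
    cfg = SimulationConfig(
        n_transcripts=2000, n_tfs=10, n_samples=500,
        sparsity=0.7, empty_fraction=0.2, seed=11,
    )
    cfg.tf_effects = default_tf_effects(cfg.tf_labels, seed=11)
    cfg.correlated_pairs = [("TF004", "TF005", 0.9)]
    cfg.tf_effects["TF005"] = cfg.tf_effects["TF004"]
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def linear_truth():
    """Linear-only effects (no saturating TFs), for coefficient recovery."""
    cfg = SimulationConfig(
        n_transcripts=3000, n_tfs=8, n_samples=1660,
        sparsity=0.6, empty_fraction=0.15, seed=23,
    )
    cfg.tf_effects = default_tf_effects(cfg.tf_labels, seed=23,
                                        prop_saturating=0)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_config(**kwargs) -> SimulationConfig:
    defaults = dict(n_transcripts=500, n_tfs=6, n_samples=100,
                    sparsity=0.6, empty_fraction=0.1, seed=0)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)
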