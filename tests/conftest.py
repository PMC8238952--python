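import numpy as np
import pytest

from nichemap.codebook import build_mhd4_codebook
from nichemap.synthetic import default_config, simulate_scene


@pytest.fixture(scope="session")
def full_codebook():
    """The complete 140-barcode codebook."""
    return build_mhd4_codebook([f"gene{i:03d}" for i in range(140)], seed=0)


@pytest.fixture(scope="session")
def small_codebook():
    return build_mhd4_codebook([f"g{i}" for i in range(10)], seed=1)


@pytest.fixture(scope="session")
def noiseless_scene():
    """Small clean scene shared by decoding/segmentation/assignment tests."""
    cfg = default_config(n_cells=60, field_size_um=(100.0, 100.0), seed=42)
    return simulate_scene(cfg)


@pytest.fixture(scope="session")
def noisy_scene():
    """Scene with dropout, false positives and per-round drift."""
    cfg = default_config(
        n_cells=60,
        field_size_um=(100.0, 100.0),
        seed=43,
        spot_dropout_rate=0.05,
        spot_false_positive_rate=1e-6,
        drift_per_round_px=(2, -1),
    )
    return simulate_scene(cfg)
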