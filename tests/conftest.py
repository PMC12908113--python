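import numpy as np
import pytest
from hypothesis import settings

import irdecide as ir

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ref_grid():
    return ir.make_grid(4000, 750, 2)


@pytest.fixture(scope="session")
def signal_config():
    """Default 7-case synthetic library configuration."""
    return ir.SyntheticSceneConfig(n_cases=7, seed=1)


@pytest.fixture(scope="session")
def signal_library(signal_config):
    """Baseline-corrected, normalized window spectra of the signal library."""
    return ir.library_spectra(signal_config, ir.PreconditionOption("bc_norm"))


@pytest.fixture(scope="session")
def trained_model(signal_library):
    """(equation, support vectors, decision contribution spectrum)."""
    return ir.train_full(signal_library)


@pytest.fixture(scope="session")
def one_case(signal_config):
    """(cube, truth, windows) for the first case of the signal library."""
    return ir.generate_case(signal_config, 0)


@pytest.fixture(scope="session")
def small_labeled():
    """Tiny hand-made two-case labeled set on a short grid, for fast
    geometry/plumbing tests that still need a trainable problem."""
    grid = ir.make_grid(1700, 1500, 10)  # 21 points
    rng = np.random.default_rng(42)
    n_per = 12
    base = rng.normal(0, 0.05, size=(4 * n_per, grid.count))
    signal = np.exp(-0.5 * ((grid.values - 1650) / 12.0) ** 2)
    labels = np.r_[np.ones(n_per), -np.ones(n_per), np.ones(n_per), -np.ones(n_per)]
    base[labels == 1] += signal
    cases = np.r_[["A"] * (2 * n_per), ["B"] * (2 * n_per)]
    return ir.LabeledSpectra(base, labels.astype(int), cases, grid)
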