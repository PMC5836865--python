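import dataclasses

import numpy as np
import pytest

from mrhabitats.phantom import render_phantom, three_habitat_config
from mrhabitats.relaxometry import fit_vfa_t1, signal_to_delta_r1


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, drift-free three-habitat phantom (exact round trips)."""
    cfg = three_habitat_config(
        grid_shape=(16, 16, 8), radii=(6.0, 5.0, 2.5), noise_sd=0.0, gradient=0.0, jitter=0.0
    )
    cfg = dataclasses.replace(cfg, drift_a=0.0)
    return render_phantom(cfg, seed=0)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-noise phantom with baseline drift, fixed seed."""
    cfg = three_habitat_config(grid_shape=(16, 16, 8), radii=(6.0, 5.0, 2.5), noise_sd=2.0)
    return render_phantom(cfg, seed=7)


def true_maps(out):
    """Ground-truth T10 / S0 volumes for a phantom output."""
    cfg = out.config
    t10 = np.full(cfg.grid_shape, np.nan)
    for i, h in enumerate(cfg.habitats, start=1):
        t10[out.truth.labels == i] = h.t10
    s0 = np.full(cfg.grid_shape, cfg.s0)
    return t10, s0


@pytest.fixture(scope="session")
def clean_delta_r1(clean_phantom):
    """Exact delta-R1 matrices from the noiseless phantom (true T10/S0)."""
    t10, s0 = true_maps(clean_phantom)
    dce = signal_to_delta_r1(clean_phantom.dce, s0, t10, clean_phantom.mask)
    oe = signal_to_delta_r1(clean_phantom.oe, s0, t10, clean_phantom.mask)
    return dce, oe
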