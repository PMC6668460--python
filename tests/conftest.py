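import math

import numpy as np
import pandas as pd
import pytest

from relaxdisp import (
    DispersionDataset,
    ExchangeParameters,
    SimulationConfig,
    default_residue_set,
)


@pytest.fixture(scope="session")
def noiseless_config():
    return SimulationConfig(seed=11, integral_noise_sigma=0.0)


@pytest.fixture(scope="session")
def noisy_config():
    return SimulationConfig(seed=11)


def make_rate_dataset(
    residues,
    kex,
    fields=(600.0, 700.0),
    spin_locks_khz=(1.0, 1.5, 2.5, 4.0, 6.0, 8.5, 11.5, 15.0, 20.0, 25.0),
    noise_sigma=0.0,
    error=0.4,
    seed=0,
):
    """On-resonance rate dataset built directly from the exchange model.

    ``residues``: mapping label -> (phi_ex, plateau). phi_ex is at the
    lowest field. Gaussian rate noise of ``noise_sigma`` s^-1; the reported
    error is ``error`` s^-1.
    """
    rng = np.random.default_rng(seed)
    ref = min(fields)
    rows = []
    for label, (phi, plateau) in residues.items():
        for f in fields:
            scale = (f / ref) ** 2
            for sl in spin_locks_khz:
                w1 = 2 * math.pi * sl * 1e3
                rate = plateau + scale * phi * kex / (w1**2 + kex**2)
                if noise_sigma > 0:
                    rate += rng.normal(0.0, noise_sigma)
                rows.append((label, f, sl, rate, error))
    pts = pd.DataFrame(
        rows, columns=["residue_label", "field_mhz", "spinlock_khz", "r1rho", "error"]
    )
    return DispersionDataset(pts, ref)


@pytest.fixture(scope="session")
def two_residue_noiseless():
    return make_rate_dataset(
        {"A1": (8.0e4, 10.0), "B2": (4.0e4, 9.0)}, kex=1.4e4
    )


@pytest.fixture(scope="session")
def five_residue_noiseless():
    residues = {
        f"G{i}": (3.0e4 + 2.0e4 * i, 8.0 + 0.5 * i) for i in range(5)
    }
    return make_rate_dataset(residues, kex=1.4e4)
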