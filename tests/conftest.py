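import math

import numpy as np
import pytest

from timsom.models import ViscoModel
from timsom.spectra import chi_t_from_signals, extract_fundamental
from timsom.tsim import (TimeSharingConfig, cycles_for, sample_voltages,
                         simulate_probe)


@pytest.fixture(scope="session")
def cfg():
    """Instrument configuration used throughout: 25 kHz two-slot sharing,
    10 us ramps, 30 us dwells, 33 us acoustic sampling delay, k = 50 pN/um,
    a = 0.5 um, A = 100 nm (the water-simulation parameters)."""
    return TimeSharingConfig()


@pytest.fixture(scope="session")
def water():
    return ViscoModel("newtonian", eta=1e-3)


@pytest.fixture(scope="session")
def fkv_cell():
    """Fractional Kelvin-Voigt parameters of cytoplasm-like magnitude."""
    return ViscoModel("fractional_kv", C_alpha=5.0, alpha=0.2,
                      C_beta=0.01, beta=0.9)


@pytest.fixture(scope="session")
def fm_condensate():
    """Fractional Maxwell parameters of condensate-like magnitude."""
    return ViscoModel("fractional_maxwell", C_alpha=10.0, alpha=0.1,
                      C_beta=1.0, beta=0.9)


def fde_chi_t(model, freq, cfg, n_periods=4, method=None):
    """Deviated response from a full forward simulation at one frequency."""
    nc = cycles_for(freq, cfg, n_periods)
    traj = simulate_probe(model, 2.0 * math.pi * freq, cfg, nc,
                          method=method)
    v1, v2 = extract_fundamental(sample_voltages(traj))
    return complex(chi_t_from_signals(v1, v2, cfg.k))


def gaver_stehfest(F, t, n=14):
    """Independent Laplace-inversion oracle (Gaver-Stehfest, double
    precision; adequate to ~1e-6 for smooth completely monotone targets)."""
    import math as m
    v = np.zeros(n)
    for k in range(1, n + 1):
        s = 0.0
        for j in range((k + 1) // 2, min(k, n // 2) + 1):
            s += (j ** (n // 2) * m.factorial(2 * j)
                  / (m.factorial(n // 2 - j) * m.factorial(j)
                     * m.factorial(j - 1) * m.factorial(k - j)
                     * m.factorial(2 * j - k)))
        v[k - 1] = (-1) ** (k + n // 2) * s
    ln2t = math.log(2.0) / t
    return ln2t * sum(v[k - 1] * F(k * ln2t) for k in range(1, n + 1))
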