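"""Photon interaction data for liquid water.

A compact table of standard published mass attenuation (mu/rho, coherent
included) and mass energy-absorption (mu_en/rho) coefficients for liquid
water, log-log interpolated.  The Compton share of the attenuation is
computed from the Klein-Nishina total cross-section and the electron
density of water; the remainder is treated as photoelectric (local
absorption).  Density 1 g/cm^3, so mass coefficients double as linear
ones in cm^-1.
"""

from __future__ import annotations

import numpy as np

ELECTRON_REST_MEV = 0.51099895
R_E2_CM2 = 7.94079e-26  # classical electron radius squared
WATER_ELECTRONS_PER_G = 3.3428e23

# energy MeV, mu/rho cm^2/g, mu_en/rho cm^2/g
_WATER_TABLE = np.array([
    [0.010, 5.329, 4.944],
    [0.015, 1.673, 1.374],
    [0.020, 0.8096, 0.5503],
    [0.030, 0.3756, 0.1557],
    [0.040, 0.2683, 0.06947],
    [0.050, 0.2269, 0.04223],
    [0.060, 0.2059, 0.03190],
    [0.080, 0.1837, 0.02597],
    [0.100, 0.1707, 0.02546],
    [0.150, 0.1505, 0.02764],
    [0.200, 0.1370, 0.02967],
    [0.300, 0.1186, 0.03192],
    [0.400, 0.1061, 0.03279],
    [0.500, 0.09687, 0.03299],
    [0.600, 0.08956, 0.03284],
    [0.800, 0.07865, 0.03206],
    [1.000, 0.07072, 0.03103],
    [1.250, 0.06323, 0.02965],
    [1.500, 0.05754, 0.02833],
])

_LOG_E = np.log(_WATER_TABLE[:, 0])
_LOG_MU = np.log(_WATER_TABLE[:, 1])
_LOG_MUEN = np.log(_WATER_TABLE[:, 2])

E_MIN_MEV = float(_WATER_TABLE[0, 0])
E_MAX_MEV = float(_WATER_TABLE[-1, 0])


def mu_water(energy_mev):
    """Linear attenuation coefficient of water, cm^-1 (rho = 1)."""
    e = np.clip(np.asarray(energy_mev, float), E_MIN_MEV, E_MAX_MEV)
    return np.exp(np.interp(np.log(e), _LOG_E, _LOG_MU))


def muen_water(energy_mev):
    """Mass energy-absorption coefficient of water, cm^2/g."""
    e = np.clip(np.asarray(energy_mev, float), E_MIN_MEV, E_MAX_MEV)
    return np.exp(np.interp(np.log(e), _LOG_E, _LOG_MUEN))


def klein_nishina_total(energy_mev):
    """Total Klein-Nishina cross-section per electron, cm^2."""
    a = np.asarray(energy_mev, float) / ELECTRON_REST_MEV
    t = 1.0 + 2.0 * a
    lnt = np.log(t)
    sigma = 2.0 * np.pi * R_E2_CM2 * (
        (1.0 + a) / a**2 * (2.0 * (1.0 + a) / t - lnt / a)
        + lnt / (2.0 * a)
        - (1.0 + 3.0 * a) / t**2
    )
    return sigma


def compton_mu_water(energy_mev):
    """Compton linear attenuation in water from Klein-Nishina, cm^-1."""
    return WATER_ELECTRONS_PER_G * klein_nishina_total(energy_mev)


def photoelectric_fraction(energy_mev):
    """Share of collisions treated as photoelectric (local absorption)."""
    mu = mu_water(energy_mev)
    frac = 1.0 - compton_mu_water(energy_mev) / mu
    return np.clip(frac, 0.0, 1.0)


def klein_nishina_dcs(energy_mev, cos_theta):
    """Differential KN cross-section dsigma/dOmega per electron, cm^2/sr."""
    a = np.asarray(energy_mev, float) / ELECTRON_REST_MEV
    c = np.asarray(cos_theta, float)
    x = 1.0 / (1.0 + a * (1.0 - c))  # E'/E
    sin2 = 1.0 - c * c
    return 0.5 * R_E2_CM2 * x * x * (x + 1.0 / x - sin2)
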