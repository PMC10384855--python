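"""Photon attenuation data for water.

Mass attenuation (µ/ρ) and mass energy-absorption (µ_en/ρ) coefficients for
liquid water, cm²/g, on a standard evaluated grid from 30 keV to 1.25 MeV.
Values between grid points are interpolated log-log (both coefficients are
smooth power-law-like functions of energy in this range).  Tissue is treated
as water with the local mass density: µ(E, x) = (µ/ρ)_water(E) · ρ(x).
"""

from __future__ import annotations

import numpy as np

# energy keV, mu/rho cm^2/g, mu_en/rho cm^2/g
_WATER = np.array(
    [
        [30.0, 0.3756, 0.1557],
        [40.0, 0.2683, 0.06947],
        [50.0, 0.2269, 0.04223],
        [60.0, 0.2059, 0.03190],
        [80.0, 0.1837, 0.02597],
        [100.0, 0.1707, 0.02546],
        [150.0, 0.1505, 0.02764],
        [200.0, 0.1370, 0.02967],
        [300.0, 0.1186, 0.03192],
        [400.0, 0.1061, 0.03279],
        [500.0, 0.09687, 0.03299],
        [600.0, 0.08956, 0.03284],
        [800.0, 0.07865, 0.03206],
        [1000.0, 0.07072, 0.03103],
        [1250.0, 0.06323, 0.02965],
    ]
)


def _loglog_interp(energy_kev: float, column: int) -> float:
    e = float(energy_kev)
    grid = _WATER[:, 0]
    if not grid[0] <= e <= grid[-1]:
        raise ValueError(
            f"photon energy {e} keV outside tabulated range "
            f"[{grid[0]}, {grid[-1]}] keV"
        )
    return float(
        np.exp(np.interp(np.log(e), np.log(grid), np.log(_WATER[:, column])))
    )


def mu_over_rho_water(energy_kev: float) -> float:
    """Mass attenuation coefficient of water, cm²/g."""
    return _loglog_interp(energy_kev, 1)


def mu_en_over_rho_water(energy_kev: float) -> float:
    """Mass energy-absorption coefficient of water, cm²/g."""
    return _loglog_interp(energy_kev, 2)


def absorption_fraction(energy_kev: float) -> float:
    """Fraction µ_en/µ of a photon's energy locally absorbed at its first
    interaction under the single-interaction transport model; the remainder
    is carried away by scatter and treated as escaped."""
    return mu_en_over_rho_water(energy_kev) / mu_over_rho_water(energy_kev)
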