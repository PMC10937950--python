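"""Temperature-dependent properties of liquid water (20-70 degC working range).

Density follows the Kell (1975) rational polynomial for air-free water at
atmospheric pressure; viscosity follows a Vogel-Fulcher-Tammann fit. The
thermal expansion coefficient is obtained analytically from the density
polynomial, alpha = -(1/rho) drho/dT.
"""

from __future__ import annotations

import numpy as np

__all__ = ["density", "viscosity", "thermal_expansion"]

# Kell (1975) coefficients, rho in kg m^-3, t in degC:
# rho = (a0 + a1 t + ... + a5 t^5) / (1 + b t)
_KELL_A = np.array(
    [999.83952, 16.945176, -7.9870401e-3, -46.170461e-6, 105.56302e-9, -280.54253e-12]
)
_KELL_B = 16.89785e-3

# VFT viscosity, eta in Pa s, T in K: eta = A exp(B / (T - C))
_VFT_A = 0.02939e-3
_VFT_B = 507.88
_VFT_C = 149.3


def _celsius(T_kelvin):
    return np.asarray(T_kelvin, dtype=float) - 273.15


def density(T):
    """Water density [kg m^-3] at absolute temperature ``T`` [K]."""
    t = _celsius(T)
    num = np.polyval(_KELL_A[::-1], t)
    return num / (1.0 + _KELL_B * t)


def viscosity(T):
    """Dynamic viscosity of water [Pa s] at absolute temperature ``T`` [K]."""
    T = np.asarray(T, dtype=float)
    return _VFT_A * np.exp(_VFT_B / (T - _VFT_C))


def thermal_expansion(T):
    """Volumetric expansion coefficient alpha [K^-1], alpha = -(1/rho) drho/dT."""
    t = _celsius(T)
    num = np.polyval(_KELL_A[::-1], t)
    dnum = np.polyval(np.polyder(np.poly1d(_KELL_A[::-1])), t)
    den = 1.0 + _KELL_B * t
    # d(rho)/dt via quotient rule
    drho = (dnum * den - num * _KELL_B) / den**2
    rho = num / den
    return -drho / rho
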