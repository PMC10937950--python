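"""Particle-level transport coefficients for EV-sized colloids.

Thermophoretic mobility is characterized by the Soret coefficient
S_T(a) = 0.03 (a / 100 nm)^2 K^-1, an empirical quadratic law for
extracellular vesicles, and Brownian diffusion follows Stokes-Einstein,
D = kT / (3 pi eta a).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BOLTZMANN = 1.380649e-23  # J K^-1

__all__ = [
    "BOLTZMANN",
    "soret_coefficient",
    "diffusion_coefficient",
    "ParticleSpec",
    "SizeDistribution",
]


def soret_coefficient(diameter: float) -> float:
    """Soret coefficient [K^-1] of an EV of diameter ``diameter`` [m].

    S_T = 0.03 (a / 100 nm)^2 K^-1.
    """
    a = np.asarray(diameter, dtype=float)
    if np.any(a <= 0):
        raise ValueError("particle diameter must be positive")
    out = 0.03 * (a / 100e-9) ** 2
    return float(out) if out.ndim == 0 else out


def diffusion_coefficient(diameter: float, T: float, eta: float) -> float:
    """Stokes-Einstein diffusivity [m^2 s^-1], D = kT / (3 pi eta a)."""
    a = np.asarray(diameter, dtype=float)
    T = np.asarray(T, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if np.any(a <= 0) or np.any(T < 0) or np.any(eta <= 0):
        raise ValueError("diameter and viscosity must be positive, T non-negative")
    out = BOLTZMANN * T / (3.0 * np.pi * eta * a)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ParticleSpec:
    """A single EV size class."""

    diameter: float  # m

    @property
    def soret(self) -> float:
        return soret_coefficient(self.diameter)

    def diffusivity(self, T, eta):
        return diffusion_coefficient(self.diameter, T, eta)


@dataclass
class SizeDistribution:
    """NTA-style binned size distribution (bin centers in m, weights sum to 1)."""

    bin_centers: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.bin_centers.ndim != 1 or self.bin_centers.shape != self.weights.shape:
            raise ValueError("bin_centers and weights must be 1-D and aligned")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 within 1e-9")

    def __len__(self):
        return self.bin_centers.size
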