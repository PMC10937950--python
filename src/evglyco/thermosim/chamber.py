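"""Chamber geometry, layered materials, laser source and the axisymmetric mesh.

The microchamber is a fluid disk (default 400 um high, 3.5 mm radius)
sandwiched between a glass top and a sapphire bottom (1 mm each). The mesh
is a cell-centered finite-volume grid in (r, z), stretched toward the axis
and toward the fluid-sapphire interface where the laser spot and the
accumulation layer live.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChamberGeometry", "MaterialProperties", "LaserSource", "Mesh", "WATER", "GLASS", "SAPPHIRE"]


@dataclass(frozen=True)
class MaterialProperties:
    """Bulk thermal properties; viscosity/expansion only meaningful for the fluid."""

    density: float  # kg m^-3
    thermal_conductivity: float  # W m^-1 K^-1
    heat_capacity: float  # J kg^-1 K^-1
    dynamic_viscosity: float | None = None  # Pa s, fluid only (reference value)

    def __post_init__(self):
        if min(self.density, self.thermal_conductivity, self.heat_capacity) <= 0:
            raise ValueError("density, conductivity and heat capacity must be positive")


WATER = MaterialProperties(density=997.0, thermal_conductivity=0.6, heat_capacity=4200.0,
                           dynamic_viscosity=0.89e-3)
GLASS = MaterialProperties(density=2500.0, thermal_conductivity=1.3, heat_capacity=761.0)
SAPPHIRE = MaterialProperties(density=3980.0, thermal_conductivity=35.0, heat_capacity=755.0)


@dataclass(frozen=True)
class ChamberGeometry:
    fluid_radius: float = 3.5e-3  # m
    fluid_height: float = 400e-6  # m
    top_solid_thickness: float = 1e-3  # m
    bottom_solid_thickness: float = 1e-3  # m
    grid_nr: int = 64
    grid_nz_fluid: int = 32
    grid_nz_solid: int = 8
    # stretching parameters (sinh clustering toward axis / geometric in solids);
    # defaults put the first radial cell at ~5 um and the first z cell at
    # ~0.5 um, resolving the near-wall accumulation layer (thickness D/v_T,
    # a few um for the largest EVs)
    stretch_r: float = 4.6
    stretch_z: float = 5.7
    solid_ratio: float = 1.4

    def __post_init__(self):
        lengths = (self.fluid_radius, self.fluid_height,
                   self.top_solid_thickness, self.bottom_solid_thickness)
        if min(lengths) <= 0:
            raise ValueError("all lengths must be positive")
        if min(self.grid_nr, self.grid_nz_fluid, self.grid_nz_solid) < 8:
            raise ValueError("grid counts must be >= 8 per region")


@dataclass(frozen=True)
class LaserSource:
    """Gaussian beam absorbed by Beer-Lambert decay through the fluid.

    S(r, z) = (2 P alpha / (pi w^2)) exp(-2 r^2 / w^2) exp(-alpha * depth), with
    w the 1/e^2 spot radius and ``depth`` the optical path length into the
    fluid. The beam enters through the glass top by default (the infrared
    heating beam and the fluorescence collection objective are on opposite
    sides of the chamber), so the heated core sits near the top while the
    sapphire keeps the imaged bottom cold. ``calibration_target_peak_T``
    (degC), when set, rescales the source so the peak fluid temperature
    matches it.
    """

    power: float = 0.150  # W
    spot_diameter: float = 160e-6  # m
    absorption_coefficient: float = 2300.0  # m^-1 (water near 1480 nm)
    calibration_target_peak_T: float | None = 65.0  # degC
    entry: str = "top"  # "top" (through glass) or "bottom" (through sapphire)

    def __post_init__(self):
        if self.power < 0 or self.spot_diameter <= 0 or self.absorption_coefficient <= 0:
            raise ValueError("invalid laser parameters")
        if self.entry not in ("top", "bottom"):
            raise ValueError("entry must be 'top' or 'bottom'")

    def volumetric_source(self, r, z, fluid_height):
        """Unit-calibration source field [W m^-3]; z is height above the bottom."""
        w = self.spot_diameter / 2.0
        depth = (fluid_height - z) if self.entry == "top" else z
        amp = 2.0 * self.power * self.absorption_coefficient / (np.pi * w**2)
        return amp * np.exp(-2.0 * (r / w) ** 2) * np.exp(-self.absorption_coefficient * depth)


def _sinh_points(n: int, length: float, beta: float) -> np.ndarray:
    """n+1 monotone points on [0, length], clustered toward 0 (sinh map)."""
    xi = np.linspace(0.0, 1.0, n + 1)
    return length * np.sinh(beta * xi) / np.sinh(beta)


def _geometric_points(n: int, length: float, ratio: float) -> np.ndarray:
    """n+1 points on [0, length]; first interval smallest, geometric growth."""
    widths = ratio ** np.arange(n)
    widths = widths / widths.sum() * length
    return np.concatenate([[0.0], np.cumsum(widths)])


class Mesh:
    """Axisymmetric finite-volume mesh over bottom solid + fluid + top solid.

    z = 0 at the fluid-sapphire interface; fluid occupies 0 <= z <= H.
    Cell-centered scalar fields are indexed [i_r, j_z] with j running over the
    full stack; fluid cells are ``j in [jf0, jf1)``.
    """

    def __init__(self, geom: ChamberGeometry):
        self.geom = geom
        g = geom
        # radial faces, clustered at the axis
        self.rf = _sinh_points(g.grid_nr, g.fluid_radius, g.stretch_r)
        # z faces: bottom solid (clustered at interface), fluid (clustered at bottom), top solid
        zb = -_geometric_points(g.grid_nz_solid, g.bottom_solid_thickness, g.solid_ratio)[::-1]
        zfl = _sinh_points(g.grid_nz_fluid, g.fluid_height, g.stretch_z)
        zt = g.fluid_height + _geometric_points(g.grid_nz_solid, g.top_solid_thickness, g.solid_ratio)
        self.zf = np.concatenate([zb[:-1], zfl, zt[1:]])
        self.nr = g.grid_nr
        self.nz = self.zf.size - 1
        self.jf0 = g.grid_nz_solid
        self.jf1 = g.grid_nz_solid + g.grid_nz_fluid

        self.rc = 0.5 * (self.rf[1:] + self.rf[:-1])
        self.zc = 0.5 * (self.zf[1:] + self.zf[:-1])
        self.dr = np.diff(self.rf)
        self.dz = np.diff(self.zf)
        # geometric factors
        ring = np.pi * (self.rf[1:] ** 2 - self.rf[:-1] ** 2)  # annulus areas
        self.area_z = ring  # z-face area per radial cell [nr]
        self.vol = ring[:, None] * self.dz[None, :]  # [nr, nz]
        # radial face area per (face i, cell j): 2 pi r_f dz
        self.area_r = 2.0 * np.pi * self.rf[:, None] * self.dz[None, :]  # [nr+1, nz]

    @property
    def fluid_slice(self):
        return slice(self.jf0, self.jf1)

    def material_index(self):
        """0 = bottom solid, 1 = fluid, 2 = top solid, per z-cell."""
        idx = np.full(self.nz, 2, dtype=int)
        idx[: self.jf0] = 0
        idx[self.jf0: self.jf1] = 1
        return idx
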