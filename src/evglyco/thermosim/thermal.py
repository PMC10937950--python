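"""Steady conjugate heat transfer + buoyant Stokes flow in the microchamber.

The temperature field is solved over the full solid/fluid stack by a
conservative finite-volume discretization (harmonic-mean conductivities,
upwind advection in the fluid, Dirichlet ambient on the exterior z faces,
adiabatic side wall by default). The flow is axisymmetric buoyancy-driven
Stokes flow, solved monolithically in stream function-vorticity form with
Thom wall vorticity; at the micron scales and mm/s velocities involved the
Reynolds number is far below 1, so inertia is dropped. The two are coupled
by fixed-point iteration (T -> buoyancy -> u -> advected T) and the laser
source amplitude is optionally rescaled each pass so the peak fluid
temperature hits the calibration target.

Face volume fluxes are derived directly from stream-function differences,
which makes the discrete velocity field exactly divergence-free on the
species grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator

from .. import water
from .chamber import ChamberGeometry, LaserSource, Mesh, MaterialProperties, WATER, GLASS, SAPPHIRE

__all__ = ["ThermalFlowSolution", "SolverError", "solve_steady_thermal_flow"]

G_STANDARD = 9.81  # m s^-2


class SolverError(RuntimeError):
    pass


@dataclass
class ThermalFlowSolution:
    mesh: Mesh
    T: np.ndarray               # cell-centered temperature [K], full stack [nr, nz]
    psi: np.ndarray             # stream function at fluid nodes [nr+1, nzf+1], m^3 s^-1 / 2pi
    flux_r: np.ndarray          # volume flux through radial fluid faces [nr+1, nzf], m^3 s^-1
    flux_z: np.ndarray          # volume flux through z fluid faces [nr, nzf+1], m^3 s^-1
    source_scale: float         # calibration factor applied to the nominal source
    ambient: float              # K
    iterations: int

    @property
    def T_fluid(self):
        return self.T[:, self.mesh.fluid_slice]

    @property
    def max_T(self) -> float:
        """Peak fluid temperature [K]."""
        return float(self.T_fluid.max())

    @property
    def bottom_interface_max_T(self) -> float:
        """Maximum temperature [K] on the fluid-sapphire interface."""
        m = self.mesh
        js, jf = m.jf0 - 1, m.jf0
        ds = m.zf[m.jf0] - m.zc[js]
        df = m.zc[jf] - m.zf[m.jf0]
        gs = SAPPHIRE.thermal_conductivity / ds
        gf = WATER.thermal_conductivity / df
        t_face = (gs * self.T[:, js] + gf * self.T[:, jf]) / (gs + gf)
        return float(t_face.max())

    @property
    def max_speed(self) -> float:
        """Approximate maximum fluid speed [m s^-1] from face fluxes."""
        m = self.mesh
        uz = 0.5 * (self.flux_z[:, 1:] + self.flux_z[:, :-1]) / m.area_z[:, None]
        ar = np.maximum(m.area_r[:, m.fluid_slice], 1e-300)
        ur_face = self.flux_r / ar
        ur = 0.5 * (ur_face[1:, :] + ur_face[:-1, :])
        return float(np.sqrt(uz**2 + ur**2).max())

    def cell_speed(self):
        m = self.mesh
        uz = 0.5 * (self.flux_z[:, 1:] + self.flux_z[:, :-1]) / m.area_z[:, None]
        ar = np.maximum(m.area_r[:, m.fluid_slice], 1e-300)
        ur_face = self.flux_r / ar
        ur = 0.5 * (ur_face[1:, :] + ur_face[:-1, :])
        return np.sqrt(uz**2 + ur**2)


def _conductivity_per_cell(mesh: Mesh, mats) -> np.ndarray:
    lam = np.array([m.thermal_conductivity for m in mats])
    return lam[mesh.material_index()]


def _assemble_temperature(mesh: Mesh, lam_z, source, flux_r, flux_z,
                          rho_cp_fluid, side_dirichlet):
    """Sparse system A theta = b for theta = T - T_ambient (theta=0 exterior)."""
    nr, nz = mesh.nr, mesh.nz
    n = nr * nz
    idx = lambda i, j: j * nr + i
    rows, cols, vals = [], [], []
    b = np.zeros(n)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    rc, zc, rf, zf = mesh.rc, mesh.zc, mesh.rf, mesh.zf
    jf0, jf1 = mesh.jf0, mesh.jf1

    for j in range(nz):
        lam = lam_z[j]
        for i in range(nr):
            k = idx(i, j)
            diag = 0.0
            # radial neighbours (same material in a layer -> lam uniform radially)
            if i > 0:
                d = (rc[i] - rc[i - 1])
                g = mesh.area_r[i, j] * lam / d
                add(k, idx(i - 1, j), g)
                diag -= g
            if i < nr - 1:
                d = (rc[i + 1] - rc[i])
                g = mesh.area_r[i + 1, j] * lam / d
                add(k, idx(i + 1, j), g)
                diag -= g
            elif side_dirichlet:
                g = mesh.area_r[nr, j] * lam / (rf[nr] - rc[nr - 1])
                diag -= g  # theta_amb = 0
            # vertical neighbours (harmonic mean across layer boundaries)
            if j > 0:
                dlo = zf[j] - zc[j - 1]
                dhi = zc[j] - zf[j]
                g = mesh.area_z[i] / (dlo / lam_z[j - 1] + dhi / lam)
                add(k, idx(i, j - 1), g)
                diag -= g
            else:
                g = mesh.area_z[i] * lam / (zc[0] - zf[0])
                diag -= g
            if j < nz - 1:
                dlo = zf[j + 1] - zc[j]
                dhi = zc[j + 1] - zf[j + 1]
                g = mesh.area_z[i] / (dlo / lam + dhi / lam_z[j + 1])
                add(k, idx(i, j + 1), g)
                diag -= g
            else:
                g = mesh.area_z[i] * lam / (zf[nz] - zc[nz - 1])
                diag -= g
            add(k, k, diag)
            b[k] = -source[i, j] * mesh.vol[i, j]

    # upwind advection inside the fluid: flux of rho*cp*T through fluid faces
    if flux_r is not None:
        for j in range(jf0, jf1):
            jl = j - jf0
            for i in range(nr):
                k = idx(i, j)
                # radial faces i (left) and i+1 (right); positive flux = +r direction
                for face, nb in ((i, idx(i - 1, j) if i > 0 else None),
                                 (i + 1, idx(i + 1, j) if i < nr - 1 else None)):
                    q = flux_r[face, jl]
                    outward = 1.0 if face == i + 1 else -1.0
                    qo = outward * q  # flow out of cell k when positive
                    if qo > 0:
                        add(k, k, -rho_cp_fluid * qo)
                    elif nb is not None:
                        add(k, nb, -rho_cp_fluid * qo)
                # z faces jl (below) and jl+1 (above)
                for face, nb in ((jl, idx(i, j - 1) if j > jf0 else None),
                                 (jl + 1, idx(i, j + 1) if j < jf1 - 1 else None)):
                    q = flux_z[i, face]
                    outward = 1.0 if face == jl + 1 else -1.0
                    qo = outward * q
                    if qo > 0:
                        add(k, k, -rho_cp_fluid * qo)
                    elif nb is not None:
                        add(k, nb, -rho_cp_fluid * qo)

    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return A, b


def _solve_stokes(mesh: Mesh, T_cells, ambient, gravity):
    """Monolithic stream function-vorticity Stokes solve on fluid nodes.

    Returns psi [nr+1, nzf+1] such that the volume flux between two nodes is
    2 pi * delta(psi).
    """
    nzf = mesh.jf1 - mesh.jf0
    rn = mesh.rf
    zn = mesh.zf[mesh.jf0: mesh.jf1 + 1]
    ni, nj = rn.size, zn.size

    # node temperature by bilinear interpolation (linear extrapolation at edges)
    interp = RegularGridInterpolator(
        (mesh.rc, mesh.zc[mesh.fluid_slice]), T_cells,
        bounds_error=False, fill_value=None)
    RR, ZZ = np.meshgrid(rn, zn, indexing="ij")
    Tn = interp(np.stack([RR.ravel(), ZZ.ravel()], axis=1)).reshape(ni, nj)

    rho_amb = water.density(ambient)
    Fz = gravity * (rho_amb - water.density(Tn))  # upward buoyancy force density
    eta_n = water.viscosity(Tn)

    # radial derivative of Fz at nodes
    dFdr = np.zeros_like(Fz)
    hm = rn[1:-1] - rn[:-2]
    hp = rn[2:] - rn[1:-1]
    dFdr[1:-1, :] = (Fz[2:, :] - Fz[:-2, :]) / (hm + hp)[:, None]

    n = ni * nj
    psi_of = lambda i, j: j * ni + i
    omg_of = lambda i, j: n + j * ni + i
    rows, cols, vals = [], [], []
    b = np.zeros(2 * n)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for j in range(nj):
        for i in range(ni):
            kp, ko = psi_of(i, j), omg_of(i, j)
            on_axis = i == 0
            on_side = i == ni - 1
            on_bot = j == 0
            on_top = j == nj - 1
            if on_axis or on_side or on_bot or on_top:
                add(kp, kp, 1.0)  # psi = 0 on all boundaries
                corner = (on_axis or on_side) and (on_bot or on_top)
                if on_axis or corner:
                    add(ko, ko, 1.0)  # omega = 0 on the axis and at corners
                elif on_bot:
                    dz = zn[1] - zn[0]
                    add(ko, ko, 1.0)
                    add(ko, psi_of(i, 1), 2.0 / (rn[i] * dz**2))
                elif on_top:
                    dz = zn[nj - 1] - zn[nj - 2]
                    add(ko, ko, 1.0)
                    add(ko, psi_of(i, nj - 2), 2.0 / (rn[i] * dz**2))
                else:  # side wall
                    dr = rn[ni - 1] - rn[ni - 2]
                    add(ko, ko, 1.0)
                    add(ko, psi_of(ni - 2, j), 2.0 / (rn[i] * dr**2))
                continue

            r = rn[i]
            hrm, hrp = rn[i] - rn[i - 1], rn[i + 1] - rn[i]
            hzm, hzp = zn[j] - zn[j - 1], zn[j + 1] - zn[j]
            # second-derivative weights
            crr = 2.0 / (hrm + hrp)
            czz = 2.0 / (hzm + hzp)
            wr_m, wr_p = crr / hrm, crr / hrp
            wz_m, wz_p = czz / hzm, czz / hzp
            # first derivative (central, nonuniform)
            dr_m, dr_p = -1.0 / (hrm + hrp), 1.0 / (hrm + hrp)

            # psi equation: psi_rr - psi_r / r + psi_zz + r * omega = 0
            add(kp, psi_of(i - 1, j), wr_m - dr_m / r)
            add(kp, psi_of(i + 1, j), wr_p - dr_p / r)
            add(kp, psi_of(i, j - 1), wz_m)
            add(kp, psi_of(i, j + 1), wz_p)
            add(kp, kp, -(wr_m + wr_p + wz_m + wz_p))
            add(kp, ko, r)

            # omega equation: eta (omega_rr + omega_r/r + omega_zz - omega/r^2) = dFz/dr
            e = eta_n[i, j]
            add(ko, omg_of(i - 1, j), e * (wr_m + dr_m / r))
            add(ko, omg_of(i + 1, j), e * (wr_p + dr_p / r))
            add(ko, omg_of(i, j - 1), e * wz_m)
            add(ko, omg_of(i, j + 1), e * wz_p)
            add(ko, ko, -e * (wr_m + wr_p + wz_m + wz_p + 1.0 / r**2))
            b[ko] = dFdr[i, j]

    A = sp.csr_matrix((vals, (rows, cols)), shape=(2 * n, 2 * n))
    sol = spla.spsolve(A, b)
    return sol[:n].reshape(nj, ni).T


def _fluxes_from_psi(psi):
    """Face volume fluxes [m^3/s] on the fluid cell grid from nodal psi."""
    # z-faces: flux up through annulus between radial nodes i, i+1 at z-level j
    flux_z = 2.0 * np.pi * (psi[1:, :] - psi[:-1, :])
    # radial faces: flux outward through cylinder strip at r-node i between z j, j+1
    flux_r = -2.0 * np.pi * (psi[:, 1:] - psi[:, :-1])
    return flux_r, flux_z


def solve_steady_thermal_flow(
    geom: ChamberGeometry,
    laser: LaserSource,
    materials=(SAPPHIRE, WATER, GLASS),
    gravity: float = G_STANDARD,
    ambient: float = 298.15,
    rtol: float = 1e-4,
    max_iter: int = 40,
) -> ThermalFlowSolution:
    """Coupled steady temperature and buoyant Stokes flow.

    ``materials`` are (bottom solid, fluid, top solid). If the laser carries a
    calibration target, the source amplitude is rescaled each outer pass so the
    peak fluid temperature matches the target (within ``rtol`` relative).
    """
    mesh = Mesh(geom)
    mats_by_region = (materials[0], materials[1], materials[2])
    lam_z = np.array([mats_by_region[k].thermal_conductivity for k in mesh.material_index()])
    rho_cp = materials[1].density * materials[1].heat_capacity

    # nominal source field in fluid cells, z measured above the bottom interface
    src = np.zeros((mesh.nr, mesh.nz))
    zfl = mesh.zc[mesh.fluid_slice]
    src[:, mesh.fluid_slice] = laser.volumetric_source(
        mesh.rc[:, None], np.clip(zfl, 0.0, geom.fluid_height)[None, :],
        geom.fluid_height)

    target = laser.calibration_target_peak_T
    target_dT = (target + 273.15 - ambient) if target is not None else None

    flux_r = flux_z = None
    psi = np.zeros((mesh.nr + 1, mesh.jf1 - mesh.jf0 + 1))
    T_old = np.full((mesh.nr, mesh.nz), ambient)
    scale = 1.0
    it = 0
    for it in range(1, max_iter + 1):
        A, bvec = _assemble_temperature(mesh, lam_z, src, flux_r, flux_z,
                                        rho_cp, side_dirichlet=False)
        theta = spla.spsolve(A, bvec).reshape(mesh.nz, mesh.nr).T
        peak = theta[:, mesh.fluid_slice].max()
        if target_dT is not None:
            if peak <= 0:
                if laser.power == 0:
                    scale = 1.0
                else:
                    raise SolverError("calibration impossible: no heating")
            else:
                scale = target_dT / peak
        T = ambient + scale * theta
        if gravity != 0.0 and laser.power > 0:
            psi = _solve_stokes(mesh, T[:, mesh.fluid_slice], ambient, gravity)
            flux_r, flux_z = _fluxes_from_psi(psi)
        else:
            psi = np.zeros_like(psi)
            flux_r, flux_z = _fluxes_from_psi(psi)
        err = np.abs(T - T_old).max()
        T_old = T
        dT_ref = max(scale * peak, 1.0)
        if it >= 2 and err < rtol * dT_ref:
            break
    else:
        raise SolverError(
            f"thermal/flow fixed point did not converge in {max_iter} iterations "
            f"(last max |dT| = {err:.3e} K)")

    return ThermalFlowSolution(
        mesh=mesh, T=T_old, psi=psi, flux_r=flux_r, flux_z=flux_z,
        source_scale=scale, ambient=ambient, iterations=it)
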