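"""Axisymmetric incompressible flow with coupled erythrocyte transport.

Solves the saline-flushing problem on the annular vessel/catheter domain:
Reynolds-averaged continuity and momentum with a haematocrit-dependent
viscosity, plus a conservative scalar transport equation for the erythrocyte
phase.  Because the blood/saline density contrast is below 6% and the
erythrocyte diffusivity is vanishingly small (Peclet number ~1e11, advection
dominated), the velocity field is treated as solenoidal and the pressure
projection uses a constant reference density; the species and viscosity
fields remain fully composition-dependent.

Discretization: structured staggered (MAC) finite volumes in ``(r, z)``,
upwind-biased advection (second-order minmod-limited for the species,
first-order for momentum), Chorin pressure projection with a prefactorized
sparse Poisson solve, radial diffusion implicit (unconditionally stable
across the thin annular gap), axial diffusion explicit, time step adaptive
on an advective CFL limit.  The guiding catheter is embedded as a blocked
cell region with no-slip walls.

Turbulence fidelities:

* ``laminar`` — molecular transport only.
* ``laminar_eddy`` (default) — algebraic mixing-length eddy viscosity with
  a local-Reynolds-number transition ramp, plus eddy species diffusivity at
  turbulent Schmidt number 0.7.  This is the shipped desk-scale closure.
* ``rans_komega`` — Wilcox two-equation k-omega closure with a near-wall
  specific-dissipation floor (a reduced low-Reynolds treatment), same eddy
  species diffusivity.

The solver is fully deterministic: no random numbers anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .config import MM, Config, GeometryConfig, PhysicalConstants
from .mixture import (
    diffusion_coefficient,
    erythrocyte_density,
    mass_fraction_from_haematocrit,
    mixture_density,
    mixture_viscosity,
)
from .schedules import FlowWaveform

__all__ = [
    "Grid",
    "FlowState",
    "SpeciesField",
    "WallStressProfile",
    "FlushResult",
    "SolverDivergenceError",
    "solve_flushing",
    "wall_stress",
    "mass_balance_report",
    "annular_poiseuille_velocity",
    "annular_poiseuille_wall_shear",
]

# Wilcox (1988) k-omega closure constants
KW_ALPHA = 5.0 / 9.0
KW_BETA = 3.0 / 40.0
KW_BETA_STAR = 0.09
KW_SIGMA = 0.5
VON_KARMAN = 0.41
MIXING_LENGTH_CAP_FRACTION = 0.09  # of the annular gap
TRANSITION_RE_LOW = 500.0
TRANSITION_RE_HIGH = 2000.0
INLET_TURBULENCE_INTENSITY = 0.05


class SolverDivergenceError(RuntimeError):
    """The iterative solution blew up; carries the residual history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


# ----------------------------------------------------------------------
# grid
# ----------------------------------------------------------------------


@dataclass
class Grid:
    """Structured staggered grid on the annular flow domain (SI units)."""

    nr: int
    nz: int
    r_in: float
    r_out: float
    z_min: float
    z_max: float
    dr: float = field(init=False)
    dz: float = field(init=False)
    r_f: np.ndarray = field(init=False)  # radial faces, (nr+1,)
    r_c: np.ndarray = field(init=False)  # radial centers, (nr,)
    z_f: np.ndarray = field(init=False)
    z_c: np.ndarray = field(init=False)
    solid: np.ndarray = field(init=False)  # (nr, nz) blocked cells
    inlet_saline: np.ndarray = field(init=False)  # (nr,) bool rows at z_min
    inlet_blood: np.ndarray = field(init=False)
    wall_distance: np.ndarray = field(init=False)  # (nr, nz) m

    @classmethod
    def from_geometry(cls, geometry: GeometryConfig, nr: int, nz: int) -> "Grid":
        g = cls.__new__(cls)
        g.nr, g.nz = nr, nz
        g.r_in = geometry.oct_catheter_radius * MM
        g.r_out = geometry.vessel_inner_radius * MM
        g.z_min = geometry.blood_inlet_z * MM
        g.z_max = geometry.domain_z_max * MM
        g.dr = (g.r_out - g.r_in) / nr
        g.dz = (g.z_max - g.z_min) / nz
        g.r_f = g.r_in + g.dr * np.arange(nr + 1)
        g.r_c = 0.5 * (g.r_f[:-1] + g.r_f[1:])
        g.z_f = g.z_min + g.dz * np.arange(nz + 1)
        g.z_c = 0.5 * (g.z_f[:-1] + g.z_f[1:])
        gc_in = geometry.guiding_catheter_inner_radius * MM
        gc_out = geometry.guiding_catheter_outer_radius * MM
        gc_tip = geometry.guiding_catheter_outlet_z * MM
        in_wall_r = (g.r_c > gc_in) & (g.r_c < gc_out)
        g.solid = in_wall_r[:, None] & (g.z_c < gc_tip)[None, :]
        g.inlet_saline = (g.r_c < gc_in) & ~g.solid[:, 0]
        g.inlet_blood = (g.r_c > gc_out) & ~g.solid[:, 0]
        # distance to the nearest no-slip surface (catheter walls count;
        # the open inlet/outlet ends do not)
        fluid = ~g.solid
        padded = np.zeros((g.nr + 2, g.nz), dtype=bool)
        padded[1:-1, :] = fluid
        dist = ndimage.distance_transform_edt(padded, sampling=(g.dr, g.dz))
        g.wall_distance = dist[1:-1, :]
        return g

    @property
    def face_area_r(self) -> np.ndarray:  # (nr+1,) area of radial faces / dz
        return 2.0 * np.pi * self.r_f * self.dz

    @property
    def face_area_z(self) -> np.ndarray:  # (nr,) area of axial faces
        return 2.0 * np.pi * self.r_c * self.dr

    @property
    def cell_volume(self) -> np.ndarray:  # (nr,)
        return 2.0 * np.pi * self.r_c * self.dr * self.dz


# ----------------------------------------------------------------------
# state containers
# ----------------------------------------------------------------------


@dataclass
class FlowState:
    """Axisymmetric flow snapshot on the staggered grid (SI units)."""

    time: float
    u: np.ndarray  # radial velocity at radial faces, (nr+1, nz)
    w: np.ndarray  # axial velocity at axial faces, (nr, nz+1)
    p: np.ndarray  # pressure, (nr, nz)
    k: np.ndarray | None = None  # turbulence kinetic energy
    omega: np.ndarray | None = None  # specific dissipation
    nu_t: np.ndarray | None = None  # eddy (kinematic) viscosity


@dataclass
class SpeciesField:
    """Erythrocyte field snapshot: haematocrit and mixture properties."""

    time: float
    haematocrit: np.ndarray  # (nr, nz) volume fraction
    constants: PhysicalConstants

    @property
    def mass_fraction(self) -> np.ndarray:
        return mass_fraction_from_haematocrit(
            np.clip(self.haematocrit, 0.0, 1.0), self.constants
        )

    @property
    def density(self) -> np.ndarray:
        c = self.constants
        rho_e = erythrocyte_density(
            c.whole_blood_density, c.saline_density, c.whole_blood_haematocrit
        )
        return mixture_density(np.clip(self.haematocrit, 0.0, 1.0), rho_e, c.saline_density)

    @property
    def viscosity(self) -> np.ndarray:
        return mixture_viscosity(
            np.clip(self.haematocrit, 0.0, 1.0), self.constants.plasma_viscosity
        )

    @property
    def diffusivity(self) -> np.ndarray:
        return diffusion_coefficient(
            np.clip(self.haematocrit, 0.0, 1.0), constants=self.constants
        )


@dataclass
class WallStressProfile:
    """Stress exerted by the fluid on the wetted vessel inner wall.

    Shear is the axial traction component, positive in +z (forward flow
    drags the wall downstream); normal stress is pressure plus the viscous
    normal term, compression positive.
    """

    z_mm: np.ndarray
    shear: np.ndarray  # Pa
    normal: np.ndarray  # Pa
    time: float


# ----------------------------------------------------------------------
# small numerical kernels
# ----------------------------------------------------------------------


def _thomas_py(lower, diag, upper, rhs):
    """Solve tridiagonal systems along axis 0, vectorized over axis 1."""
    n = diag.shape[0]
    cp = np.empty_like(diag)
    dp = np.empty_like(rhs)
    cp[0] = upper[0] / diag[0]
    dp[0] = rhs[0] / diag[0]
    for i in range(1, n):
        denom = diag[i] - lower[i] * cp[i - 1]
        cp[i] = upper[i] / denom
        dp[i] = (rhs[i] - lower[i] * dp[i - 1]) / denom
    x = np.empty_like(rhs)
    x[-1] = dp[-1]
    for i in range(n - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]
    return x


try:  # compiled fast path; the NumPy fallback is numerically identical
    from numba import njit as _njit

    _thomas = _njit(cache=True)(_thomas_py)
    _thomas(*(np.ones((2, 2)),) * 3, np.ones((2, 2)))  # warm the JIT
except Exception:  # pragma: no cover - numba is an optional accelerator
    _thomas = _thomas_py


def _pad_edge(X: np.ndarray, axis: int, width: int) -> np.ndarray:
    """Edge-replicating pad along one axis (fast np.pad replacement)."""
    if axis == 1:
        out = np.empty((X.shape[0], X.shape[1] + 2 * width), dtype=X.dtype)
        out[:, width:-width] = X
        out[:, :width] = X[:, :1]
        out[:, -width:] = X[:, -1:]
    else:
        out = np.empty((X.shape[0] + 2 * width, X.shape[1]), dtype=X.dtype)
        out[width:-width, :] = X
        out[:width, :] = X[:1, :]
        out[-width:, :] = X[-1:, :]
    return out


def _minmod(a, b):
    return 0.5 * (np.sign(a) + np.sign(b)) * np.minimum(np.abs(a), np.abs(b))


def _muscl_faces(X: np.ndarray, vel: np.ndarray, axis: int) -> np.ndarray:
    """Second-order minmod-limited upwind face values along ``axis``.

    ``vel`` holds the face-normal velocities on all n+1 faces along the
    axis; boundary faces fall back to the clamped edge value.
    """
    Xp = _pad_edge(X, axis, 2)
    if axis == 1:
        A0, A1 = Xp[:, :-3], Xp[:, 1:-2]
        A2, A3 = Xp[:, 2:-1], Xp[:, 3:]
    else:
        A0, A1 = Xp[:-3, :], Xp[1:-2, :]
        A2, A3 = Xp[2:-1, :], Xp[3:, :]
    face_pos = A1 + 0.5 * _minmod(A2 - A1, A1 - A0)
    face_neg = A2 + 0.5 * _minmod(A1 - A2, A2 - A3)
    return np.where(vel >= 0.0, face_pos, face_neg)


def annular_poiseuille_velocity(r, a: float, b: float, flow_rate: float, mu: float):
    """Closed-form steady axial velocity in an annulus ``a <= r <= b`` (SI).

    Normalised so the profile carries ``flow_rate`` m^3/s; used as the
    analytic oracle for the solver's laminar limit.
    """
    r = np.asarray(r, dtype=float)
    log_ba = math.log(b / a)
    shape = b**2 - r**2 - (b**2 - a**2) * np.log(b / np.maximum(r, a * 1e-9)) / log_ba
    # integral of shape * 2 pi r dr over [a, b]
    rr = np.linspace(a, b, 20001)
    shp = b**2 - rr**2 - (b**2 - a**2) * np.log(b / rr) / log_ba
    q_shape = np.trapezoid(shp * 2.0 * np.pi * rr, rr)
    return flow_rate * shape / q_shape


def annular_poiseuille_wall_shear(a: float, b: float, flow_rate: float, mu: float) -> float:
    """Analytic wall-shear magnitude at the outer wall ``r = b`` (Pa)."""
    log_ba = math.log(b / a)
    rr = np.linspace(a, b, 20001)
    shp = b**2 - rr**2 - (b**2 - a**2) * np.log(b / rr) / log_ba
    q_shape = np.trapezoid(shp * 2.0 * np.pi * rr, rr)
    scale = flow_rate / q_shape
    dshape_dr = -2.0 * b + (b**2 - a**2) / (b * log_ba)
    return abs(mu * scale * dshape_dr)


# ----------------------------------------------------------------------
# the solver
# ----------------------------------------------------------------------


class _FlushSolver:
    def __init__(
        self,
        config: Config,
        blood_waveform: FlowWaveform | None,
        injection_waveform: FlowWaveform | None,
        fidelity: str,
        nr: int,
        nz: int,
        initial_haematocrit: float | np.ndarray | None = None,
    ):
        self.config = config
        self.constants = config.constants
        self.fidelity = fidelity
        self.grid = Grid.from_geometry(config.geometry, nr, nz)
        g = self.grid
        self.blood_waveform = blood_waveform
        self.injection_waveform = injection_waveform
        c = self.constants
        self.rho_e = erythrocyte_density(
            c.whole_blood_density, c.saline_density, c.whole_blood_haematocrit
        )
        self.rho_ref = c.whole_blood_density
        self.X_blood = c.whole_blood_haematocrit
        self.sc_t = config.solver.turbulent_schmidt
        self.nu_t_cap = config.solver.eddy_viscosity_cap
        self.cfl = config.solver.cfl

        fluid = ~g.solid
        self.fluid = fluid
        # blocked velocity faces
        ub = np.zeros((g.nr + 1, g.nz), dtype=bool)
        ub[0, :] = ub[-1, :] = True
        ub[1:-1, :] = g.solid[:-1, :] | g.solid[1:, :]
        self.u_block = ub
        wb = np.zeros((g.nr, g.nz + 1), dtype=bool)
        wb[:, 1:-1] = g.solid[:, :-1] | g.solid[:, 1:]
        wb[:, 0] = ~(g.inlet_saline | g.inlet_blood)
        wb[:, -1] = g.solid[:, -1]
        self.w_block = wb

        # inlet channel areas from the discrete face sum so the prescribed
        # plug velocity reproduces Q(t) exactly on the grid
        self.area_saline = float(g.face_area_z[g.inlet_saline].sum())
        self.area_blood = float(g.face_area_z[g.inlet_blood].sum())

        # mixing length and k-omega wall helpers
        gap = g.r_out - g.r_in
        self.mixing_length = np.minimum(
            VON_KARMAN * g.wall_distance, MIXING_LENGTH_CAP_FRACTION * gap
        )
        self.gap = gap
        self.near_wall = (g.wall_distance < 0.75 * g.dr) & fluid

        self._build_poisson()

        # state
        self.t = 0.0
        self.u = np.zeros((g.nr + 1, g.nz))
        self.w = np.zeros((g.nr, g.nz + 1))
        self.p = np.zeros((g.nr, g.nz))
        if initial_haematocrit is None:
            self.X = np.full((g.nr, g.nz), self.X_blood)
        else:
            self.X = np.broadcast_to(
                np.asarray(initial_haematocrit, dtype=float), (g.nr, g.nz)
            ).copy()
        self.nu_t = np.zeros((g.nr, g.nz))
        if fidelity == "rans_komega":
            self.k = np.full((g.nr, g.nz), 1e-8)
            self.omega = np.full((g.nr, g.nz), 100.0)
        else:
            self.k = None
            self.omega = None
        # erythrocyte bookkeeping (volume of erythrocyte phase, m^3)
        self.boundary_net = 0.0  # cumulative net influx since last frame

    # -- assembly ------------------------------------------------------

    def _build_poisson(self) -> None:
        g = self.grid
        nr, nz = g.nr, g.nz
        idx = np.arange(nr * nz).reshape(nr, nz)
        fluid = self.fluid
        rows, cols, vals = [], [], []
        diag = np.zeros((nr, nz))
        inv_rho = 1.0 / self.rho_ref
        # radial couplings (flux divergence in cell i carries 1/r_c[i])
        open_r = fluid[:-1, :] & fluid[1:, :]
        i_idx, j_idx = np.nonzero(open_r)
        t_lo = inv_rho * g.r_f[i_idx + 1] / (g.r_c[i_idx] * g.dr**2)
        t_hi = inv_rho * g.r_f[i_idx + 1] / (g.r_c[i_idx + 1] * g.dr**2)
        rows += [idx[i_idx, j_idx], idx[i_idx + 1, j_idx]]
        cols += [idx[i_idx + 1, j_idx], idx[i_idx, j_idx]]
        vals += [t_lo, t_hi]
        np.add.at(diag, (i_idx, j_idx), -t_lo)
        np.add.at(diag, (i_idx + 1, j_idx), -t_hi)
        # axial couplings
        open_z = fluid[:, :-1] & fluid[:, 1:]
        i_idx, j_idx = np.nonzero(open_z)
        t_z = np.full(i_idx.shape, inv_rho / g.dz**2)
        rows += [idx[i_idx, j_idx], idx[i_idx, j_idx + 1]]
        cols += [idx[i_idx, j_idx + 1], idx[i_idx, j_idx]]
        vals += [t_z, t_z]
        np.add.at(diag, (i_idx, j_idx), -t_z)
        np.add.at(diag, (i_idx, j_idx + 1), -t_z)
        # outlet Dirichlet (p = 0 at the z_max face, half-cell distance)
        out_rows = np.nonzero(fluid[:, -1])[0]
        diag[out_rows, -1] -= 2.0 * inv_rho / g.dz**2
        # solid cells: identity
        diag[~fluid] = 1.0
        rows.append(idx.ravel())
        cols.append(idx.ravel())
        vals.append(diag.ravel())
        A = sp.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(nr * nz, nr * nz),
        )
        self._poisson_lu = spla.splu(A)

    # -- boundary data -------------------------------------------------

    def _inlet_velocities(self, t: float) -> tuple[float, float]:
        q_s = self.injection_waveform(t) * 1e-6 if self.injection_waveform else 0.0
        q_b = self.blood_waveform(t) * 1e-6 if self.blood_waveform else 0.0
        w_s = q_s / self.area_saline if self.area_saline > 0 else 0.0
        w_b = q_b / self.area_blood if self.area_blood > 0 else 0.0
        return w_s, w_b

    def _apply_inlet(self, w: np.ndarray, t: float) -> None:
        g = self.grid
        w_s, w_b = self._inlet_velocities(t)
        w[:, 0] = 0.0
        w[g.inlet_saline, 0] = w_s
        w[g.inlet_blood, 0] = w_b

    # -- physics helpers -----------------------------------------------

    def _inlet_reynolds(self) -> float:
        """Instantaneous duct Reynolds number of the combined inflow."""
        w_s, w_b = self._inlet_velocities(self.t)
        q_total = abs(w_s) * self.area_saline + abs(w_b) * self.area_blood
        c = self.constants
        return (
            4.0
            * c.saline_density
            * q_total
            / (np.pi * 2.0 * self.grid.r_out * c.plasma_viscosity)
        )

    def _cell_velocities(self):
        uc = 0.5 * (self.u[:-1, :] + self.u[1:, :])
        wc = 0.5 * (self.w[:, :-1] + self.w[:, 1:])
        return uc, wc

    def _strain_rate(self):
        g = self.grid
        # exact face-difference gradients on the staggered grid
        dudr = (self.u[1:, :] - self.u[:-1, :]) / g.dr
        dwdz = (self.w[:, 1:] - self.w[:, :-1]) / g.dz
        uc = 0.5 * (self.u[:-1, :] + self.u[1:, :])
        wc = 0.5 * (self.w[:, :-1] + self.w[:, 1:])
        wp = _pad_edge(wc, 0, 1)
        dwdr = (wp[2:, :] - wp[:-2, :]) / (2.0 * g.dr)
        up = _pad_edge(uc, 1, 1)
        dudz = (up[:, 2:] - up[:, :-2]) / (2.0 * g.dz)
        hoop = uc / g.r_c[:, None]
        return np.sqrt(
            2.0 * (dudr**2 + dwdz**2 + hoop**2) + (dwdr + dudz) ** 2
        )

    def _update_eddy_viscosity(self) -> None:
        if self.fidelity == "laminar":
            self.nu_t[:] = 0.0
            return
        g = self.grid
        Xc = np.clip(self.X, 0.0, 1.0)
        nu_mol = mixture_viscosity(Xc, self.constants.plasma_viscosity) / np.maximum(
            mixture_density(Xc, self.rho_e, self.constants.saline_density), 1.0
        )
        if self.fidelity == "rans_komega":
            nu_t = self.k / np.maximum(self.omega, 1e-3)
        else:
            S = self._strain_rate()
            # regime-level transition: the closure activates as the
            # instantaneous duct Reynolds number (built from the inlet flow
            # rates, the lumen diameter and saline properties) crosses the
            # transitional range; low-Re runs stay laminar everywhere
            ramp = np.clip(
                (self._inlet_reynolds() - TRANSITION_RE_LOW)
                / (TRANSITION_RE_HIGH - TRANSITION_RE_LOW),
                0.0,
                1.0,
            )
            nu_t = self.mixing_length**2 * S * ramp
        self.nu_t = np.where(self.fluid, np.minimum(nu_t, self.nu_t_cap), 0.0)

    def _effective_viscosity(self):
        Xc = np.clip(self.X, 0.0, 1.0)
        rho = mixture_density(Xc, self.rho_e, self.constants.saline_density)
        nu_mol = mixture_viscosity(Xc, self.constants.plasma_viscosity) / rho
        return nu_mol + self.nu_t

    def _effective_diffusivity(self):
        Xc = np.clip(self.X, 0.0, 1.0)
        D_mol = diffusion_coefficient(Xc, constants=self.constants)
        if self.fidelity == "laminar":
            return D_mol
        return D_mol + self.nu_t / self.sc_t

    # -- advection -----------------------------------------------------

    def _advect_momentum(self, dt: float):
        g = self.grid
        u, w = self.u, self.w
        dr, dz = g.dr, g.dz
        # radial velocity on interior radial faces
        um = u[1:-1, :]
        dudr = np.where(
            um >= 0.0, (um - u[:-2, :]) / dr, (u[2:, :] - um) / dr
        )
        w_u = 0.25 * (w[:-1, :-1] + w[:-1, 1:] + w[1:, :-1] + w[1:, 1:])
        ump = _pad_edge(um, 1, 1)
        dudz = np.where(
            w_u >= 0.0,
            (ump[:, 1:-1] - ump[:, :-2]) / dz,
            (ump[:, 2:] - ump[:, 1:-1]) / dz,
        )
        u_new = u.copy()
        u_new[1:-1, :] -= dt * (um * dudr + w_u * dudz)
        # axial velocity on interior axial faces
        wm = w[:, 1:-1]
        dwdz = np.where(
            wm >= 0.0, (wm - w[:, :-2]) / dz, (w[:, 2:] - wm) / dz
        )
        u_w = 0.25 * (u[:-1, :-1] + u[1:, :-1] + u[:-1, 1:] + u[1:, 1:])
        wmp = _pad_edge(wm, 0, 1)
        dwdr = np.where(
            u_w >= 0.0,
            (wmp[1:-1, :] - wmp[:-2, :]) / dr,
            (wmp[2:, :] - wmp[1:-1, :]) / dr,
        )
        w_new = w.copy()
        w_new[:, 1:-1] -= dt * (u_w * dwdr + wm * dwdz)
        return u_new, w_new

    def _advect_scalar(self, X, dt: float, inlet_values: np.ndarray):
        """Conservative minmod-limited transport; returns (X_new, net_influx).

        ``inlet_values`` gives the inflow composition per inlet row; outflow
        (including any backflow at the outlet) uses the interior value.
        """
        g = self.grid
        u, w = self.u, self.w
        fr = _muscl_faces(X, u, axis=0)
        fz = _muscl_faces(X, w, axis=1)
        w_in = w[:, 0]
        fz[:, 0] = np.where(w_in > 0, inlet_values, X[:, 0])
        fz[:, -1] = X[:, -1]
        F_r = u * g.face_area_r[:, None] * fr
        F_z = w * g.face_area_z[:, None] * fz
        F_r[self.u_block] = 0.0
        F_z[:, 1:][self.w_block[:, 1:]] = 0.0
        div = (F_r[1:, :] - F_r[:-1, :]) + (F_z[:, 1:] - F_z[:, :-1])
        X_new = X - dt * div / g.cell_volume[:, None]
        X_new[~self.fluid] = X[~self.fluid]
        net_in = float(F_z[:, 0].sum() - F_z[:, -1].sum())  # m^3 of phase / s
        return X_new, net_in

    # -- diffusion -----------------------------------------------------

    def _diffuse_scalar(self, X, D_cell, dt: float):
        """No-flux implicit radial + explicit axial diffusion (conservative)."""
        g = self.grid
        # axial explicit
        Dz = np.zeros((g.nr, g.nz + 1))
        Dz[:, 1:-1] = 0.5 * (D_cell[:, :-1] + D_cell[:, 1:])
        Dz[self.w_block] = 0.0
        Dz[:, 0] = 0.0
        Dz[:, -1] = 0.0
        flux = Dz[:, 1:-1] * (X[:, 1:] - X[:, :-1]) / g.dz
        div = np.zeros_like(X)
        div[:, :-1] += flux
        div[:, 1:] -= flux
        X = X + dt * div / g.dz
        # radial implicit
        Df = np.zeros((g.nr + 1, g.nz))
        Df[1:-1, :] = 0.5 * (D_cell[:-1, :] + D_cell[1:, :])
        Df[self.u_block] = 0.0
        beta = g.r_f[:, None] * Df / (g.dr**2)
        lower = -dt * beta[:-1, :] / g.r_c[:, None]
        upper = -dt * beta[1:, :] / g.r_c[:, None]
        diag = 1.0 - lower - upper
        rhs = X.copy()
        solidm = ~self.fluid
        lower[solidm] = 0.0
        upper[solidm] = 0.0
        diag[solidm] = 1.0
        return _thomas(lower, diag, upper, rhs)

    def _diffuse_u(self, u, nu_cell, dt: float):
        g = self.grid
        # axial explicit with clamped ends
        nu_u = np.zeros((g.nr + 1, g.nz))
        nu_u[1:-1, :] = 0.5 * (nu_cell[:-1, :] + nu_cell[1:, :])
        up = _pad_edge(u, 1, 1)
        u = u + dt * nu_u * (up[:, 2:] - 2.0 * u + up[:, :-2]) / g.dz**2
        # radial implicit; interior faces couple through the cell centers
        lower = np.zeros_like(u)
        upper = np.zeros_like(u)
        diag = np.ones_like(u)
        i = np.arange(1, g.nr)
        coef_lo = dt * g.r_c[i - 1, None] * nu_cell[i - 1, :] / (
            g.r_f[i, None] * g.dr**2
        )
        coef_hi = dt * g.r_c[i, None] * nu_cell[i, :] / (g.r_f[i, None] * g.dr**2)
        lower[1:-1, :] = -coef_lo
        upper[1:-1, :] = -coef_hi
        diag[1:-1, :] = (
            1.0
            + coef_lo
            + coef_hi
            + dt * nu_u[1:-1, :] / g.r_f[1:-1, None] ** 2
        )
        blk = self.u_block
        lower[blk] = 0.0
        upper[blk] = 0.0
        diag[blk] = 1.0
        rhs = u.copy()
        rhs[blk] = 0.0
        return _thomas(lower, diag, upper, rhs)

    def _diffuse_w(self, w, nu_cell, nu_mol_cell, dt: float):
        g = self.grid
        nu_w = np.zeros((g.nr, g.nz + 1))
        nu_w[:, 1:-1] = 0.5 * (nu_cell[:, :-1] + nu_cell[:, 1:])
        nu_w[:, 0] = nu_cell[:, 0]
        nu_w[:, -1] = nu_cell[:, -1]
        nu_mol_w = np.zeros((g.nr, g.nz + 1))
        nu_mol_w[:, 1:-1] = 0.5 * (nu_mol_cell[:, :-1] + nu_mol_cell[:, 1:])
        nu_mol_w[:, 0] = nu_mol_cell[:, 0]
        nu_mol_w[:, -1] = nu_mol_cell[:, -1]
        # axial explicit on interior faces (inlet Dirichlet, outlet clamped)
        w2 = w.copy()
        w2[:, 1:-1] += (
            dt
            * nu_w[:, 1:-1]
            * (w[:, 2:] - 2.0 * w[:, 1:-1] + w[:, :-2])
            / g.dz**2
        )
        w = w2
        # radial implicit per axial-face column, with no-slip wall treatment
        blk = self.w_block
        nu_face = np.zeros((g.nr + 1, g.nz + 1))
        nu_face[1:-1, :] = 0.5 * (nu_w[:-1, :] + nu_w[1:, :])
        open_face = np.zeros((g.nr + 1, g.nz + 1), dtype=bool)
        open_face[1:-1, :] = ~blk[:-1, :] & ~blk[1:, :]
        beta = g.r_f[:, None] * nu_face / g.dr**2
        beta_open = np.where(open_face, beta, 0.0)
        lower = -dt * beta_open[:-1, :] / g.r_c[:, None]
        upper = -dt * beta_open[1:, :] / g.r_c[:, None]
        diag = 1.0 - lower - upper
        # no-slip wall faces: one-sided quadratic wall flux through the two
        # near-wall cells (exact for a parabolic profile, matching the
        # wall-stress extraction) with molecular viscosity at the wall;
        # falls back to the half-cell linear flux in single-cell channels
        pad_lo = np.ones((g.nr, g.nz + 1), dtype=bool)
        pad_lo[1:, :] = blk[:-1, :]
        pad_hi = np.ones((g.nr, g.nz + 1), dtype=bool)
        pad_hi[:-1, :] = blk[1:, :]
        wall_lo = ~blk & pad_lo
        wall_hi = ~blk & pad_hi
        gam_lo = dt * g.r_f[:-1, None] * nu_mol_w / (g.r_c[:, None] * g.dr**2)
        gam_hi = dt * g.r_f[1:, None] * nu_mol_w / (g.r_c[:, None] * g.dr**2)
        quad_lo = wall_lo & ~pad_hi  # second neighbor (above) is fluid
        quad_hi = wall_hi & ~pad_lo  # second neighbor (below) is fluid
        lin_lo = wall_lo & ~quad_lo
        lin_hi = wall_hi & ~quad_hi
        diag += np.where(quad_lo, 3.0 * gam_lo, 0.0)
        upper += np.where(quad_lo, -gam_lo / 3.0, 0.0)
        diag += np.where(quad_hi, 3.0 * gam_hi, 0.0)
        lower += np.where(quad_hi, -gam_hi / 3.0, 0.0)
        diag += np.where(lin_lo, 2.0 * gam_lo, 0.0)
        diag += np.where(lin_hi, 2.0 * gam_hi, 0.0)
        lower[blk] = 0.0
        upper[blk] = 0.0
        diag[blk] = 1.0
        rhs = w.copy()
        rhs[blk] = 0.0
        # keep the prescribed inlet column fixed
        lower[:, 0] = upper[:, 0] = 0.0
        diag[:, 0] = 1.0
        rhs[:, 0] = w[:, 0]
        return _thomas(lower, diag, upper, rhs)

    # -- turbulence transport ------------------------------------------

    def _step_komega(self, dt: float) -> None:
        g = self.grid
        nu_mol = self._effective_viscosity() - self.nu_t
        S = self._strain_rate()
        nu_t = np.minimum(self.k / np.maximum(self.omega, 1e-3), self.nu_t_cap)
        # standard production limiter (shear-layer / stagnation anomaly fix)
        prod = np.minimum(nu_t * S**2, 10.0 * KW_BETA_STAR * self.k * self.omega)
        # inlet values from 5% turbulence intensity
        w_s, w_b = self._inlet_velocities(self.t)
        k_in = np.zeros(g.nr)
        k_in[g.inlet_saline] = 1.5 * (INLET_TURBULENCE_INTENSITY * abs(w_s)) ** 2
        k_in[g.inlet_blood] = 1.5 * (INLET_TURBULENCE_INTENSITY * abs(w_b)) ** 2
        len_scale = 0.07 * self.gap
        om_in = np.sqrt(np.maximum(k_in, 1e-12)) / (KW_BETA_STAR**0.25 * len_scale)

        k_new, _ = self._advect_scalar(self.k, dt, k_in)
        om_new, _ = self._advect_scalar(self.omega, dt, om_in)
        k_new = (k_new + dt * prod) / (1.0 + dt * KW_BETA_STAR * self.omega)
        om_new = (om_new + dt * KW_ALPHA * S**2) / (1.0 + dt * KW_BETA * self.omega)
        # near-wall specific-dissipation floor (reduced low-Re treatment)
        om_wall = 6.0 * nu_mol / (KW_BETA * (0.5 * g.dr) ** 2)
        om_new = np.where(self.near_wall, np.maximum(om_new, om_wall), om_new)
        k_new = self._diffuse_scalar(k_new, nu_mol + KW_SIGMA * self.nu_t, dt)
        om_new = self._diffuse_scalar(om_new, nu_mol + KW_SIGMA * self.nu_t, dt)
        self.k = np.maximum(k_new, 1e-12)
        self.omega = np.maximum(om_new, 1e-2)

    # -- one sub-step --------------------------------------------------

    def _substep(self, dt: float) -> None:
        g = self.grid
        t_new = self.t + dt
        nu_eff = self._effective_viscosity()

        u_star, w_star = self._advect_momentum(dt)
        # incremental pressure-correction: the predictor carries the current
        # pressure gradient so the steady momentum balance (including the
        # near-wall flux rows) holds without splitting error
        inv_rho = 1.0 / self.rho_ref
        dpdr = (self.p[1:, :] - self.p[:-1, :]) / g.dr
        u_star[1:-1, :] -= np.where(
            self.u_block[1:-1, :], 0.0, dt * inv_rho * dpdr
        )
        dpdz = (self.p[:, 1:] - self.p[:, :-1]) / g.dz
        w_star[:, 1:-1] -= np.where(
            self.w_block[:, 1:-1], 0.0, dt * inv_rho * dpdz
        )
        w_star[:, -1] += np.where(
            self.w_block[:, -1], 0.0, 2.0 * dt * inv_rho * self.p[:, -1] / g.dz
        )
        u_star[self.u_block] = 0.0
        self._apply_inlet(w_star, t_new)
        w_star[:, 1:][self.w_block[:, 1:]] = 0.0

        u_star = self._diffuse_u(u_star, nu_eff, dt)
        w_star = self._diffuse_w(w_star, nu_eff, nu_eff - self.nu_t, dt)
        u_star[self.u_block] = 0.0
        self._apply_inlet(w_star, t_new)
        w_star[:, -1] = w_star[:, -2]
        w_star[self.w_block[:, -1], -1] = 0.0

        # projection
        div = (
            g.r_f[1:, None] * u_star[1:, :] - g.r_f[:-1, None] * u_star[:-1, :]
        ) / (g.r_c[:, None] * g.dr) + (w_star[:, 1:] - w_star[:, :-1]) / g.dz
        rhs = (div / dt).ravel()
        rhs[(~self.fluid).ravel()] = 0.0
        psi = self._poisson_lu.solve(rhs).reshape(g.nr, g.nz)
        du = dt * inv_rho * (psi[1:, :] - psi[:-1, :]) / g.dr
        u_star[1:-1, :] -= np.where(self.u_block[1:-1, :], 0.0, du)
        dw = dt * inv_rho * (psi[:, 1:] - psi[:, :-1]) / g.dz
        w_star[:, 1:-1] -= np.where(self.w_block[:, 1:-1], 0.0, dw)
        w_star[:, -1] += np.where(
            self.w_block[:, -1], 0.0, 2.0 * dt * inv_rho * psi[:, -1] / g.dz
        )
        self.u, self.w = u_star, w_star
        self.p = self.p + psi
        self.p[~self.fluid] = 0.0
        if not np.isfinite(self.w).all() or np.abs(self.w).max() > 1e3:
            raise SolverDivergenceError(
                f"velocity field diverged at t = {t_new:.4f} s",
                [float(np.abs(self.w).max())],
            )

        # species transport on the corrected (solenoidal) field
        g_inlet_X = np.where(self.grid.inlet_blood, self.X_blood, 0.0)
        X_new, net_in = self._advect_scalar(self.X, dt, g_inlet_X)
        self.boundary_net += net_in * dt
        D_eff = self._effective_diffusivity()
        self.X = self._diffuse_scalar(X_new, D_eff, dt)

        if self.fidelity == "rans_komega":
            self._step_komega(dt)
        self._update_eddy_viscosity()
        self.t = t_new

    def _frame_dt_subdivision(self, frame_dt: float) -> int:
        g = self.grid
        w_s, w_b = self._inlet_velocities(self.t)
        w_s2, w_b2 = self._inlet_velocities(self.t + frame_dt)
        vmax_z = max(
            float(np.abs(self.w).max()), abs(w_s), abs(w_b), abs(w_s2), abs(w_b2), 1e-6
        )
        vmax_r = max(float(np.abs(self.u).max()), 1e-6)
        dt_adv = self.cfl / (vmax_r / g.dr + vmax_z / g.dz)
        d_max = max(
            float(self._effective_viscosity().max()),
            float(self._effective_diffusivity().max()),
        )
        dt_diff_z = 0.25 * g.dz**2 / d_max
        dt = min(dt_adv, dt_diff_z)
        if self.config.clock.solver_dt is not None:
            dt = min(dt, self.config.clock.solver_dt)
        return max(1, int(math.ceil(1.2 * frame_dt / dt)))

    def advance_frame(self, frame_dt: float) -> None:
        n_sub = self._frame_dt_subdivision(frame_dt)
        dt = frame_dt / n_sub
        for _ in range(n_sub):
            self._substep(dt)

    # -- observations --------------------------------------------------

    def erythrocyte_volume(self) -> float:
        return float((self.X * self.grid.cell_volume[:, None])[self.fluid].sum())

    def wall_profiles(self):
        g = self.grid
        wc = 0.5 * (self.w[:, :-1] + self.w[:, 1:])
        Xw = np.clip(self.X[-1, :], 0.0, 1.0)
        mu_w = mixture_viscosity(Xw, self.constants.plasma_viscosity)
        # quadratic one-sided fit through the two near-wall cells (exact for
        # a parabolic profile): dw/dr|wall = -(9 w1 - w2) / (3 dr)
        shear = mu_w * (9.0 * wc[-1, :] - wc[-2, :]) / (3.0 * g.dr)
        # viscous normal component from the radial velocity gradient
        dudr_wall = (self.u[-1, :] - self.u[-2, :]) / g.dr
        normal = self.p[-1, :] - 2.0 * mu_w * dudr_wall
        return shear, normal

    def haematocrit_column(self, r_mm: np.ndarray, z_mm: float) -> np.ndarray:
        return _interp_column(self.grid, self.X, r_mm, z_mm)

    def flow_state(self) -> FlowState:
        return FlowState(
            time=self.t,
            u=self.u.copy(),
            w=self.w.copy(),
            p=self.p.copy(),
            k=None if self.k is None else self.k.copy(),
            omega=None if self.omega is None else self.omega.copy(),
            nu_t=self.nu_t.copy(),
        )


def _interp_column(grid: Grid, X: np.ndarray, r_mm, z_mm: float) -> np.ndarray:
    """Bilinear sample of a cell field along radius at one axial station."""
    z = float(z_mm) * MM
    zc = grid.z_c
    j = int(np.clip(np.searchsorted(zc, z) - 1, 0, grid.nz - 2))
    frac = np.clip((z - zc[j]) / (zc[j + 1] - zc[j]), 0.0, 1.0)
    col = (1.0 - frac) * X[:, j] + frac * X[:, j + 1]
    r = np.asarray(r_mm, dtype=float) * MM
    return np.interp(r, grid.r_c, col)


# ----------------------------------------------------------------------
# results container and driver
# ----------------------------------------------------------------------


@dataclass
class FlushResult:
    """Frame-resolved output of one flushing simulation."""

    grid: Grid
    constants: PhysicalConstants
    times: np.ndarray  # (n_frames,)
    haematocrit_frames: np.ndarray  # (n_frames, nr, nz)
    wall_shear: np.ndarray  # (n_frames, nz) Pa
    wall_normal: np.ndarray  # (n_frames, nz) Pa
    mass_total: np.ndarray  # (n_frames,) erythrocyte mass, kg
    boundary_net_mass: np.ndarray  # (n_frames,) net boundary influx per frame, kg
    final_state: FlowState
    states: list[FlowState] | None = None
    fidelity: str = "laminar_eddy"

    @property
    def frame_dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    def frame_index(self, t: float) -> int:
        return int(np.clip(np.searchsorted(self.times, t - 1e-9), 0, self.times.size - 1))

    def haematocrit(self, r_mm, z_mm: float, t: float) -> np.ndarray:
        """Local haematocrit at ``(r mm, z mm)`` from the nearest frame."""
        i = int(np.clip(np.round((t - self.times[0]) / max(self.frame_dt, 1e-12)), 0, self.times.size - 1))
        return _interp_column(self.grid, self.haematocrit_frames[i], r_mm, z_mm)

    def species_field(self, t: float) -> SpeciesField:
        i = self.frame_index(t)
        return SpeciesField(
            time=float(self.times[i]),
            haematocrit=self.haematocrit_frames[i],
            constants=self.constants,
        )

    def wall_stress_profile(self, t: float) -> WallStressProfile:
        i = self.frame_index(t)
        return WallStressProfile(
            z_mm=self.grid.z_c / MM,
            shear=self.wall_shear[i],
            normal=self.wall_normal[i],
            time=float(self.times[i]),
        )

    def lumen_mean_haematocrit(self, z_lo_mm: float, z_hi_mm: float) -> np.ndarray:
        """Volume-weighted lumen-average haematocrit in an axial window."""
        g = self.grid
        sel = (g.z_c >= z_lo_mm * MM) & (g.z_c <= z_hi_mm * MM)
        weights = (g.cell_volume[:, None] * np.ones(g.nz)[None, :])[:, sel]
        fl = (~g.solid)[:, sel]
        w = np.where(fl, weights, 0.0)
        vals = self.haematocrit_frames[:, :, sel]
        return (vals * w).sum(axis=(1, 2)) / w.sum()

    def to_xarray(self):
        import xarray as xr

        g = self.grid
        return xr.Dataset(
            {
                "haematocrit": ( ("t", "r", "z"), self.haematocrit_frames),
                "wall_shear": (("t", "z"), self.wall_shear),
                "wall_normal": (("t", "z"), self.wall_normal),
            },
            coords={
                "t": ("t", self.times, {"units": "s"}),
                "r": ("r", g.r_c / MM, {"units": "mm"}),
                "z": ("z", g.z_c / MM, {"units": "mm"}),
            },
            attrs={"fidelity": self.fidelity},
        )


def solve_flushing(
    config: Config,
    blood_waveform: FlowWaveform | None = None,
    injection_waveform: FlowWaveform | None = None,
    fidelity: str | None = None,
    nr: int | None = None,
    nz: int | None = None,
    t_end: float | None = None,
    monitor=None,
    store_flow: bool | None = None,
    initial_haematocrit: float | np.ndarray | None = None,
) -> FlushResult:
    """Run the coupled flushing simulation and return frame snapshots.

    ``monitor(t, solver)`` is called after each frame and may return a new
    end time (e.g. to stop once a pull-back completes); returning ``None``
    keeps the current horizon.  Snapshots are taken every ``frame_dt``.
    """
    config.validate()
    fidelity = fidelity if fidelity is not None else config.solver.fidelity
    nr = nr if nr is not None else config.solver.nr
    nz = nz if nz is not None else config.solver.nz
    store_flow = store_flow if store_flow is not None else config.solver.store_flow
    solver = _FlushSolver(
        config,
        blood_waveform,
        injection_waveform,
        fidelity,
        nr,
        nz,
        initial_haematocrit=initial_haematocrit,
    )
    frame_dt = config.clock.frame_dt
    horizon = config.clock.total_time if t_end is None else t_end

    rho_e = solver.rho_e
    times = [0.0]
    frames = [solver.X.copy()]
    shear0, normal0 = solver.wall_profiles()
    shears, normals = [shear0], [normal0]
    mass = [solver.erythrocyte_volume() * rho_e]
    net = [0.0]
    states = [solver.flow_state()] if store_flow else None

    while solver.t < horizon - 1e-9:
        solver.boundary_net = 0.0
        solver.advance_frame(frame_dt)
        times.append(solver.t)
        frames.append(solver.X.copy())
        s, n = solver.wall_profiles()
        shears.append(s)
        normals.append(n)
        mass.append(solver.erythrocyte_volume() * rho_e)
        net.append(solver.boundary_net * rho_e)
        if states is not None:
            states.append(solver.flow_state())
        if monitor is not None:
            new_end = monitor(solver.t, solver)
            if new_end is not None:
                horizon = min(new_end, config.clock.total_time)

    return FlushResult(
        grid=solver.grid,
        constants=config.constants,
        times=np.array(times),
        haematocrit_frames=np.array(frames),
        wall_shear=np.array(shears),
        wall_normal=np.array(normals),
        mass_total=np.array(mass),
        boundary_net_mass=np.array(net),
        final_state=solver.flow_state(),
        states=states,
        fidelity=fidelity,
    )


def wall_stress(
    state: FlowState,
    grid: Grid,
    haematocrit: np.ndarray,
    constants: PhysicalConstants,
) -> WallStressProfile:
    """Wall shear/normal stress profile from a flow snapshot.

    Shear uses a one-sided quadratic fit through the two near-wall cells
    (exact for a parabolic profile); sign is positive for drag in +z.
    """
    wc = 0.5 * (state.w[:, :-1] + state.w[:, 1:])
    Xw = np.clip(haematocrit[-1, :], 0.0, 1.0)
    mu_w = mixture_viscosity(Xw, constants.plasma_viscosity)
    shear = mu_w * (9.0 * wc[-1, :] - wc[-2, :]) / (3.0 * grid.dr)
    dudr_wall = (state.u[-1, :] - state.u[-2, :]) / grid.dr
    normal = state.p[-1, :] - 2.0 * mu_w * dudr_wall
    return WallStressProfile(
        z_mm=grid.z_c / MM, shear=shear, normal=normal, time=state.time
    )


def mass_balance_report(result: FlushResult) -> np.ndarray:
    """Relative per-frame erythrocyte mass-balance error.

    Compares the change of total erythrocyte mass between consecutive frames
    with the net boundary influx accumulated by the advection fluxes, scaled
    by a characteristic boundary mass rate.
    """
    dm = np.diff(result.mass_total)
    net = result.boundary_net_mass[1:]
    rho_e = erythrocyte_density(
        result.constants.whole_blood_density,
        result.constants.saline_density,
        result.constants.whole_blood_haematocrit,
    )
    # characteristic rate: whole blood erythrocytes crossing at 1 mL/s
    char_rate = rho_e * result.constants.whole_blood_haematocrit * 1e-6
    return np.abs(dm - net) / (char_rate * max(result.frame_dt, 1e-12))
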