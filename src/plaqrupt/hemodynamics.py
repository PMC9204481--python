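"""Endothelial shear stress and pressure drop in idealized stenoses.

Two desk-scale surrogates for full 3D CFD:

* a quasi-1D Poiseuille model, tau(z) = 4 mu Q / (pi R(z)^3) with the
  pressure integrated backward from the outlet via
  dp/dz = -8 mu Q / (pi R^4); and
* a steady axisymmetric Navier-Stokes solver in stream-function /
  vorticity form on a boundary-fitted grid (eta = r / R(z)), which
  captures the convective wall-shear amplification a converging
  stenosis produces above the quasi-1D value.

Both assume steady laminar flow of a homogeneous Newtonian fluid
(viscosity 0.0035 Pa s, density 1050 kg/m^3), a parabolic inlet profile
carrying 1 ml/s, a rigid no-slip wall, and 100 mmHg at the outlet.
Strut-scale flow disturbance is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.integrate import simpson
from scipy.interpolate import CubicSpline
from scipy.sparse.linalg import splu

from .geometry import IdealizedGeometry

__all__ = [
    "FlowConditions",
    "FlowSolution",
    "poiseuille_wss",
    "poiseuille_pressure_drop",
    "quasi1d_flow",
    "axisymmetric_ns_solve",
    "mesh_convergence",
    "Quasi1DFlow",
    "AxisymmetricFlow",
    "MMHG_PA",
]

#: mmHg to Pa conversion.
MMHG_PA = 133.322


@dataclass(frozen=True)
class FlowConditions:
    """Boundary conditions and fluid properties (coronary defaults)."""

    flow_rate_ml_s: float = 1.0
    viscosity_pa_s: float = 0.0035
    density_kg_m3: float = 1050.0
    outlet_pressure_mmhg: float = 100.0
    high_ess_pa: float = 7.0

    @property
    def q_m3_s(self) -> float:
        return self.flow_rate_ml_s * 1e-6


@dataclass
class FlowSolution:
    """Wall shear stress and pressure along the lesion, with summaries."""

    z_mm: np.ndarray
    wss_pa: np.ndarray
    pressure_mmhg: np.ndarray
    solver: str
    tau_max_pa: float = 0.0
    tau_min_pa: float = 0.0
    tau_max_z_mm: float = 0.0
    pressure_drop_mmhg: float = 0.0
    pct_area_high_ess: float = 0.0
    tau_at_min_cap_pa: Optional[float] = None
    mass_flux_error_pct: float = 0.0
    velocity: Optional[np.ndarray] = None  # (n_z, n_r) axial velocity, m/s
    eta: Optional[np.ndarray] = None
    residual_history: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"solver:             {self.solver}",
            f"tau_max (Pa):       {self.tau_max_pa:.3f} at z = {self.tau_max_z_mm:.2f} mm",
            f"tau_min (Pa):       {self.tau_min_pa:.3f}",
            f"pressure drop:      {self.pressure_drop_mmhg:.3f} mmHg",
            f"wall area > {FlowConditions().high_ess_pa:.0f} Pa: {self.pct_area_high_ess:.1f} %",
        ]
        if self.tau_at_min_cap_pa is not None:
            lines.append(f"tau at min cap:     {self.tau_at_min_cap_pa:.3f} Pa")
        return "\n".join(lines)


def poiseuille_wss(radius_mm: float, conditions: FlowConditions | None = None) -> float:
    """Fully developed wall shear stress 4 mu Q / (pi R^3), in Pa."""
    conditions = conditions or FlowConditions()
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    R = radius_mm * 1e-3
    return 4.0 * conditions.viscosity_pa_s * conditions.q_m3_s / (math.pi * R**3)


def poiseuille_pressure_drop(
    radius_mm: float, length_mm: float, conditions: FlowConditions | None = None
) -> float:
    """Pressure drop 8 mu Q L / (pi R^4) of a straight tube, in mmHg."""
    conditions = conditions or FlowConditions()
    R, L = radius_mm * 1e-3, length_mm * 1e-3
    dp = 8.0 * conditions.viscosity_pa_s * conditions.q_m3_s * L / (math.pi * R**4)
    return dp / MMHG_PA


def _wall_area_weights(z_m: np.ndarray, R_m: np.ndarray) -> np.ndarray:
    """Per-station lateral wall area weights 2 pi R sqrt(1 + R'^2) dz."""
    dRdz = np.gradient(R_m, z_m)
    w = 2.0 * math.pi * R_m * np.sqrt(1.0 + dRdz**2)
    dz = np.gradient(z_m)
    return w * dz


def _summaries(
    sol: FlowSolution, geom: IdealizedGeometry, conditions: FlowConditions
) -> FlowSolution:
    z_m = sol.z_mm * 1e-3
    R_m = geom.radius_at(sol.z_mm) * 1e-3
    i = int(np.argmax(sol.wss_pa))
    sol.tau_max_pa = float(sol.wss_pa[i])
    sol.tau_max_z_mm = float(sol.z_mm[i])
    sol.tau_min_pa = float(np.min(sol.wss_pa))
    sol.pressure_drop_mmhg = float(sol.pressure_mmhg[0] - sol.pressure_mmhg[-1])
    w = _wall_area_weights(z_m, R_m)
    sol.pct_area_high_ess = float(
        100.0 * np.sum(w[sol.wss_pa > conditions.high_ess_pa]) / np.sum(w)
    )
    z_cap, _ = geom.min_cap_station()
    sol.tau_at_min_cap_pa = float(np.interp(z_cap, sol.z_mm, sol.wss_pa))
    return sol


def quasi1d_flow(
    geom: IdealizedGeometry, conditions: FlowConditions | None = None
) -> FlowSolution:
    """Quasi-1D Poiseuille solution along the lesion axis."""
    conditions = conditions or FlowConditions()
    R_m = geom.lumen_radius_mm * 1e-3
    if np.any(R_m <= 0):
        raise ValueError("non-positive lumen radius")
    z_m = geom.z_mm * 1e-3
    mu, Q = conditions.viscosity_pa_s, conditions.q_m3_s
    tau = 4.0 * mu * Q / (math.pi * R_m**3)
    dpdz = -8.0 * mu * Q / (math.pi * R_m**4)
    # integrate backward from the outlet
    p = np.empty_like(z_m)
    p[-1] = conditions.outlet_pressure_mmhg * MMHG_PA
    for i in range(len(z_m) - 2, -1, -1):
        p[i] = p[i + 1] - 0.5 * (dpdz[i] + dpdz[i + 1]) * (z_m[i + 1] - z_m[i])
    sol = FlowSolution(
        z_mm=geom.z_mm.copy(),
        wss_pa=tau,
        pressure_mmhg=p / MMHG_PA,
        solver="quasi1d",
    )
    return _summaries(sol, geom, conditions)


# ---------------------------------------------------------------------------
# axisymmetric stream-function / vorticity solver
# ---------------------------------------------------------------------------

def _extend_profile(
    geom: IdealizedGeometry, extension_mm: float, n_z: int
) -> tuple[np.ndarray, CubicSpline]:
    """Axial grid with straight inlet/outlet extensions and a radius spline."""
    z0, z1 = geom.z_mm[0], geom.z_mm[-1]
    z = np.linspace(z0 - extension_mm, z1 + extension_mm, n_z) * 1e-3
    zp = np.concatenate(
        [[z0 - extension_mm], geom.z_mm, [z1 + extension_mm]]
    ) * 1e-3
    rp = np.concatenate(
        [[geom.lumen_radius_mm[0]], geom.lumen_radius_mm, [geom.lumen_radius_mm[-1]]]
    ) * 1e-3
    spline = CubicSpline(zp, rp, bc_type="clamped")
    return z, spline


def axisymmetric_ns_solve(
    geom: IdealizedGeometry,
    conditions: FlowConditions | None = None,
    n_z: int = 121,
    n_r: int = 21,
    extension_mm: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 1500,
    relax: float = 0.1,
) -> FlowSolution:
    """Steady axisymmetric laminar flow by stream-function / vorticity
    finite differences on the boundary-fitted grid (zeta = z, eta = r/R(z)).

    The coupled system is solved by Picard iteration: the linear
    stream-function (E^2 psi = -r omega) and the upwinded
    advection-diffusion vorticity systems are solved alternately with
    sparse LU factorizations, the wall vorticity being updated from the
    no-slip condition (second-order one-sided formula with the wall-slope
    metric factor) under relaxation.  Convergence: relative L2 update
    below ``tol``.

    Wall shear stress is mu |omega_wall|; the pressure is recovered from
    the axial momentum integral of the computed velocity field, which
    reduces exactly to Poiseuille in a straight tube.
    """
    conditions = conditions or FlowConditions()
    mu = conditions.viscosity_pa_s
    rho = conditions.density_kg_m3
    nu = mu / rho
    Q = conditions.q_m3_s
    psi_w = Q / (2.0 * math.pi)

    z, spline = _extend_profile(geom, extension_mm, n_z)
    R = spline(z)
    Rp = spline(z, 1)
    Rpp = spline(z, 2)
    # Reynolds check (diameter-based, at the tightest station)
    re = 2.0 * rho * Q / (math.pi * float(np.min(R)) * mu)
    if re > 2000.0:
        raise ValueError(f"Reynolds number {re:.0f} outside the laminar regime")

    eta = np.linspace(0.0, 1.0, n_r)
    dz = z[1] - z[0]
    de = eta[1] - eta[0]
    E, Z = np.meshgrid(eta, z)  # shape (n_z, n_r)
    Rg = R[:, None]
    a = -E * (Rp / R)[:, None]                     # d eta/d z metric
    c = -E * (Rpp / R - 2.0 * (Rp / R) ** 2)[:, None]
    r_phys = E * Rg

    n = n_z * n_r
    idx = np.arange(n).reshape(n_z, n_r)
    inter = np.zeros((n_z, n_r), dtype=bool)
    inter[1:-1, 1:-1] = True
    ii, jj = np.where(inter)
    rc = idx[ii, jj]

    def _boundary_rows() -> tuple[list, list, list]:
        """Dirichlet axis/wall/inlet rows and the Neumann outlet rows."""
        rows, cols, vals = [], [], []
        for i in range(n_z):
            rows += [idx[i, 0], idx[i, n_r - 1]]
            cols += [idx[i, 0], idx[i, n_r - 1]]
            vals += [1.0, 1.0]
        for j in range(1, n_r - 1):
            rows += [idx[0, j]]
            cols += [idx[0, j]]
            vals += [1.0]
            rows += [idx[n_z - 1, j], idx[n_z - 1, j]]
            cols += [idx[n_z - 1, j], idx[n_z - 2, j]]
            vals += [1.0, -1.0]
        return rows, cols, vals

    def _stencil(diag, zp, zm, ep, em, cross) -> sparse.csc_matrix:
        """Assemble interior 9-point stencil + boundary rows (vectorized).

        ``cross`` multiplies the mixed-derivative pattern
        (+ at (i+1,j+1)/(i-1,j-1), - at the other two corners).
        """
        rows = [rc, rc, rc, rc, rc, rc, rc, rc, rc]
        cols = [
            idx[ii, jj], idx[ii + 1, jj], idx[ii - 1, jj],
            idx[ii, jj + 1], idx[ii, jj - 1],
            idx[ii + 1, jj + 1], idx[ii - 1, jj - 1],
            idx[ii + 1, jj - 1], idx[ii - 1, jj + 1],
        ]
        vals = [diag, zp, zm, ep, em, cross, cross, -cross, -cross]
        br, bc_, bv = _boundary_rows()
        rows = np.concatenate([np.concatenate(rows), np.array(br)])
        cols = np.concatenate([np.concatenate(cols), np.array(bc_)])
        vals = np.concatenate([np.concatenate(vals), np.array(bv)])
        return sparse.csc_matrix((vals, (rows, cols)), shape=(n, n))

    def assemble_psi() -> sparse.csc_matrix:
        """E^2 psi operator with Dirichlet axis/wall/inlet, Neumann outlet."""
        A = 1.0
        B = (a**2 + 1.0 / R[:, None] ** 2)[ii, jj]
        C = (c - 1.0 / (np.maximum(E, 1e-12) * R[:, None] ** 2))[ii, jj]
        X = 2.0 * a[ii, jj]
        return _stencil(
            diag=-2.0 * A / dz**2 - 2.0 * B / de**2,
            zp=np.full_like(B, A / dz**2),
            zm=np.full_like(B, A / dz**2),
            ep=B / de**2 + C / (2 * de),
            em=B / de**2 - C / (2 * de),
            cross=X / (4.0 * dz * de),
        )

    psi_lu = splu(assemble_psi())

    def psi_rhs(omega: np.ndarray) -> np.ndarray:
        b = np.zeros((n_z, n_r))
        b[inter] = -r_phys[inter] * omega[inter]
        b[:, n_r - 1] = psi_w
        b[0, 1:-1] = psi_w * (eta[1:-1] ** 2 * (2.0 - eta[1:-1] ** 2))
        return b.ravel()

    def velocities(psi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        psi_e = np.gradient(psi, de, axis=1)
        psi_z = np.gradient(psi, dz, axis=0) + a * psi_e
        with np.errstate(divide="ignore", invalid="ignore"):
            uz = psi_e / (E * Rg**2)
            ur = -psi_z / (E * Rg)
        # axis limit: psi ~ c1 eta^2 + c2 eta^4 -> u_z(0) = 2 c1 / R^2
        uz[:, 0] = (16.0 * psi[:, 1] - psi[:, 2]) / (6.0 * eta[1] ** 2 * Rg[:, 0] ** 2)
        ur[:, 0] = 0.0
        # no-slip wall, exactly
        uz[:, -1] = 0.0
        ur[:, -1] = 0.0
        return uz, ur

    def assemble_omega(uz, ur, signs=None) -> tuple[sparse.csc_matrix, tuple]:
        """Upwinded advection-diffusion operator for the vorticity.

        Equation (LHS = 0):
        u.grad(omega) - (u_r/r) omega
            - nu [lap(omega) + (1/r) d omega/dr - omega/r^2] = 0

        ``signs`` optionally freezes the upwind directions: near the fixed
        point, sign flips of tiny advection velocities otherwise make the
        Picard map discontinuous and leave a small residual limit cycle.
        """
        U = uz[ii, jj]                           # zeta advection speed
        V = (uz * a + ur / Rg)[ii, jj]           # eta advection speed
        B = nu * (a**2 + 1.0 / R[:, None] ** 2)[ii, jj]
        Cd = nu * (c + 1.0 / (np.maximum(E, 1e-12) * R[:, None] ** 2))[ii, jj]
        X = 2.0 * nu * a[ii, jj]
        rp = np.maximum(r_phys, 1e-12)
        sink = (nu / rp**2 - ur / rp)[ii, jj]
        up_pos, vp_pos = (U >= 0, V >= 0) if signs is None else signs
        diag = (
            2.0 * nu / dz**2 + 2.0 * B / de**2 + sink
            + np.where(up_pos, U, -U) / dz + np.where(vp_pos, V, -V) / de
        )
        zp = -nu / dz**2 + np.where(up_pos, 0.0, U / dz)
        zm = -nu / dz**2 + np.where(up_pos, -U / dz, 0.0)
        ep = -B / de**2 - Cd / (2 * de) + np.where(vp_pos, 0.0, V / de)
        em = -B / de**2 + Cd / (2 * de) + np.where(vp_pos, -V / de, 0.0)
        A = _stencil(diag=diag, zp=zp, zm=zm, ep=ep, em=em,
                     cross=-X / (4.0 * dz * de))
        return A, (up_pos, vp_pos)

    def wall_vorticity(psi: np.ndarray) -> np.ndarray:
        # second-order one-sided psi_eta_eta at the no-slip wall (psi_eta = 0)
        d2 = (8.0 * psi[:, n_r - 2] - psi[:, n_r - 3] - 7.0 * psi_w) / (2.0 * de**2)
        return -(1.0 + Rp**2) / R**3 * d2

    # initial guess: Poiseuille everywhere
    omega = 4.0 * Q * E / (math.pi * Rg**3)
    psi = (psi_w * (E**2 * (2.0 - E**2)))
    ow = wall_vorticity(psi)
    history: list[float] = []
    best = np.inf
    since_best = 0
    frozen_signs = None
    for it in range(max_iter):
        b = psi_rhs(omega)
        psi_new = psi_lu.solve(b).reshape(n_z, n_r)
        ow_new = wall_vorticity(psi_new)
        ow = (1.0 - relax) * ow + relax * ow_new
        psi = psi_new
        uz, ur = velocities(psi)
        A_om, signs = assemble_omega(uz, ur, signs=frozen_signs)
        if frozen_signs is None and history and history[-1] < 1e-4:
            frozen_signs = signs
        rhs = np.zeros((n_z, n_r))
        rhs[:, 0] = 0.0
        rhs[:, n_r - 1] = ow
        rhs[0, 1:-1] = 4.0 * Q * eta[1:-1] / (math.pi * R[0] ** 3)
        rhs[n_z - 1, 1:-1] = 0.0
        omega_new = splu(A_om).solve(rhs.ravel()).reshape(n_z, n_r)
        # relative L2 residual of the Picard update (standard CFD norm)
        d_om = float(
            np.linalg.norm(omega_new - omega)
            / max(np.linalg.norm(omega_new), 1e-300)
        )
        omega = (1.0 - relax) * omega + relax * omega_new
        history.append(d_om)
        if d_om < tol:
            break
        # the Picard map can settle into a small limit cycle; damp harder
        # whenever the residual stops improving
        if d_om < best:
            best, since_best = d_om, 0
        else:
            since_best += 1
            if since_best >= 40 and relax > 0.01:
                relax *= 0.5
                since_best = 0
    else:
        raise RuntimeError(
            f"axisymmetric solver did not converge in {max_iter} iterations; "
            f"residual history tail: {history[-5:]}"
        )

    # final velocity reconstruction: spline-accurate psi_eta per station
    uz = np.empty((n_z, n_r))
    for i in range(n_z):
        sp = CubicSpline(eta, psi[i])
        dpsi = sp(eta, 1)
        uz[i, 1:] = dpsi[1:] / (eta[1:] * R[i] ** 2)
        # axis limit via the local quartic psi ~ c1 eta^2 + c2 eta^4
        uz[i, 0] = (16.0 * psi[i, 1] - psi[i, 2]) / (6.0 * eta[1] ** 2 * R[i] ** 2)
        uz[i, -1] = 0.0                      # no-slip
    tau = mu * np.abs(ow)

    # mass conservation: numerically re-integrate the flux per station
    flux = 2.0 * math.pi * Rg[:, 0] ** 2 * simpson(uz * E, x=eta, axis=1)
    mass_err = float(100.0 * np.max(np.abs(flux - Q)) / Q)

    # pressure from the axial momentum integral, backward from the outlet
    Mom = 2.0 * math.pi * rho * Rg[:, 0] ** 2 * simpson(uz**2 * E, x=eta, axis=1)
    area = math.pi * R**2
    dMdz = np.gradient(Mom, z)
    dpdz = -(dMdz + 2.0 * math.pi * R * tau) / area
    p = np.empty_like(z)
    p[-1] = conditions.outlet_pressure_mmhg * MMHG_PA
    for i in range(len(z) - 2, -1, -1):
        p[i] = p[i + 1] - 0.5 * (dpdz[i] + dpdz[i + 1]) * (z[i + 1] - z[i])

    # report on the lesion's own stations (drop the inlet/outlet extensions)
    z_mm_all = z * 1e3
    inside = (z_mm_all >= geom.z_mm[0] - 1e-9) & (z_mm_all <= geom.z_mm[-1] + 1e-9)
    sol = FlowSolution(
        z_mm=geom.z_mm.copy(),
        wss_pa=np.interp(geom.z_mm, z_mm_all, tau),
        pressure_mmhg=np.interp(geom.z_mm, z_mm_all, p) / MMHG_PA,
        solver="axisymmetric",
        velocity=uz[inside],
        eta=eta,
        mass_flux_error_pct=mass_err,
        residual_history=history,
    )
    return _summaries(sol, geom, conditions)


def mesh_convergence(
    geom: IdealizedGeometry,
    conditions: FlowConditions | None = None,
    levels: Sequence[tuple[int, int]] = ((61, 11), (121, 21), (241, 41)),
    threshold_pct: float = 2.0,
) -> dict:
    """Run the axisymmetric solver across grid refinements.

    Returns a report with tau_max per level, successive relative changes,
    and whether the sequence converged (last change below the threshold).
    A non-monotone, non-converging sequence is flagged.
    """
    if len(levels) < 2:
        raise ValueError("need at least two refinement levels")
    conditions = conditions or FlowConditions()
    tau_max = []
    for n_z, n_r in levels:
        sol = axisymmetric_ns_solve(geom, conditions, n_z=n_z, n_r=n_r)
        tau_max.append(sol.tau_max_pa)
    changes = [
        100.0 * abs(tau_max[i + 1] - tau_max[i]) / abs(tau_max[i + 1])
        for i in range(len(tau_max) - 1)
    ]
    converged = changes[-1] < threshold_pct
    monotone = all(
        changes[i + 1] <= changes[i] + 1e-12 for i in range(len(changes) - 1)
    )
    return {
        "levels": list(levels),
        "tau_max_pa": tau_max,
        "pct_change": changes,
        "converged": converged,
        "flag": None if (converged or monotone) else "non-monotone, non-converging",
    }


class Quasi1DFlow:
    """Model wrapper: ``Quasi1DFlow(geom, conditions).fit()`` -> FlowSolution."""

    def __init__(self, geom: IdealizedGeometry, conditions: FlowConditions | None = None):
        self.geom = geom
        self.conditions = conditions or FlowConditions()

    def fit(self) -> FlowSolution:
        return quasi1d_flow(self.geom, self.conditions)


class AxisymmetricFlow:
    """Model wrapper for the axisymmetric solver with grid settings."""

    def __init__(
        self,
        geom: IdealizedGeometry,
        conditions: FlowConditions | None = None,
        n_z: int = 121,
        n_r: int = 21,
        **kwargs,
    ):
        self.geom = geom
        self.conditions = conditions or FlowConditions()
        self.n_z, self.n_r = n_z, n_r
        self.kwargs = kwargs

    def fit(self) -> FlowSolution:
        return axisymmetric_ns_solve(
            self.geom, self.conditions, n_z=self.n_z, n_r=self.n_r, **self.kwargs
        )
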