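"""Plaque structural stress (PSS) surrogates.

Closed-form and layered-cylinder estimators of wall stress under luminal
pressure, replacing a full nonlinear finite-element solve:

* the Lame thick-walled-cylinder solution (hoop and radial stress through
  the wall) as the analytic reference;
* an incompressible uniaxial Mooney-Rivlin stress law for the soft-tissue
  material model;
* a layered cap-stress estimator in which the lipid pool carries a
  negligible share of the load, so the superficial cap stress approaches
  the Laplace membrane limit sigma = p * R_lumen / h_cap at the thinnest
  cap.  In a stented lesion the lattice carries part of the circumferential
  load (a caging factor < 1 scales the wall tension) and concentrates the
  remainder onto discrete strut contacts in the deep layer.

The luminal load combines the static outlet pressure with the local flow
pressure when a flow solution is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import IdealizedGeometry
from .hemodynamics import FlowConditions, FlowSolution, MMHG_PA

__all__ = [
    "MooneyRivlin5",
    "LinearElastic",
    "StressSolution",
    "lame_cylinder",
    "mooney_rivlin_uniaxial",
    "laplace_cap_stress",
    "cap_stress_estimate",
    "CapStressModel",
    "ARTERIAL_WALL",
    "LIPID_POOL",
    "STENT_ALLOY",
]


@dataclass(frozen=True)
class MooneyRivlin5:
    """Five-parameter incompressible Mooney-Rivlin strain-energy model.

    W = c10 (I1-3) + c01 (I2-3) + c20 (I1-3)^2 + c11 (I1-3)(I2-3)
        + c02 (I2-3)^2, coefficients in kPa.
    """

    c10: float
    c01: float = 0.0
    c20: float = 0.0
    c11: float = 0.0
    c02: float = 0.0

    @property
    def small_strain_modulus_kpa(self) -> float:
        """Linearized Young modulus, E = 6 (c10 + c01)."""
        return 6.0 * (self.c10 + self.c01)


@dataclass(frozen=True)
class LinearElastic:
    """Linear elastic material (stent alloy default: L605 Co-Cr)."""

    elastic_modulus_gpa: float = 243.0
    poisson_ratio: float = 0.29


#: Arterial-wall coefficients from a published five-parameter calibration
#: of human arterial tissue widely used in stent mechanics (Lally et al.,
#: J Biomech 2004), in kPa.
ARTERIAL_WALL = MooneyRivlin5(c10=18.90, c01=2.75, c20=85.72, c11=590.43, c02=0.0)

#: Soft lipid pool: two orders of magnitude softer than the wall.
LIPID_POOL = MooneyRivlin5(c10=0.5)

STENT_ALLOY = LinearElastic()


@dataclass
class StressSolution:
    """Wall-stress field summary with its boundary-condition record."""

    z_mm: np.ndarray
    superficial_stress_kpa: np.ndarray
    r_profile_mm: np.ndarray
    hoop_stress_kpa: np.ndarray
    radial_stress_kpa: np.ndarray
    superficial_pss_kpa: float
    superficial_pss_z_mm: float
    max_pss_kpa: float
    max_pss_location: str          # "cap crown" or "strut vicinity"
    strut_vicinity_stress_kpa: Optional[float]
    caging_factor: float
    material: MooneyRivlin5
    boundary_conditions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.superficial_stress_kpa)):
            raise ValueError("non-finite stress field")
        if self.superficial_pss_kpa > self.max_pss_kpa + 1e-9:
            raise ValueError("superficial PSS cannot exceed the overall maximum")

    def summary(self) -> str:
        lines = [
            f"superficial PSS:   {self.superficial_pss_kpa:.1f} kPa "
            f"at z = {self.superficial_pss_z_mm:.2f} mm (thinnest cap)",
            f"max PSS:           {self.max_pss_kpa:.1f} kPa ({self.max_pss_location})",
            f"caging factor:     {self.caging_factor:.2f}",
            f"material c10..c02: {self.material}",
        ]
        if self.strut_vicinity_stress_kpa is not None:
            lines.insert(2, f"strut vicinity:    {self.strut_vicinity_stress_kpa:.1f} kPa")
        return "\n".join(lines)


def lame_cylinder(
    inner_r_mm: float,
    outer_r_mm: float,
    p_in_kpa: float,
    p_out_kpa: float = 0.0,
    n: int = 101,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lame thick-walled cylinder: (r_mm, hoop stress, radial stress) in kPa.

    sigma_theta(r) = A + B / r^2, sigma_r(r) = A - B / r^2 with
    A = (p_in a^2 - p_out b^2)/(b^2 - a^2), B = (p_in - p_out) a^2 b^2 /
    (b^2 - a^2); tension positive.
    """
    a, b = inner_r_mm, outer_r_mm
    if not 0 < a < b:
        raise ValueError("need 0 < inner radius < outer radius")
    A = (p_in_kpa * a**2 - p_out_kpa * b**2) / (b**2 - a**2)
    B = (p_in_kpa - p_out_kpa) * a**2 * b**2 / (b**2 - a**2)
    r = np.linspace(a, b, n)
    return r, A + B / r**2, A - B / r**2


def mooney_rivlin_uniaxial(material: MooneyRivlin5, stretch: float) -> float:
    """Uniaxial Cauchy stress (kPa) of an incompressible Mooney-Rivlin solid.

    sigma = 2 (lambda^2 - 1/lambda) (dW/dI1 + dW/dI2 / lambda).
    """
    lam = float(stretch)
    if lam <= 0:
        raise ValueError("stretch must be positive")
    i1 = lam**2 + 2.0 / lam
    i2 = 2.0 * lam + 1.0 / lam**2
    w1 = material.c10 + 2.0 * material.c20 * (i1 - 3.0) + material.c11 * (i2 - 3.0)
    w2 = material.c01 + material.c11 * (i1 - 3.0) + 2.0 * material.c02 * (i2 - 3.0)
    return 2.0 * (lam**2 - 1.0 / lam) * (w1 + w2 / lam)


def mooney_rivlin_energy(material: MooneyRivlin5, stretch: float) -> float:
    """Strain energy W (kPa) at a uniaxial incompressible stretch."""
    lam = float(stretch)
    i1 = lam**2 + 2.0 / lam
    i2 = 2.0 * lam + 1.0 / lam**2
    d1, d2 = i1 - 3.0, i2 - 3.0
    return (
        material.c10 * d1
        + material.c01 * d2
        + material.c20 * d1**2
        + material.c11 * d1 * d2
        + material.c02 * d2**2
    )


def laplace_cap_stress(p_kpa: float, lumen_radius_mm: float, cap_thickness_mm: float) -> float:
    """Membrane (Laplace) hoop stress p R / h of a thin cap over a soft pool."""
    if cap_thickness_mm <= 0:
        raise ValueError("cap thickness must be positive")
    return p_kpa * lumen_radius_mm / cap_thickness_mm


def default_caging_factor(
    geom: IdealizedGeometry, wall: MooneyRivlin5 = ARTERIAL_WALL
) -> float:
    """Fraction of the wall tension still carried by tissue in a stented
    lesion, from the tissue/stent membrane-stiffness ratio.

    The stent ring lattice acts as a stiff circumferential reinforcement;
    its effective membrane stiffness is diluted by the strut fill fraction
    (strut thickness / inter-strut distance).  The tissue keeps the share
    E_t h_t / (E_t h_t + E_s h_s_eff).
    """
    stent = geom.stent
    if stent is None:
        return 1.0
    e_tissue_kpa = wall.small_strain_modulus_kpa
    h_tissue_mm = float(np.mean(geom.eem_radius_mm - geom.lumen_radius_mm))
    fill = (stent.strut_thickness_um / 1000.0) / stent.inter_strut_distance_mm
    e_stent_kpa = stent.elastic_modulus_gpa * 1e6
    h_stent_mm = stent.strut_thickness_um / 1000.0
    k_t = e_tissue_kpa * h_tissue_mm
    k_s = e_stent_kpa * h_stent_mm * fill
    # the lattice is not a closed tube: only a bounded share of the load
    # path runs through it between rings
    kappa = k_t / (k_t + 0.001 * k_s)
    return float(np.clip(kappa, 0.05, 1.0))


def cap_stress_estimate(
    geom: IdealizedGeometry,
    conditions: FlowConditions | None = None,
    material: MooneyRivlin5 = ARTERIAL_WALL,
    stented: Optional[bool] = None,
    flow: Optional[FlowSolution] = None,
    caging_factor: Optional[float] = None,
    strut_concentration: float = 2.0,
) -> StressSolution:
    """Superficial and deep wall stress along the lesion.

    Superficial cap stress uses the layered-cylinder limit in which the
    lipid pool is load-free, i.e. the Laplace membrane stress
    p(z) R(z) / h_cap(z); it peaks at the thinnest-cap station, which the
    geometry builder places proximal to the MLA.  When ``stented``, the
    wall tension is scaled by the caging factor and the transferred load is
    concentrated at strut contacts in the deep layer (contact stress
    (1 - kappa) p s / w times a concentration factor).

    The through-wall hoop/radial profiles reported are the Lame solution at
    the MLA station (lumen to EEM) under the same pressure.
    """
    conditions = conditions or FlowConditions()
    if geom.cap_thickness_mm is None or np.all(geom.cap_thickness_mm <= 0):
        raise ValueError("geometry has no cap layer")
    if stented is None:
        stented = geom.stent is not None
    if stented and geom.stent is None:
        raise ValueError("stented analysis requires a stent spec on the geometry")

    p_static_kpa = conditions.outlet_pressure_mmhg * MMHG_PA / 1000.0
    if flow is not None:
        p_kpa = np.interp(geom.z_mm, flow.z_mm, flow.pressure_mmhg) * MMHG_PA / 1000.0
    else:
        p_kpa = np.full_like(geom.z_mm, p_static_kpa)

    kappa = 1.0
    if stented:
        kappa = caging_factor if caging_factor is not None else default_caging_factor(geom, material)

    sup = kappa * p_kpa * geom.lumen_radius_mm / geom.cap_thickness_mm
    i_cap = int(np.argmin(geom.cap_thickness_mm))
    sup_pss = float(sup[i_cap])
    sup_z = float(geom.z_mm[i_cap])

    strut_stress = None
    if stented:
        stent = geom.stent
        w_mm = stent.strut_thickness_um / 1000.0
        s_mm = stent.inter_strut_distance_mm
        p_at_struts = float(np.max(np.interp(geom.strut_z_mm, geom.z_mm, p_kpa))) \
            if geom.strut_z_mm.size else float(np.max(p_kpa))
        strut_stress = strut_concentration * (1.0 - kappa) * p_at_struts * s_mm / w_mm

    if strut_stress is not None and strut_stress > sup_pss:
        max_pss, max_loc = strut_stress, "strut vicinity"
    else:
        max_pss, max_loc = sup_pss, "cap crown"

    i_mla = int(np.argmin(geom.lumen_radius_mm))
    r_prof, hoop, radial = lame_cylinder(
        float(geom.lumen_radius_mm[i_mla]),
        float(geom.eem_radius_mm[i_mla]),
        float(kappa * p_kpa[i_mla]),
    )

    return StressSolution(
        z_mm=geom.z_mm.copy(),
        superficial_stress_kpa=sup,
        r_profile_mm=r_prof,
        hoop_stress_kpa=hoop,
        radial_stress_kpa=radial,
        superficial_pss_kpa=sup_pss,
        superficial_pss_z_mm=sup_z,
        max_pss_kpa=float(max_pss),
        max_pss_location=max_loc,
        strut_vicinity_stress_kpa=strut_stress,
        caging_factor=kappa,
        material=material,
        boundary_conditions={
            "ends": "fixed in space",
            "luminal_pressure_kpa": "static outlet pressure"
            + (" + local flow pressure" if flow is not None else ""),
            "outlet_pressure_mmhg": conditions.outlet_pressure_mmhg,
        },
    )


class CapStressModel:
    """Model wrapper: ``CapStressModel(geom, ...).fit()`` -> StressSolution."""

    def __init__(
        self,
        geom: IdealizedGeometry,
        conditions: FlowConditions | None = None,
        material: MooneyRivlin5 = ARTERIAL_WALL,
        flow: Optional[FlowSolution] = None,
        **kwargs,
    ):
        self.geom = geom
        self.conditions = conditions or FlowConditions()
        self.material = material
        self.flow = flow
        self.kwargs = kwargs

    def fit(self) -> StressSolution:
        return cap_stress_estimate(
            self.geom, self.conditions, self.material, flow=self.flow, **self.kwargs
        )
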