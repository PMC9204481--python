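"""Idealized pre-rupture lesion geometry.

Builds a representative axisymmetric stenosis from mean cohort parameters:
a C1 cosine-taper lumen running from the proximal reference radius down to
the minimum lumen radius at the MLA and back up to the distal reference, a
fibrous-cap layer whose thickness dips to the cohort-minimum cap thickness
at the lipid-pool crown proximal to the MLA, an arc-limited lipid pool (the
eccentric plaque is represented by restricting the pool to an angular
sector so a half-model symmetry plane exists), an external elastic membrane
(EEM) estimated from the reference EEM with a remodeling index applied at
the MLA, and, for stented lesions, a lattice of circular strut rings.

Axial convention: z runs from the proximal (inlet) end at z = 0 to the
distal end at z = lesion length, i.e. along the flow direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import equivalent_radius

__all__ = [
    "LesionSpec",
    "StentSpec",
    "IdealizedGeometry",
    "build_lumen_profile",
    "build_wall",
    "build_geometry",
    "mean_lesion_spec",
    "export_geometry",
    "load_profile_csv",
]


@dataclass(frozen=True)
class StentSpec:
    """Stent lattice parameters (drug-eluting stent with circular struts)."""

    stent_diameter_mm: float = 3.0
    strut_thickness_um: float = 90.0
    inter_strut_distance_mm: float = 1.0
    elastic_modulus_gpa: float = 243.0
    poisson_ratio: float = 0.29


@dataclass
class LesionSpec:
    """Mean geometric parameters of a lesion cohort.

    ``lipid_offset_from_mla_mm`` is the axial offset of the lipid-pool
    center from the MLA (negative = proximal); the cap-thickness minimum
    sits at the pool center, so the default places the thinnest cap
    proximal to the MLA.
    """

    prox_ref_diameter_mm: float
    dist_ref_diameter_mm: float
    min_lumen_diameter_mm: float
    lesion_length_mm: float
    mla_axial_position_mm: Optional[float] = None
    cap_min_um: float = 65.0
    cap_mean_um: float = 200.0
    lipid_arc_deg: float = 150.0
    lipid_length_mm: float = 6.0
    lipid_offset_from_mla_mm: float = -1.0
    remodeling_index: float = 1.20
    prox_ref_eem_area_mm2: Optional[float] = None
    dist_ref_eem_area_mm2: Optional[float] = None
    reference_plaque_burden_pct: float = 30.0
    stent: Optional[StentSpec] = None

    def __post_init__(self) -> None:
        if self.min_lumen_diameter_mm >= min(
            self.prox_ref_diameter_mm, self.dist_ref_diameter_mm
        ) + 1e-12:
            raise ValueError("minimum lumen diameter must be below both references")
        if self.remodeling_index < 1.0:
            raise ValueError("remodeling index must be >= 1")
        if self.mla_axial_position_mm is None:
            self.mla_axial_position_mm = 0.5 * self.lesion_length_mm
        if not 0.0 <= self.mla_axial_position_mm <= self.lesion_length_mm:
            raise ValueError("MLA position outside [0, lesion length]")


@dataclass
class IdealizedGeometry:
    """Axisymmetric lesion model: radius profiles on a shared axial grid."""

    z_mm: np.ndarray
    lumen_radius_mm: np.ndarray
    cap_outer_radius_mm: np.ndarray
    eem_radius_mm: np.ndarray
    cap_thickness_mm: np.ndarray
    lipid_z_range_mm: tuple[float, float]
    lipid_arc_deg: float
    strut_z_mm: np.ndarray = field(default_factory=lambda: np.array([]))
    stent: Optional[StentSpec] = None
    symmetry: str = "axisymmetric"
    spec: Optional[LesionSpec] = None

    def __post_init__(self) -> None:
        if np.any(self.lumen_radius_mm <= 0):
            raise ValueError("lumen radius must be positive everywhere")
        if np.any(self.cap_outer_radius_mm < self.lumen_radius_mm - 1e-12):
            raise ValueError("cap outer border inside the lumen")
        if np.any(self.eem_radius_mm < self.cap_outer_radius_mm - 1e-9):
            raise ValueError("EEM inside the cap outer border")

    @property
    def length_mm(self) -> float:
        return float(self.z_mm[-1] - self.z_mm[0])

    def lumen_area_mm2(self) -> np.ndarray:
        return math.pi * self.lumen_radius_mm**2

    def mla(self) -> tuple[float, float]:
        """(z of the minimum lumen area, MLA in mm^2)."""
        i = int(np.argmin(self.lumen_radius_mm))
        return float(self.z_mm[i]), float(math.pi * self.lumen_radius_mm[i] ** 2)

    def min_cap_station(self) -> tuple[float, float]:
        """(z of the thinnest cap, cap thickness there in mm)."""
        i = int(np.argmin(self.cap_thickness_mm))
        return float(self.z_mm[i]), float(self.cap_thickness_mm[i])

    def lumen_volume_mm3(self) -> float:
        return float(np.trapezoid(math.pi * self.lumen_radius_mm**2, self.z_mm))

    def radius_at(self, z: float | np.ndarray) -> np.ndarray:
        return np.interp(z, self.z_mm, self.lumen_radius_mm)


def _cosine_segment(z: np.ndarray, z0: float, z1: float, r0: float, r1: float) -> np.ndarray:
    """Half-cosine blend from (z0, r0) to (z1, r1); zero slope at both ends."""
    t = np.clip((z - z0) / max(z1 - z0, 1e-12), 0.0, 1.0)
    return r0 + (r1 - r0) * 0.5 * (1.0 - np.cos(math.pi * t))


def build_lumen_profile(spec: LesionSpec, n_stations: int = 201) -> tuple[np.ndarray, np.ndarray]:
    """(z, lumen radius) of a smooth cosine-taper stenosis.

    The profile passes exactly through the proximal reference radius at
    z = 0, the minimum radius at the MLA position, and the distal reference
    radius at z = L, with zero slope at all three stations (C1 everywhere).
    """
    if n_stations < 41:
        raise ValueError("need at least 41 axial stations")
    L = spec.lesion_length_mm
    zm = spec.mla_axial_position_mm
    z = np.linspace(0.0, L, n_stations)
    r_prox = spec.prox_ref_diameter_mm / 2.0
    r_dist = spec.dist_ref_diameter_mm / 2.0
    r_min = spec.min_lumen_diameter_mm / 2.0
    r = np.empty_like(z)
    if zm <= 0:
        r[:] = _cosine_segment(z, 0.0, L, r_min, r_dist)
    elif zm >= L:
        r[:] = _cosine_segment(z, 0.0, L, r_prox, r_min)
    else:
        up = z <= zm
        r[up] = _cosine_segment(z[up], 0.0, zm, r_prox, r_min)
        r[~up] = _cosine_segment(z[~up], zm, L, r_min, r_dist)
    # pin the MLA exactly onto the grid
    i = int(np.argmin(np.abs(z - zm)))
    r[i] = r_min
    return z, r


def _ref_eem_area(lumen_diameter_mm: float, eem_area: Optional[float], burden_pct: float) -> float:
    if eem_area is not None:
        return eem_area
    lumen_area = math.pi * (lumen_diameter_mm / 2.0) ** 2
    return lumen_area / (1.0 - burden_pct / 100.0)


def build_wall(
    spec: LesionSpec, z: np.ndarray, lumen_radius: np.ndarray
) -> IdealizedGeometry:
    """Wall layers over a lumen profile: cap field, lipid pool, EEM, struts.

    The cap-thickness field equals the cohort mean cap thickness away from
    the lipid pool and dips (half-cosine bump) to the cohort minimum at the
    pool center.  Reference EEM radii come from the measured reference EEM
    areas (or a nominal reference plaque burden when unmeasured); the EEM at
    the MLA equals the remodeling index times the mean reference EEM area.
    """
    if spec.cap_min_um > spec.cap_mean_um:
        raise ValueError("cap minimum exceeds cap mean")
    L = spec.lesion_length_mm
    zm = spec.mla_axial_position_mm
    lip_len = min(spec.lipid_length_mm, L)
    lip_center = float(np.clip(zm + spec.lipid_offset_from_mla_mm, lip_len / 2.0,
                               L - lip_len / 2.0)) if lip_len < L else L / 2.0
    lip_lo, lip_hi = lip_center - lip_len / 2.0, lip_center + lip_len / 2.0

    cap_mean_mm = spec.cap_mean_um / 1000.0
    cap_min_mm = spec.cap_min_um / 1000.0
    cap = np.full_like(z, cap_mean_mm)
    if lip_len > 0:
        inside = (z >= lip_lo) & (z <= lip_hi)
        bump = 0.5 * (1.0 + np.cos(
            2.0 * math.pi * (z[inside] - lip_center) / max(lip_len, 1e-9)
        ))
        cap[inside] = cap_mean_mm - (cap_mean_mm - cap_min_mm) * bump
    # pin the minimum exactly at the crown station
    if lip_len > 0:
        i = int(np.argmin(np.abs(z - lip_center)))
        cap[i] = cap_min_mm

    eem_prox = _ref_eem_area(spec.prox_ref_diameter_mm, spec.prox_ref_eem_area_mm2,
                             spec.reference_plaque_burden_pct)
    eem_dist = _ref_eem_area(spec.dist_ref_diameter_mm, spec.dist_ref_eem_area_mm2,
                             spec.reference_plaque_burden_pct)
    eem_mla = spec.remodeling_index * 0.5 * (eem_prox + eem_dist)
    r_eem_prox = equivalent_radius(eem_prox)
    r_eem_dist = equivalent_radius(eem_dist)
    r_eem_mla = equivalent_radius(eem_mla)
    eem = np.empty_like(z)
    up = z <= zm
    eem[up] = _cosine_segment(z[up], 0.0, max(zm, 1e-9), r_eem_prox, r_eem_mla)
    eem[~up] = _cosine_segment(z[~up], zm, L, r_eem_mla, r_eem_dist)

    cap_outer = lumen_radius + cap
    eem = np.maximum(eem, cap_outer + 1e-6)  # EEM never inside the wall layers

    struts = np.array([])
    if spec.stent is not None:
        struts = np.arange(0.0, L + 1e-9, spec.stent.inter_strut_distance_mm)

    return IdealizedGeometry(
        z_mm=z,
        lumen_radius_mm=lumen_radius,
        cap_outer_radius_mm=cap_outer,
        eem_radius_mm=eem,
        cap_thickness_mm=cap,
        lipid_z_range_mm=(lip_lo, lip_hi),
        lipid_arc_deg=spec.lipid_arc_deg,
        strut_z_mm=struts,
        stent=spec.stent,
        symmetry="half-model" if spec.lipid_arc_deg < 360.0 else "axisymmetric",
        spec=spec,
    )


def build_geometry(spec: LesionSpec, n_stations: int = 201) -> IdealizedGeometry:
    """Lumen profile + wall layers in one call."""
    z, r = build_lumen_profile(spec, n_stations)
    return build_wall(spec, z, r)


# ---------------------------------------------------------------------------
# cohort -> mean spec
# ---------------------------------------------------------------------------

def mean_lesion_spec(
    cohort: pd.DataFrame,
    group: str = "PR-NV",
    stent_diameter_mm: Optional[float] = None,
) -> LesionSpec:
    """Arithmetic-mean lesion spec from a per-lesion metric table.

    Diameters are means of per-lesion equivalent diameters (2 *
    sqrt(area/pi)); where a lesion ruptured the areas are understood to
    describe the reconstructed pre-rupture lumen.  For stented
    (neoatherosclerotic) lesions the stent diameter defaults to the mean
    reference lumen diameter when not measured.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")

    def mean_diam(col: str) -> float:
        return float(np.mean([2.0 * equivalent_radius(a) for a in cohort[col].dropna()]))

    d_prox = mean_diam("prox_ref_area_mm2")
    d_dist = mean_diam("dist_ref_area_mm2")
    d_min = mean_diam("mla_mm2")
    stent = None
    if group == "PR-NA":
        if stent_diameter_mm is None:
            stent_diameter_mm = 0.5 * (d_prox + d_dist)
        stent = StentSpec(stent_diameter_mm=stent_diameter_mm)

    def col_mean(col: str, default: float) -> float:
        return float(cohort[col].dropna().mean()) if col in cohort else default

    return LesionSpec(
        prox_ref_diameter_mm=d_prox,
        dist_ref_diameter_mm=d_dist,
        min_lumen_diameter_mm=d_min,
        lesion_length_mm=float(cohort["lesion_length_mm"].mean()),
        cap_min_um=col_mean("min_fct_um", 65.0),
        cap_mean_um=col_mean("mean_fct_um", 200.0),
        lipid_arc_deg=col_mean("mean_lipid_arc_deg", 150.0),
        lipid_length_mm=col_mean("lipid_length_mm", 6.0),
        lipid_offset_from_mla_mm=col_mean("lipid_offset_from_mla_mm", -1.0),
        stent=stent,
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _surface_mesh(geom: IdealizedGeometry, n_theta: int = 64):
    """Closed triangulated surface of revolution of the lumen (trimesh)."""
    import trimesh

    z = geom.z_mm
    r = geom.lumen_radius_mm
    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    rings = [
        np.column_stack(
            [ri * np.cos(theta), ri * np.sin(theta), np.full(n_theta, zi)]
        )
        for zi, ri in zip(z, r)
    ]
    verts = np.vstack(rings)
    faces = []
    for i in range(len(z) - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append([a, b, d])
            faces.append([a, d, c])
    # end caps (fans around the axis points)
    c0 = len(verts)
    verts = np.vstack([verts, [[0.0, 0.0, z[0]], [0.0, 0.0, z[-1]]]])
    for j in range(n_theta):
        faces.append([c0, (j + 1) % n_theta, j])
        base = (len(z) - 1) * n_theta
        faces.append([c0 + 1, base + j, base + (j + 1) % n_theta])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    return mesh


def export_geometry(
    geom: IdealizedGeometry, path: str | Path, format: str = "profile-csv"
) -> Path:
    """Write the geometry as an STL surface, a legacy-VTK polydata file, or
    a per-station profile CSV (the lossless text form)."""
    path = Path(path)
    if format == "profile-csv":
        df = pd.DataFrame(
            {
                "z_mm": geom.z_mm,
                "lumen_radius_mm": geom.lumen_radius_mm,
                "cap_outer_radius_mm": geom.cap_outer_radius_mm,
                "eem_radius_mm": geom.eem_radius_mm,
                "cap_thickness_mm": geom.cap_thickness_mm,
            }
        )
        df.to_csv(path, index=False)
    elif format == "stl":
        _surface_mesh(geom).export(path, file_type="stl")
    elif format == "vtk":
        mesh = _surface_mesh(geom)
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\nidealized lesion lumen\nASCII\n")
            fh.write("DATASET POLYDATA\n")
            fh.write(f"POINTS {len(mesh.vertices)} float\n")
            for v in mesh.vertices:
                fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            fh.write(f"POLYGONS {len(mesh.faces)} {4 * len(mesh.faces)}\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def load_profile_csv(path: str | Path) -> IdealizedGeometry:
    """Re-import a station-profile CSV written by :func:`export_geometry`."""
    df = pd.read_csv(path)
    z = df["z_mm"].to_numpy()
    cap = df["cap_thickness_mm"].to_numpy()
    i = int(np.argmin(cap))
    return IdealizedGeometry(
        z_mm=z,
        lumen_radius_mm=df["lumen_radius_mm"].to_numpy(),
        cap_outer_radius_mm=df["cap_outer_radius_mm"].to_numpy(),
        eem_radius_mm=df["eem_radius_mm"].to_numpy(),
        cap_thickness_mm=cap,
        lipid_z_range_mm=(float(z[i]), float(z[i])),
        lipid_arc_deg=360.0,
    )
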