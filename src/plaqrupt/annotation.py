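"""Frame-level OCT annotation data model.

Every downstream stage (lesion delimitation, tissue morphometry, cohort
statistics, geometry reconstruction) consumes the types defined here.  A
:class:`Pullback` is an ordered stack of analyzed cross-sections
(:class:`FrameAnnotation`), each carrying the lumen geometry (either a full
angular radius profile or a plain area), optional external-elastic-membrane
(EEM) and stent areas, the tissue arcs identified by the analyst, a
fibrous-cap thickness profile over lipid tissue, and the rupture/thrombus
state of the frame.

Angular convention: degrees, counter-clockwise, origin (0°) at 3 o'clock.
Arcs are stored as (start, end) pairs and widths are computed modulo 360 so
spans crossing the origin are handled exactly.

Serialization: JSON is the canonical format (schema version
``SCHEMA_VERSION``); CSV is a flat one-row-per-frame export for spreadsheet
use.  Unknown keys found on input are preserved in ``metadata`` maps.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ArcKind",
    "ArcSpan",
    "FrameAnnotation",
    "Pullback",
    "ThresholdConfig",
    "ValidationError",
    "arc_width",
    "equivalent_radius",
    "read_pullback",
    "write_pullback",
]

SCHEMA_VERSION = "1.0"

#: Tissue/feature kinds an angular span may carry.
ARC_KINDS = (
    "lipid",
    "calcific",
    "macrophage_spotted",
    "macrophage_lined",
    "rupture",
    "thrombus",
)
ArcKind = str

#: Recognized frame spacings (mm): 0.4 mm standard, 0.375 mm Lunawave.
FRAME_SPACINGS_MM = (0.4, 0.375)

GROUPS = ("PR-NV", "PR-NA")
VESSELS = ("LAD", "LCx", "RCA")


class ValidationError(ValueError):
    """Raised when an annotation violates a schema invariant."""


def arc_width(start_deg: float, end_deg: float) -> float:
    """Circumferential width of an arc in degrees, in (0, 360].

    Computed as ``(end - start) mod 360`` with the convention that a zero
    residue means the arc wraps the full circumference.  Exact for spans
    crossing the angular origin.
    """
    w = (float(end_deg) - float(start_deg)) % 360.0
    return 360.0 if w == 0.0 else w


def equivalent_radius(area_mm2: float) -> float:
    """Radius (mm) of the circle with the given area (mm^2)."""
    if not area_mm2 > 0:
        raise ValidationError(f"area must be positive, got {area_mm2}")
    return math.sqrt(area_mm2 / math.pi)


@dataclass(frozen=True)
class ArcSpan:
    """A circumferential tissue arc on one frame.

    ``start_deg``/``end_deg`` follow the package angular convention
    (degrees, CCW, 0° at 3 o'clock); the arc runs CCW from start to end.
    """

    start_deg: float
    end_deg: float
    kind: ArcKind

    def __post_init__(self) -> None:
        if self.kind not in ARC_KINDS:
            raise ValidationError(f"unknown arc kind {self.kind!r}")
        for name in ("start_deg", "end_deg"):
            v = getattr(self, name)
            if not (0.0 <= v < 360.0):
                raise ValidationError(f"{name}={v} outside [0, 360)")

    @property
    def width_deg(self) -> float:
        return arc_width(self.start_deg, self.end_deg)

    @property
    def midpoint_deg(self) -> float:
        return (self.start_deg + self.width_deg / 2.0) % 360.0

    def contains(self, angle_deg: float) -> bool:
        return (angle_deg - self.start_deg) % 360.0 <= self.width_deg


@dataclass
class FrameAnnotation:
    """One analyzed OCT cross-section.

    The lumen may be supplied as a full angular radius profile
    (``lumen_radius``, >= 36 samples, mm) or as an area only; operations that
    require a profile state so.  ``approximated_lumen_radius`` is the
    reconstructed pre-rupture lumen border (the border connecting the edges
    of the ruptured fibrous cap) and is only meaningful on rupture frames.
    """

    frame_index: int
    z_mm: float
    lumen_area_mm2: Optional[float] = None
    lumen_radius: Optional[Sequence[float]] = None
    eem_area_mm2: Optional[float] = None
    stent_area_mm2: Optional[float] = None
    neointima_thickness_mm: Optional[float] = None
    arcs: Sequence[ArcSpan] = field(default_factory=tuple)
    cap_thickness_um: Optional[Sequence[float]] = None
    rupture_present: bool = False
    approximated_lumen_radius: Optional[Sequence[float]] = None
    rupture_depth_mm: Optional[float] = None
    thrombus_quadrants: Sequence[bool] = (False, False, False, False)
    microchannel_diameter_um: Optional[float] = None
    cholesterol_crystal: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fi = self.frame_index
        if not (isinstance(fi, (int, np.integer)) and fi >= 0):
            raise ValidationError(f"frame_index must be a non-negative integer, got {fi!r}")
        if self.lumen_radius is not None:
            r = np.asarray(self.lumen_radius, dtype=float)
            if r.size < 36:
                raise ValidationError(
                    f"frame {fi}: lumen_radius needs >=36 angular samples, got {r.size}"
                )
            if not np.all(r > 0):
                raise ValidationError(f"frame {fi}: lumen_radius must be positive")
            self.lumen_radius = tuple(float(x) for x in r)
        if self.lumen_area_mm2 is None and self.lumen_radius is None:
            raise ValidationError(f"frame {fi}: need lumen_area_mm2 or lumen_radius")
        for name in ("lumen_area_mm2", "eem_area_mm2", "stent_area_mm2",
                     "microchannel_diameter_um"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"frame {fi}: {name}={v} must be positive")
        if self.neointima_thickness_mm is not None and self.neointima_thickness_mm < 0:
            raise ValidationError(f"frame {fi}: neointima_thickness_mm must be >= 0")
        if self.rupture_depth_mm is not None and self.rupture_depth_mm < 0:
            raise ValidationError(f"frame {fi}: rupture_depth_mm must be >= 0")
        lum = self.lumen_area()
        if self.eem_area_mm2 is not None and self.eem_area_mm2 < lum - 1e-12:
            raise ValidationError(
                f"frame {fi}: eem_area_mm2 ({self.eem_area_mm2}) < lumen area ({lum})"
            )
        if self.stent_area_mm2 is not None and self.stent_area_mm2 < lum - 1e-12:
            raise ValidationError(
                f"frame {fi}: stent_area_mm2 ({self.stent_area_mm2}) < lumen area ({lum})"
            )
        if self.approximated_lumen_radius is not None:
            if not self.rupture_present:
                raise ValidationError(
                    f"frame {fi}: approximated_lumen_radius requires rupture_present"
                )
            self.approximated_lumen_radius = tuple(
                float(x) for x in self.approximated_lumen_radius
            )
            if any(x <= 0 for x in self.approximated_lumen_radius):
                raise ValidationError(f"frame {fi}: approximated_lumen_radius must be positive")
        tq = tuple(bool(q) for q in self.thrombus_quadrants)
        if len(tq) != 4:
            raise ValidationError(f"frame {fi}: exactly 4 thrombus quadrant flags required")
        self.thrombus_quadrants = tq
        self.arcs = tuple(
            a if isinstance(a, ArcSpan) else ArcSpan(**a) for a in self.arcs
        )
        if self.cap_thickness_um is not None:
            self.cap_thickness_um = tuple(float(x) for x in self.cap_thickness_um)
            if any(x < 0 for x in self.cap_thickness_um):
                raise ValidationError(f"frame {fi}: cap thickness must be >= 0")

    # -- geometry helpers -------------------------------------------------

    def lumen_area(self) -> float:
        """Lumen area (mm^2), from the stored area or the radius profile.

        The profile-based area uses the polygon formed by the angular
        samples (trapezoidal integral of r^2/2 over theta).
        """
        if self.lumen_area_mm2 is not None:
            return float(self.lumen_area_mm2)
        r = np.asarray(self.lumen_radius, dtype=float)
        return float(0.5 * np.sum(r * np.roll(r, -1)) * (2 * math.pi / r.size))

    def arcs_of(self, kind: ArcKind) -> tuple[ArcSpan, ...]:
        return tuple(a for a in self.arcs if a.kind == kind)

    def total_arc_deg(self, kind: ArcKind) -> float:
        """Summed circumferential width (deg) of all arcs of a kind, capped at 360."""
        return min(360.0, sum(a.width_deg for a in self.arcs_of(kind)))

    def plaque_burden_pct(self) -> Optional[float]:
        """Plaque burden 100*(EEM - lumen)/EEM, or None when EEM invisible."""
        if self.eem_area_mm2 is None:
            return None
        return 100.0 * (self.eem_area_mm2 - self.lumen_area()) / self.eem_area_mm2


@dataclass
class Pullback:
    """An ordered sequence of analyzed frames from one culprit vessel."""

    frames: Sequence[FrameAnnotation]
    frame_spacing_mm: float = 0.4
    group: str = "PR-NV"
    vessel: str = "LAD"
    patient_meta: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_spacing_mm not in FRAME_SPACINGS_MM:
            raise ValidationError(
                f"frame_spacing_mm must be one of {FRAME_SPACINGS_MM}, "
                f"got {self.frame_spacing_mm}"
            )
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.vessel not in VESSELS:
            raise ValidationError(f"vessel must be one of {VESSELS}, got {self.vessel!r}")
        self.frames = tuple(self.frames)
        z = np.array([f.z_mm for f in self.frames], dtype=float)
        if np.any(np.diff(z) <= 0):
            bad = int(np.argmax(np.diff(z) <= 0))
            raise ValidationError(
                f"z_mm not strictly increasing at frame_index "
                f"{self.frames[bad + 1].frame_index}"
            )
        if z.size > 1 and not np.allclose(np.diff(z), self.frame_spacing_mm, atol=1e-9):
            raise ValidationError(
                f"z_mm increments must equal frame_spacing_mm={self.frame_spacing_mm}"
            )

    def __len__(self) -> int:
        return len(self.frames)

    def lumen_areas(self) -> np.ndarray:
        return np.array([f.lumen_area() for f in self.frames])

    def z(self) -> np.ndarray:
        return np.array([f.z_mm for f in self.frames])


@dataclass(frozen=True)
class ThresholdConfig:
    """Diagnostic thresholds used throughout the pipeline.

    Defaults are the consensus OCT criteria: a thin-cap fibroatheroma has a
    minimum fibrous cap <= 65 um; a lipid pool requires an arc > 45 deg; a
    macrophage accumulation a lateral extent > 20 deg; micro-channels are
    signal-poor holes <= 300 um across seen in >= 3 consecutive frames;
    thrombus needs a dimension >= 250 um; native lesion borders use plaque
    burden >= 40% and neoatherosclerotic borders mean neointima >= 0.5 mm;
    the MLA-site segment spans 2.5 mm to either side of the minimum lumen
    area; high endothelial shear stress is > 7 Pa; "superficial" wall stress
    is within 200 um of the lumen.
    """

    tcfa_cap_um: float = 65.0
    lipid_pool_min_arc_deg: float = 45.0
    macrophage_min_extent_deg: float = 20.0
    microchannel_max_diameter_um: float = 300.0
    microchannel_min_consecutive_frames: int = 3
    thrombus_min_dimension_um: float = 250.0
    plaque_burden_min_pct: float = 40.0
    neointima_min_thickness_mm: float = 0.5
    segment_half_length_mm: float = 2.5
    quadrant_deg: float = 90.0
    high_ess_pa: float = 7.0
    superficial_depth_um: float = 200.0
    # conventions flagged as convention-dependent in outputs
    shoulder_tolerance_deg: float = 30.0
    fibroatheroma_min_lipid_arc_deg: float = 90.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not v > 0:
                raise ValidationError(f"threshold {name} must be positive, got {v}")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_FRAME_FIELDS = [
    "frame_index", "z_mm", "lumen_area_mm2", "lumen_radius", "eem_area_mm2",
    "stent_area_mm2", "neointima_thickness_mm", "arcs", "cap_thickness_um",
    "rupture_present", "approximated_lumen_radius", "rupture_depth_mm",
    "thrombus_quadrants", "microchannel_diameter_um", "cholesterol_crystal",
]


def _frame_to_dict(f: FrameAnnotation) -> dict:
    d: dict[str, Any] = {}
    for k in _FRAME_FIELDS:
        v = getattr(f, k)
        if k == "arcs":
            v = [asdict(a) for a in v]
        elif isinstance(v, tuple):
            v = list(v)
        if v is not None:
            d[k] = v
    if f.metadata:
        d["metadata"] = f.metadata
    return d


def _frame_from_dict(d: dict) -> FrameAnnotation:
    known = {k: d[k] for k in _FRAME_FIELDS if k in d}
    meta = dict(d.get("metadata", {}))
    meta.update({k: v for k, v in d.items() if k not in _FRAME_FIELDS and k != "metadata"})
    try:
        return FrameAnnotation(**known, metadata=meta)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ValidationError(str(exc)) from exc


def pullback_to_dict(pb: Pullback) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "frame_spacing_mm": pb.frame_spacing_mm,
        "group": pb.group,
        "vessel": pb.vessel,
        "patient_meta": pb.patient_meta,
        "metadata": pb.metadata,
        "frames": [_frame_to_dict(f) for f in pb.frames],
    }


def pullback_from_dict(d: dict) -> Pullback:
    version = d.get("schema_version", SCHEMA_VERSION)
    if str(version).split(".")[0] != SCHEMA_VERSION.split(".")[0]:
        raise ValidationError(f"unsupported schema version {version!r}")
    extra = {k: v for k, v in d.items()
             if k not in {"schema_version", "frame_spacing_mm", "group", "vessel",
                          "patient_meta", "metadata", "frames"}}
    meta = dict(d.get("metadata", {}))
    meta.update(extra)
    return Pullback(
        frames=[_frame_from_dict(fd) for fd in d.get("frames", [])],
        frame_spacing_mm=d.get("frame_spacing_mm", 0.4),
        group=d.get("group", "PR-NV"),
        vessel=d.get("vessel", "LAD"),
        patient_meta=dict(d.get("patient_meta", {})),
        metadata=meta,
    )


def write_pullback(pb: Pullback, path: str | Path, format: str = "json") -> Path:
    """Serialize a pullback to JSON (canonical) or a flat CSV frame table."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(pullback_to_dict(pb), indent=1, sort_keys=True))
    elif format == "csv":
        _write_csv(pb, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_pullback(path: str | Path, format: str | None = None) -> Pullback:
    """Read and validate a pullback from JSON or CSV.

    Validation errors name the offending frame_index and field.  Unknown
    fields are preserved in the metadata maps.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "json"
    if format == "json":
        try:
            d = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ValidationError(f"{path}: not valid JSON: {exc}") from exc
        return pullback_from_dict(d)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {format!r}")


_CSV_LIST_FIELDS = {"lumen_radius", "cap_thickness_um", "approximated_lumen_radius"}


def _write_csv(pb: Pullback, path: Path) -> None:
    cols = _FRAME_FIELDS
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["# schema_version", SCHEMA_VERSION,
                    "frame_spacing_mm", pb.frame_spacing_mm,
                    "group", pb.group, "vessel", pb.vessel])
        w.writerow(cols)
        for f in pb.frames:
            row = []
            for k in cols:
                v = getattr(f, k)
                if k == "arcs":
                    v = ";".join(f"{a.kind}:{a.start_deg}:{a.end_deg}" for a in v)
                elif k == "thrombus_quadrants":
                    v = "".join("1" if q else "0" for q in v)
                elif k in _CSV_LIST_FIELDS and v is not None:
                    v = ";".join(repr(x) for x in v)
                row.append("" if v is None else v)
            w.writerow(row)


def _read_csv(path: Path) -> Pullback:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    header, cols, data = rows[0], rows[1], rows[2:]
    hdr = dict(zip(header[::2], header[1::2]))
    frames = []
    for raw in data:
        d: dict[str, Any] = {}
        for k, v in zip(cols, raw):
            if v == "":
                continue
            if k == "arcs":
                d[k] = [
                    {"kind": p.split(":")[0], "start_deg": float(p.split(":")[1]),
                     "end_deg": float(p.split(":")[2])}
                    for p in v.split(";") if p
                ]
            elif k == "thrombus_quadrants":
                d[k] = [c == "1" for c in v]
            elif k in _CSV_LIST_FIELDS:
                d[k] = [float(x) for x in v.split(";")]
            elif k in ("rupture_present", "cholesterol_crystal"):
                d[k] = v in ("True", "true", "1")
            elif k == "frame_index":
                d[k] = int(v)
            else:
                d[k] = float(v)
        frames.append(_frame_from_dict(d))
    return Pullback(
        frames=frames,
        frame_spacing_mm=float(hdr.get("frame_spacing_mm", 0.4)),
        group=hdr.get("group", "PR-NV"),
        vessel=hdr.get("vessel", "LAD"),
    )
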