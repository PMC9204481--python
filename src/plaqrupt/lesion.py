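"""Culprit-lesion delimitation and longitudinal geometry metrics.

Implements lesion border detection for native (PR-NV) and neoatherosclerotic
(PR-NA) ruptured plaques, minimum-lumen-area (MLA) search, the
upstream / MLA-site / downstream segment split, the radius gradient (RG),
area stenosis, and the longitudinal/circumferential classification of
rupture sites.

Lesion borders follow the group-specific rules: a native lesion runs from
the first to the last frame that carries lipid tissue or has a plaque burden
(EEM - lumen)/EEM of at least 40%; a neoatherosclerotic lesion from the most
distal to the most proximal frame whose mean neointima thickness is at least
0.5 mm, falling back to the native rule on frames outside the stent when the
lesion extends beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annotation import (
    Pullback,
    ThresholdConfig,
    ValidationError,
    equivalent_radius,
)

__all__ = [
    "LesionRecord",
    "RuptureSite",
    "NoLesionError",
    "delimit_lesion",
    "find_mla",
    "split_segments",
    "radius_gradient",
    "area_stenosis",
    "classify_rupture_sites",
    "analyze_lesion_geometry",
]

#: Longitudinal segment labels. The throat of the stenosis is identified
#: with the MLA-site segment (2.5 mm to either side of the MLA).
UPSTREAM, MLA_SITE, DOWNSTREAM = "upstream", "mla_site", "downstream"


class NoLesionError(ValueError):
    """No frame satisfies the lesion-delimitation rule."""


@dataclass
class LesionRecord:
    """A delimited culprit lesion and its longitudinal geometry metrics."""

    pullback_ref: str
    start_frame: int
    end_frame: int
    lesion_length_mm: float
    mla_mm2: float
    mla_frame: int
    prox_ref_area_mm2: Optional[float] = None
    dist_ref_area_mm2: Optional[float] = None
    area_stenosis_pct: Optional[float] = None
    rg_upstream: Optional[float] = None
    rg_downstream: Optional[float] = None
    segments: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.start_frame <= self.mla_frame <= self.end_frame:
            raise ValidationError("MLA frame must lie within lesion limits")
        if self.area_stenosis_pct is not None and not (
            0.0 <= self.area_stenosis_pct < 100.0
        ):
            raise ValidationError("area stenosis must be in [0, 100)")


@dataclass
class RuptureSite:
    """A contiguous run of rupture frames with its location classes.

    ``circumferential_class`` (center vs shoulder of the lipid pool) is
    convention-dependent: the rupture-arc midpoint within a configurable
    angular tolerance of a lipid-arc edge counts as shoulder.
    """

    frame_range: tuple[int, int]
    longitudinal_class: str
    circumferential_class: str
    distance_to_mla_mm: float
    peak_frame: int
    peak_arc_deg: float
    convention_note: str = "shoulder = rupture midpoint within tolerance of a lipid-arc edge"


def _index_of(pullback: Pullback, frame_index: int) -> int:
    for i, f in enumerate(pullback.frames):
        if f.frame_index == frame_index:
            return i
    raise KeyError(f"frame_index {frame_index} not in pullback")


def _frame_qualifies_nv(frame, thresholds: ThresholdConfig) -> bool:
    if frame.arcs_of("lipid"):
        return True
    burden = frame.plaque_burden_pct()
    # frames with invisible EEM are skipped for the burden criterion
    return burden is not None and burden >= thresholds.plaque_burden_min_pct


def _frame_qualifies_na(frame, thresholds: ThresholdConfig) -> bool:
    in_stent = frame.stent_area_mm2 is not None or frame.neointima_thickness_mm is not None
    if in_stent:
        return (
            frame.neointima_thickness_mm is not None
            and frame.neointima_thickness_mm >= thresholds.neointima_min_thickness_mm
        )
    # beyond the stented segment the native-vessel rule applies
    return _frame_qualifies_nv(frame, thresholds)


def delimit_lesion(
    pullback: Pullback, thresholds: ThresholdConfig | None = None
) -> tuple[int, int]:
    """Proximal/distal lesion limits as (start_frame, end_frame) indices.

    Frames are ordered proximal-to-distal by increasing index and z (the
    flow direction); the returned pair is the first (proximal) and last
    (distal) qualifying frame.  Raises
    :class:`NoLesionError` when no frame qualifies.
    """
    thresholds = thresholds or ThresholdConfig()
    qualify = _frame_qualifies_na if pullback.group == "PR-NA" else _frame_qualifies_nv
    hits = [f.frame_index for f in pullback.frames if qualify(f, thresholds)]
    if not hits:
        raise NoLesionError(f"no frame satisfies the {pullback.group} lesion rule")
    return hits[0], hits[-1]


def find_mla(pullback: Pullback, start: int, end: int) -> tuple[int, float]:
    """Frame with the minimum lumen area in [start, end].

    Ties are broken toward the most distal frame (highest index within
    the tie, under the proximal-to-distal frame ordering).
    """
    if start > end:
        raise ValueError(f"empty frame range [{start}, {end}]")
    frames = [f for f in pullback.frames if start <= f.frame_index <= end]
    if not frames:
        raise ValueError(f"no frames in range [{start}, {end}]")
    areas = np.array([f.lumen_area() for f in frames])
    i = int(np.flatnonzero(areas == areas.min())[-1])  # last = most distal
    return frames[i].frame_index, float(areas[i])


def split_segments(
    pullback: Pullback,
    start: int,
    end: int,
    mla_frame: int,
    thresholds: ThresholdConfig | None = None,
) -> dict[int, str]:
    """Assign every lesion frame to upstream / mla_site / downstream.

    The MLA site spans ``segment_half_length_mm`` (default 2.5 mm) to either
    side of the MLA; frames landing exactly on a boundary belong to the MLA
    site.  Segments may be empty for short lesions.
    """
    thresholds = thresholds or ThresholdConfig()
    half = thresholds.segment_half_length_mm
    z_mla = pullback.frames[_index_of(pullback, mla_frame)].z_mm
    segments: dict[int, str] = {}
    for f in pullback.frames:
        if not start <= f.frame_index <= end:
            continue
        dz = f.z_mm - z_mla
        if abs(dz) <= half + 1e-9:
            segments[f.frame_index] = MLA_SITE
        elif dz < 0:
            segments[f.frame_index] = UPSTREAM
        else:
            segments[f.frame_index] = DOWNSTREAM
    return segments


def _lumen_radius_at(pullback: Pullback, frame_index: int) -> float:
    f = pullback.frames[_index_of(pullback, frame_index)]
    return equivalent_radius(f.lumen_area())


def radius_gradient(
    pullback: Pullback, start: int, end: int, mla_frame: int
) -> tuple[Optional[float], Optional[float]]:
    """Upstream and downstream radius gradient (mm of radius per mm of length).

    RG = (lumen radius at the lesion end - radius at the MLA) / segment
    length, measured along the pullback axis from each lesion end to the MLA
    frame.  A side of zero length (MLA at the lesion end) yields None for
    that side.
    """
    z = {f.frame_index: f.z_mm for f in pullback.frames}
    r_mla = _lumen_radius_at(pullback, mla_frame)
    rg_up = rg_down = None
    l_up = z[mla_frame] - z[start]
    if l_up > 0:
        rg_up = (_lumen_radius_at(pullback, start) - r_mla) / l_up
    l_down = z[end] - z[mla_frame]
    if l_down > 0:
        rg_down = (_lumen_radius_at(pullback, end) - r_mla) / l_down
    return rg_up, rg_down


def area_stenosis(
    mla_mm2: float, prox_ref_area_mm2: float, dist_ref_area_mm2: float
) -> float:
    """Percent area stenosis relative to the mean of the two reference areas."""
    if prox_ref_area_mm2 is None or dist_ref_area_mm2 is None:
        raise ValueError("both reference areas are required")
    ref = 0.5 * (prox_ref_area_mm2 + dist_ref_area_mm2)
    if ref <= 0:
        raise ValueError("reference areas must be positive")
    return 100.0 * (1.0 - mla_mm2 / ref)


def _rupture_runs(pullback: Pullback, start: int, end: int) -> list[list[int]]:
    runs: list[list[int]] = []
    prev = None
    for f in pullback.frames:
        if not (start <= f.frame_index <= end and f.rupture_present):
            prev = None
            continue
        if not f.arcs_of("rupture"):
            raise ValidationError(
                f"frame {f.frame_index}: rupture_present without a rupture arc"
            )
        if prev is not None and f.frame_index == prev + 1:
            runs[-1].append(f.frame_index)
        else:
            runs.append([f.frame_index])
        prev = f.frame_index
    return runs


def classify_rupture_sites(
    pullback: Pullback,
    start: int,
    end: int,
    mla_frame: int,
    thresholds: ThresholdConfig | None = None,
) -> list[RuptureSite]:
    """Group contiguous rupture frames into sites and classify each.

    Longitudinal class is the segment of the site's peak frame (the frame
    with the widest rupture arc), with the MLA-site segment reported as
    "throat".  Circumferential class is "shoulder" when the rupture-arc
    midpoint lies within ``shoulder_tolerance_deg`` of a lipid-arc edge on
    the peak frame, else "center".
    """
    thresholds = thresholds or ThresholdConfig()
    segments = split_segments(pullback, start, end, mla_frame, thresholds)
    z = {f.frame_index: f.z_mm for f in pullback.frames}
    by_index = {f.frame_index: f for f in pullback.frames}
    sites: list[RuptureSite] = []
    for run in _rupture_runs(pullback, start, end):
        arcs = {fi: by_index[fi].total_arc_deg("rupture") for fi in run}
        peak = max(run, key=lambda fi: arcs[fi])
        seg = segments.get(peak, MLA_SITE)
        longitudinal = "throat" if seg == MLA_SITE else seg
        peak_frame = by_index[peak]
        rupture_arcs = peak_frame.arcs_of("rupture")
        mid = max(rupture_arcs, key=lambda a: a.width_deg).midpoint_deg
        circumferential = "center"
        for lip in peak_frame.arcs_of("lipid"):
            for edge in (lip.start_deg, lip.end_deg):
                d = abs((mid - edge + 180.0) % 360.0 - 180.0)
                if d <= thresholds.shoulder_tolerance_deg:
                    circumferential = "shoulder"
        sites.append(
            RuptureSite(
                frame_range=(run[0], run[-1]),
                longitudinal_class=longitudinal,
                circumferential_class=circumferential,
                distance_to_mla_mm=abs(z[peak] - z[mla_frame]),
                peak_frame=peak,
                peak_arc_deg=arcs[peak],
            )
        )
    return sites


def analyze_lesion_geometry(
    pullback: Pullback,
    thresholds: ThresholdConfig | None = None,
    pullback_ref: str = "",
) -> tuple[LesionRecord, list[RuptureSite]]:
    """Full longitudinal-geometry pass: delimit, locate MLA, split, score."""
    thresholds = thresholds or ThresholdConfig()
    start, end = delimit_lesion(pullback, thresholds)
    mla_frame, mla = find_mla(pullback, start, end)
    z = {f.frame_index: f.z_mm for f in pullback.frames}
    by_index = {f.frame_index: f for f in pullback.frames}
    prox_ref = by_index[start].lumen_area()
    dist_ref = by_index[end].lumen_area()
    rg_up, rg_down = radius_gradient(pullback, start, end, mla_frame)
    record = LesionRecord(
        pullback_ref=pullback_ref,
        start_frame=start,
        end_frame=end,
        lesion_length_mm=z[end] - z[start],
        mla_mm2=mla,
        mla_frame=mla_frame,
        prox_ref_area_mm2=prox_ref,
        dist_ref_area_mm2=dist_ref,
        area_stenosis_pct=area_stenosis(mla, prox_ref, dist_ref),
        rg_upstream=rg_up,
        rg_downstream=rg_down,
        segments=split_segments(pullback, start, end, mla_frame, thresholds),
    )
    sites = classify_rupture_sites(pullback, start, end, mla_frame, thresholds)
    return record, sites
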