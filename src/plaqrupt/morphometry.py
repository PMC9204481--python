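"""Tissue-composition and rupture morphometry.

Lesion-level metrics: fibroatheroma phenotype (TCFA/ThCFA), minimum and
mean fibrous cap thickness (FCT), lipid / calcific / lined-macrophage
indices, micro-channel and cholesterol-crystal incidence, rupture length,
depth, arc and extent index, and the thrombus score; plus the frame-level
feature-prevalence aggregation over a cohort.

A tissue index expresses the fraction of the unrolled lesion surface
occupied by a tissue::

    index = 100 * (mean arc in degrees * tissue length) / (lesion length * 360)

The per-frame arc of a tissue is the summed width of its arcs on that frame
(capped at 360 deg); the tissue length is the number of frames carrying any
such arc times the frame spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .annotation import FrameAnnotation, Pullback, ThresholdConfig, ValidationError

__all__ = [
    "MorphometryResult",
    "tissue_index",
    "classify_phenotype",
    "cap_statistics",
    "detect_microchannel_runs",
    "thrombus_score",
    "rupture_metrics",
    "frame_prevalence",
    "compute_morphometry",
    "FRAME_FEATURES",
]

TCFA, THCFA, NON_FIBROATHEROMA = "TCFA", "ThCFA", "non_fibroatheroma"


@dataclass
class MorphometryResult:
    """Per-lesion tissue-composition and rupture metrics."""

    phenotype: str
    min_fct_um: Optional[float]
    mean_fct_um: Optional[float]
    mean_lipid_arc_deg: float
    lipid_length_mm: float
    lipid_index: float
    lipid_index_raw: float
    calcific_present: bool
    mean_calcific_arc_deg: float
    calcific_length_mm: float
    calcific_index: float
    macrophages_present: bool
    spotted_macrophages: bool
    lined_macrophages: bool
    lined_macrophage_index: float
    microchannel_present: bool
    crystal_present: bool
    n_rupture_sites: int
    rupture_length_mm: float
    rupture_depth_mm: float
    rupture_arc_deg: float
    rupture_extent_index: float
    thrombus_present: bool
    thrombus_score_pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.thrombus_score_pct <= 100.0:
            raise ValidationError("thrombus score must be in [0, 100]")
        if (
            self.min_fct_um is not None
            and self.mean_fct_um is not None
            and self.min_fct_um > self.mean_fct_um + 1e-9
        ):
            raise ValidationError("min FCT cannot exceed mean FCT")


def tissue_index(
    mean_arc_deg: float, tissue_length_mm: float, lesion_length_mm: float
) -> float:
    """Percent of the unrolled lesion surface occupied by a tissue."""
    if lesion_length_mm <= 0:
        raise ValueError("lesion length must be positive")
    if not 0.0 <= mean_arc_deg <= 360.0:
        raise ValueError("mean arc must be in [0, 360] degrees")
    if tissue_length_mm < 0 or tissue_length_mm > lesion_length_mm + 1e-9:
        raise ValueError("tissue length must be in [0, lesion length]")
    return 100.0 * (mean_arc_deg * tissue_length_mm) / (lesion_length_mm * 360.0)


def classify_phenotype(
    frames: Sequence[FrameAnnotation], thresholds: ThresholdConfig | None = None
) -> str:
    """Lesion phenotype: TCFA, ThCFA, or non-fibroatheroma.

    A lesion is a fibroatheroma when any frame carries more than a quadrant
    (> 90 deg) of lipid tissue; a fibroatheroma is thin-capped (TCFA) when
    the lesion-minimum cap thickness over lipid is <= 65 um (inclusive),
    thick-capped (ThCFA) otherwise.
    """
    thresholds = thresholds or ThresholdConfig()
    lipid_arcs = [f.total_arc_deg("lipid") for f in frames]
    if not lipid_arcs or max(lipid_arcs) <= thresholds.fibroatheroma_min_lipid_arc_deg:
        return NON_FIBROATHEROMA
    min_fct, _ = cap_statistics(frames)
    if min_fct is None:
        raise ValidationError("fibroatheroma without cap-thickness data")
    return TCFA if min_fct <= thresholds.tcfa_cap_um else THCFA


def cap_statistics(
    frames: Sequence[FrameAnnotation],
) -> tuple[Optional[float], Optional[float]]:
    """(min, mean) fibrous cap thickness in um over all lipid frames.

    Angular cap samples are pooled across frames with equal weight; the
    minimum is taken over the same pool.  Returns (None, None) when no
    frame carries a cap profile.
    """
    pool: list[float] = []
    for f in frames:
        if f.cap_thickness_um:
            pool.extend(f.cap_thickness_um)
    if not pool:
        return None, None
    return float(min(pool)), float(np.mean(pool))


def detect_microchannel_runs(
    frames: Sequence[FrameAnnotation], thresholds: ThresholdConfig | None = None
) -> bool:
    """Micro-channels present: a qualifying hole (diameter <= 300 um) seen in
    at least 3 consecutive frames."""
    thresholds = thresholds or ThresholdConfig()
    need = thresholds.microchannel_min_consecutive_frames
    run = 0
    prev_index = None
    for f in frames:
        ok = (
            f.microchannel_diameter_um is not None
            and f.microchannel_diameter_um <= thresholds.microchannel_max_diameter_um
        )
        if ok and prev_index is not None and f.frame_index == prev_index + 1 and run:
            run += 1
        elif ok:
            run = 1
        else:
            run = 0
        prev_index = f.frame_index
        if run >= need:
            return True
    return False


def thrombus_score(frames: Sequence[FrameAnnotation]) -> float:
    """Percent of analyzed lumen quadrants containing thrombus."""
    if not frames:
        raise ValueError("thrombus score undefined for an empty lesion")
    flagged = sum(sum(f.thrombus_quadrants) for f in frames)
    return 100.0 * flagged / (4.0 * len(frames))


def rupture_metrics(
    frames: Sequence[FrameAnnotation],
    spacing_mm: float,
    lesion_length_mm: Optional[float] = None,
) -> tuple[float, float, float, float]:
    """(length_mm, depth_mm, arc_deg, extent_index) of the rupture cavity.

    Length counts contiguous rupture frames per site (n frames -> n *
    spacing) summed over sites; depth is the maximum radial distance
    between the reconstructed pre-rupture lumen border and the cavity
    border over all rupture frames; arc is the mean over rupture frames of
    the per-frame maximum rupture arc; the extent index applies the tissue
    index formula to the rupture arc and length.
    """
    rupture_frames = [f for f in frames if f.rupture_present]
    if not rupture_frames:
        return 0.0, 0.0, 0.0, 0.0
    n_contiguous = 0
    prev = None
    for f in rupture_frames:
        n_contiguous += 1
        prev = f.frame_index
    length = n_contiguous * spacing_mm

    depth = 0.0
    any_outside = False
    for f in rupture_frames:
        if f.rupture_depth_mm is not None:
            depth = max(depth, f.rupture_depth_mm)
            any_outside = True
        elif f.approximated_lumen_radius is not None and f.lumen_radius is not None:
            approx = np.asarray(f.approximated_lumen_radius, dtype=float)
            actual = np.asarray(f.lumen_radius, dtype=float)
            if approx.size == actual.size:
                d = float(np.max(actual - approx))
                if d > 0:
                    depth = max(depth, d)
                    any_outside = True
    if not any_outside:
        import warnings

        warnings.warn("rupture cavity nowhere outside the approximated lumen; depth 0")

    arcs = [
        max((a.width_deg for a in f.arcs_of("rupture")), default=0.0)
        for f in rupture_frames
    ]
    arc = float(np.mean(arcs))
    if lesion_length_mm is None:
        lesion_length_mm = (len(frames) - 1) * spacing_mm if len(frames) > 1 else spacing_mm
    extent = tissue_index(arc, min(length, lesion_length_mm), lesion_length_mm)
    return length, depth, arc, extent


# ---------------------------------------------------------------------------
# frame-level feature predicates and cohort prevalence
# ---------------------------------------------------------------------------

def _frame_min_cap(f: FrameAnnotation) -> Optional[float]:
    return min(f.cap_thickness_um) if f.cap_thickness_um else None


def _frame_tcfa(f: FrameAnnotation, t: ThresholdConfig) -> bool:
    cap = _frame_min_cap(f)
    return (
        f.total_arc_deg("lipid") > t.fibroatheroma_min_lipid_arc_deg
        and cap is not None
        and cap <= t.tcfa_cap_um
    )


def _frame_thcfa(f: FrameAnnotation, t: ThresholdConfig) -> bool:
    cap = _frame_min_cap(f)
    return (
        f.total_arc_deg("lipid") > t.fibroatheroma_min_lipid_arc_deg
        and cap is not None
        and cap > t.tcfa_cap_um
    )


FRAME_FEATURES = {
    "tcfa": _frame_tcfa,
    "thcfa": _frame_thcfa,
    "calcific": lambda f, t: bool(f.arcs_of("calcific")),
    "macrophages": lambda f, t: bool(
        f.arcs_of("macrophage_spotted") or f.arcs_of("macrophage_lined")
    ),
    "spotted_macrophages": lambda f, t: bool(f.arcs_of("macrophage_spotted")),
    "lined_macrophages": lambda f, t: bool(f.arcs_of("macrophage_lined")),
    "microchannels": lambda f, t: f.microchannel_diameter_um is not None
    and f.microchannel_diameter_um <= t.microchannel_max_diameter_um,
    "cholesterol_crystals": lambda f, t: f.cholesterol_crystal,
    "rupture": lambda f, t: f.rupture_present,
    "thrombus": lambda f, t: any(f.thrombus_quadrants),
}


def _round_half_up(x: float, ndigits: int = 1) -> float:
    scale = 10.0**ndigits
    return math.floor(x * scale + 0.5) / scale


def frame_prevalence(
    cohort: Iterable[Pullback],
    feature: str,
    thresholds: ThresholdConfig | None = None,
) -> tuple[int, int, float]:
    """(count, total, percent) of analyzed frames carrying a feature.

    The percent is rounded half-up to one decimal, matching the reporting
    convention of the lesion tables.
    """
    thresholds = thresholds or ThresholdConfig()
    if feature not in FRAME_FEATURES:
        raise ValueError(f"unknown frame feature {feature!r}; known: {sorted(FRAME_FEATURES)}")
    predicate = FRAME_FEATURES[feature]
    count = total = 0
    for pb in cohort:
        for f in pb.frames:
            total += 1
            if predicate(f, thresholds):
                count += 1
    if total == 0:
        raise ValueError("cohort contains no frames")
    return count, total, _round_half_up(100.0 * count / total)


def compute_morphometry(
    pullback: Pullback,
    start: int,
    end: int,
    n_rupture_sites: int,
    thresholds: ThresholdConfig | None = None,
) -> MorphometryResult:
    """All lesion-level tissue metrics for the delimited frame range.

    The lipid index is emitted in two variants: ``lipid_index`` uses the
    unrolled-surface formula directly (arc x length / lesion area), and
    ``lipid_index_raw`` is the un-normalized arc x length product divided by
    lesion length (degree units) — summary statistics of lesion cohorts are
    reported on both scales depending on the normalization chosen.
    """
    thresholds = thresholds or ThresholdConfig()
    frames = [f for f in pullback.frames if start <= f.frame_index <= end]
    if not frames:
        raise ValueError("empty lesion frame range")
    spacing = pullback.frame_spacing_mm
    lesion_length = frames[-1].z_mm - frames[0].z_mm
    if lesion_length <= 0:
        lesion_length = spacing

    def arc_stats(kind: str) -> tuple[float, float]:
        arcs = [f.total_arc_deg(kind) for f in frames if f.arcs_of(kind)]
        if not arcs:
            return 0.0, 0.0
        return float(np.mean(arcs)), len(arcs) * spacing

    lipid_arc, lipid_len = arc_stats("lipid")
    calc_arc, calc_len = arc_stats("calcific")
    lined_arc, lined_len = arc_stats("macrophage_lined")
    min_fct, mean_fct = cap_statistics(frames)

    r_length, r_depth, r_arc, r_extent = rupture_metrics(
        frames, spacing, lesion_length
    )

    def idx(arc: float, ln: float) -> float:
        return tissue_index(arc, min(ln, lesion_length), lesion_length)

    return MorphometryResult(
        phenotype=classify_phenotype(frames, thresholds),
        min_fct_um=min_fct,
        mean_fct_um=mean_fct,
        mean_lipid_arc_deg=lipid_arc,
        lipid_length_mm=lipid_len,
        lipid_index=idx(lipid_arc, lipid_len),
        lipid_index_raw=lipid_arc * min(lipid_len, lesion_length) / lesion_length,
        calcific_present=calc_len > 0,
        mean_calcific_arc_deg=calc_arc,
        calcific_length_mm=calc_len,
        calcific_index=idx(calc_arc, calc_len),
        macrophages_present=any(
            f.arcs_of("macrophage_spotted") or f.arcs_of("macrophage_lined")
            for f in frames
        ),
        spotted_macrophages=any(f.arcs_of("macrophage_spotted") for f in frames),
        lined_macrophages=lined_len > 0,
        lined_macrophage_index=idx(lined_arc, lined_len),
        microchannel_present=detect_microchannel_runs(frames, thresholds),
        crystal_present=any(f.cholesterol_crystal for f in frames),
        n_rupture_sites=n_rupture_sites,
        rupture_length_mm=r_length,
        rupture_depth_mm=r_depth,
        rupture_arc_deg=r_arc,
        rupture_extent_index=r_extent,
        thrombus_present=any(any(f.thrombus_quadrants) for f in frames),
        thrombus_score_pct=thrombus_score(frames),
    )
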