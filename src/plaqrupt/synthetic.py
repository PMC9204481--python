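"""Synthetic lesion cohorts and frame-level pullbacks.

Generates cohorts with the statistical structure of the two study groups —
ruptured plaques in native vessels (PR-NV, n = 56) and in
neoatherosclerotic stented segments (PR-NA, n = 24) — so the whole
analysis pipeline is testable without patient data.

Continuous per-lesion metrics are drawn from truncated normal
distributions whose parent parameters are re-targeted so the realized
(post-truncation) mean and SD match the published cohort summaries;
binary features are Bernoulli draws at the published incidences.  Metrics
are drawn with independent margins (pairwise correlations are not
published); physical consistency (MLA below both reference areas, minimum
cap not above the mean cap, tissue lengths within the lesion) is enforced
by redrawing the non-focal member of each constraint so the headline
margins stay unbiased.

``synthesize_pullback`` inverts the morphometry pipeline: it builds a
cosine-taper lumen from a cohort row, samples frames at the pullback
spacing, paints tissue arcs, cap-thickness profiles, the rupture cavity
and thrombus quadrants so that lesion delimitation and morphometry
recover the row's metrics within discretization tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .annotation import ArcSpan, FrameAnnotation, Pullback, equivalent_radius

__all__ = [
    "GroupParams",
    "PRNV_PARAMS",
    "PRNA_PARAMS",
    "group_params",
    "simulate_cohort",
    "synthesize_pullback",
    "truncated_normal_parent",
]

#: Published cohort summaries for ruptured plaques in native vessels
#: (n = 56).  Continuous rows: (mean, sd, lower bound, upper bound);
#: binary rows: incidence.
PRNV_PARAMS = {
    "n": 56,
    "continuous": {
        "lesion_length_mm": (16.3, 6.0, 2.0, np.inf),
        "mla_mm2": (2.93, 2.03, 0.0, np.inf),
        "prox_ref_area_mm2": (9.21, 4.11, 0.0, np.inf),
        "dist_ref_area_mm2": (7.78, 3.87, 0.0, np.inf),
        "min_fct_um": (49.0, 22.0, 0.0, np.inf),
        "mean_fct_um": (186.0, 65.0, 0.0, np.inf),
        "mean_lipid_arc_deg": (150.5, 49.4, 46.0, 359.0),
        "lipid_length_mm": (6.1, 5.3, 0.4, np.inf),
        "mean_calcific_arc_deg": (62.8, 31.0, 5.0, 359.0),
        "rupture_length_mm": (2.4, 2.2, 0.4, np.inf),
        "rupture_depth_mm": (0.9, 0.5, 0.05, np.inf),
        "rupture_arc_deg": (58.7, 35.1, 5.0, 359.0),
        "thrombus_score_pct": (21.8, 18.3, 0.0, 100.0),
    },
    "binary": {
        "calcific_present": 31 / 56,
        "macrophages_present": 52 / 56,
        "spotted_macrophages": 50 / 56,
        "lined_macrophages": 48 / 56,
        "crystal_present": 0.345,
        "microchannel_present": 0.414,
        "thrombus_present": 43 / 56,
    },
    "rupture_sites_p2": 0.1,  # P(two sites); mean site count 1.1
}

#: Published cohort summaries for ruptured neoatherosclerotic lesions
#: (n = 24).
PRNA_PARAMS = {
    "n": 24,
    "continuous": {
        "lesion_length_mm": (14.8, 11.1, 2.0, np.inf),
        "mla_mm2": (2.00, 1.26, 0.0, np.inf),
        "prox_ref_area_mm2": (5.80, 2.99, 0.0, np.inf),
        "dist_ref_area_mm2": (4.96, 2.11, 0.0, np.inf),
        "min_fct_um": (60.0, 38.0, 0.0, np.inf),
        "mean_fct_um": (232.0, 80.0, 0.0, np.inf),
        "mean_lipid_arc_deg": (167.3, 34.0, 46.0, 359.0),
        "lipid_length_mm": (7.8, 8.6, 0.4, np.inf),
        "mean_calcific_arc_deg": (79.2, 14.7, 5.0, 359.0),
        "rupture_length_mm": (1.9, 2.0, 0.4, np.inf),
        "rupture_depth_mm": (0.6, 0.3, 0.05, np.inf),
        "rupture_arc_deg": (64.7, 31.5, 5.0, 359.0),
        "thrombus_score_pct": (21.5, 17.3, 0.0, 100.0),
    },
    "binary": {
        "calcific_present": 5 / 24,
        "macrophages_present": 21 / 24,
        "spotted_macrophages": 20 / 24,
        "lined_macrophages": 18 / 24,
        "crystal_present": 0.33,
        "microchannel_present": 0.125,
        "thrombus_present": 21 / 24,
    },
    "rupture_sites_p2": 0.2,
}


@dataclass
class GroupParams:
    """Distribution specs for one simulated cohort."""

    group: str
    n: int
    continuous: dict[str, tuple[float, float, float, float]]
    binary: dict[str, float]
    rupture_sites_p2: float
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (mean, sd, lo, hi) in self.continuous.items():
            if sd <= 0 or not lo < hi:
                raise ValueError(f"{name}: invalid distribution spec")
            if not lo <= mean <= hi:
                raise ValueError(f"{name}: mean outside truncation bounds")
        for name, p in self.binary.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}: incidence outside [0, 1]")


def group_params(group: str, n: Optional[int] = None, seed: int = 0) -> GroupParams:
    """Published-parameter spec for "PR-NV" or "PR-NA"."""
    src = {"PR-NV": PRNV_PARAMS, "PR-NA": PRNA_PARAMS}.get(group)
    if src is None:
        raise ValueError(f"unknown group {group!r}")
    return GroupParams(
        group=group,
        n=n if n is not None else src["n"],
        continuous=dict(src["continuous"]),
        binary=dict(src["binary"]),
        rupture_sites_p2=src["rupture_sites_p2"],
        seed=seed,
    )


_PARENT_CACHE: dict[tuple, tuple[float, float]] = {}


def truncated_normal_parent(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Parent (mu, sigma) whose [lo, hi]-truncated normal has the target
    mean and SD (moment re-targeting); returns (mean, sd) unchanged when
    truncation is negligible."""
    key = (mean, sd, lo, hi)
    if key in _PARENT_CACHE:
        return _PARENT_CACHE[key]
    z_lo = (lo - mean) / sd
    z_hi = (hi - mean) / sd if np.isfinite(hi) else np.inf
    if z_lo < -6 and z_hi > 6:
        _PARENT_CACHE[key] = (mean, sd)
        return mean, sd

    def moments(params):
        mu, log_sig = params
        sig = math.exp(log_sig)
        a, b = (lo - mu) / sig, ((hi - mu) / sig) if np.isfinite(hi) else np.inf
        d = sps.truncnorm(a, b, loc=mu, scale=sig)
        return [d.mean() - mean, d.std() - sd]

    sol = optimize.root(moments, x0=[mean, math.log(sd)], method="hybr")
    if not sol.success:
        raise ValueError(
            f"infeasible truncated-normal target mean={mean}, sd={sd} on [{lo}, {hi}]"
        )
    mu, sig = float(sol.x[0]), float(math.exp(sol.x[1]))
    _PARENT_CACHE[key] = (mu, sig)
    return mu, sig


def _draw(rng: np.random.Generator, spec: tuple, size: int) -> np.ndarray:
    """Moment-matched draw on [lo, hi].

    Truncated normal where feasible.  A lower-truncated normal cannot
    realize SD >= (mean - lo); published summaries of strongly skewed
    metrics (e.g. rupture and lipid lengths) exceed that limit, and those
    rows fall back to a moment-matched shifted lognormal on [lo, inf),
    clipped at a finite upper bound (negligible mass there).
    """
    mean, sd, lo, hi = spec
    if sd < 0.93 * (mean - lo):
        mu, sig = truncated_normal_parent(mean, sd, lo, hi)
        a = (lo - mu) / sig
        b = ((hi - mu) / sig) if np.isfinite(hi) else np.inf
        return sps.truncnorm(a, b, loc=mu, scale=sig).rvs(size=size, random_state=rng)
    shift = mean - lo
    s2 = math.log(1.0 + (sd / shift) ** 2)
    m = math.log(shift) - s2 / 2.0
    x = lo + rng.lognormal(mean=m, sigma=math.sqrt(s2), size=size)
    return np.clip(x, lo, hi)


def simulate_cohort(params: GroupParams) -> pd.DataFrame:
    """One synthetic cohort: a per-lesion metric table, n rows.

    Deterministic given ``params.seed``.  Constraint handling: where a
    drawn MLA is not below 95% of both reference areas, the *references*
    are redrawn; where a minimum cap is not below the mean cap, the
    *minimum* is redrawn; lipid and rupture lengths are redrawn against
    the drawn lesion length.  Derived columns: area stenosis and the
    per-lesion rupture-site count.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    df = pd.DataFrame(
        {name: _draw(rng, spec, n) for name, spec in params.continuous.items()}
    )

    def redraw(mask: np.ndarray, col: str, accept) -> None:
        for _ in range(200):
            if not mask.any():
                return
            df.loc[mask, col] = _draw(rng, params.continuous[col], int(mask.sum()))
            mask = ~accept()
        # a handful of pathological rows: clip rather than loop forever
        df.loc[mask, col] = np.clip(df.loc[mask, col], None, None)

    ref_ok = lambda: (df["mla_mm2"] < 0.95 * df[["prox_ref_area_mm2",
                                                 "dist_ref_area_mm2"]].min(axis=1))
    redraw(~ref_ok().to_numpy(), "prox_ref_area_mm2", ref_ok)
    redraw(~ref_ok().to_numpy(), "dist_ref_area_mm2", ref_ok)
    # rare pathological rows: raise the references (never touch the MLA,
    # whose margin must stay moment-exact)
    bad = ~ref_ok()
    for col in ("prox_ref_area_mm2", "dist_ref_area_mm2"):
        df.loc[bad, col] = np.maximum(df.loc[bad, col], df.loc[bad, "mla_mm2"] / 0.9)

    fct_ok = lambda: df["min_fct_um"] < 0.95 * df["mean_fct_um"]
    redraw(~fct_ok().to_numpy(), "min_fct_um", fct_ok)
    df.loc[~fct_ok(), "min_fct_um"] = 0.9 * df.loc[~fct_ok(), "mean_fct_um"]

    for col in ("lipid_length_mm", "rupture_length_mm"):
        ok = lambda c=col: df[c] <= 0.9 * df["lesion_length_mm"]
        redraw(~ok().to_numpy(), col, ok)
        df.loc[~ok(), col] = 0.8 * df.loc[~ok(), "lesion_length_mm"]

    for name, p in params.binary.items():
        df[name] = rng.random(n) < p
    # thrombus score is a mixture: exactly 0 without thrombus; the
    # conditional distribution is re-targeted so the overall mean/SD still
    # match the published row
    p_thr = params.binary["thrombus_present"]
    mean_s, sd_s, lo_s, hi_s = params.continuous["thrombus_score_pct"]
    if p_thr > 0:
        mean_pos = mean_s / p_thr
        var_pos = (sd_s**2 + mean_s**2) / p_thr - mean_pos**2
        sd_pos = math.sqrt(max(var_pos, 1.0))
        pos = df["thrombus_present"].to_numpy()
        scores = np.zeros(n)
        scores[pos] = _draw(rng, (mean_pos, sd_pos, max(lo_s, 1.0), hi_s), int(pos.sum()))
        df["thrombus_score_pct"] = scores
    else:
        df["thrombus_score_pct"] = 0.0
    df["n_rupture_sites"] = 1 + (rng.random(n) < params.rupture_sites_p2)
    df.loc[~df["calcific_present"], "mean_calcific_arc_deg"] = np.nan
    df["area_stenosis_pct"] = 100.0 * (
        1.0 - df["mla_mm2"] / (0.5 * (df["prox_ref_area_mm2"] + df["dist_ref_area_mm2"]))
    )
    df["group"] = params.group
    df.index.name = "lesion"
    return df


# ---------------------------------------------------------------------------
# pullback synthesis (inverse morphometry)
# ---------------------------------------------------------------------------

N_CAP_SAMPLES = 8          # cap-thickness samples painted per lipid frame
N_RADIUS_SAMPLES = 72      # angular samples on rupture-frame lumen profiles
MARGIN_FRAMES = 5          # healthy reference frames beyond each lesion end


def _cosine_radius(z: np.ndarray, z_mla: float, length: float,
                   r_start: float, r_min: float, r_end: float) -> np.ndarray:
    r = np.empty_like(z)
    up = z <= z_mla
    t = np.clip(z[up] / max(z_mla, 1e-9), 0, 1)
    r[up] = r_start + (r_min - r_start) * 0.5 * (1 - np.cos(math.pi * t))
    t = np.clip((z[~up] - z_mla) / max(length - z_mla, 1e-9), 0, 1)
    r[~up] = r_min + (r_end - r_min) * 0.5 * (1 - np.cos(math.pi * t))
    return r


def synthesize_pullback(
    row: pd.Series | dict,
    seed: int = 0,
    spacing_mm: float = 0.4,
    group: Optional[str] = None,
) -> Pullback:
    """Build a frame-level pullback whose analysis recovers a cohort row.

    The lumen is a cosine-taper stenosis from the proximal reference area
    through the MLA to the distal reference area (frames ordered
    proximal-to-distal along the flow direction); tissue arcs, cap profiles, the
    rupture cavity, thrombus quadrants and feature flags are painted to
    match the row's metrics.  Native rows get EEM areas (plaque burden
    ~50% inside the lesion, ~25% in the reference margins);
    neoatherosclerotic rows get stent areas and neointima thickness
    (>=0.5 mm inside the lesion only).
    """
    row = dict(row)
    group = group or row.get("group", "PR-NV")
    rng = np.random.default_rng(seed)

    L = float(row["lesion_length_mm"])
    if not L > 0:
        raise ValueError(f"unrealizable lesion: non-positive length {L}")
    if float(row["lipid_length_mm"]) > L + 1e-9:
        raise ValueError("unrealizable lesion: lipid length exceeds lesion length")
    if float(row["rupture_length_mm"]) > L + 1e-9:
        raise ValueError("unrealizable lesion: rupture length exceeds lesion length")
    if float(row["mla_mm2"]) >= min(float(row["prox_ref_area_mm2"]),
                                    float(row["dist_ref_area_mm2"])):
        raise ValueError("unrealizable lesion: MLA not below the reference areas")
    n_lesion = max(int(round(L / spacing_mm)) + 1, 3)
    lesion_len_snap = (n_lesion - 1) * spacing_mm
    n_total = n_lesion + 2 * MARGIN_FRAMES
    start, end = MARGIN_FRAMES, MARGIN_FRAMES + n_lesion - 1
    z = np.arange(n_total) * spacing_mm
    z_lesion0 = z[start]

    r_prox = equivalent_radius(float(row["prox_ref_area_mm2"]))
    r_dist = equivalent_radius(float(row["dist_ref_area_mm2"]))
    r_min = equivalent_radius(float(row["mla_mm2"]))
    # MLA on the frame grid near mid-lesion
    i_mla_local = n_lesion // 2
    z_mla_local = i_mla_local * spacing_mm
    zl = z[start : end + 1] - z_lesion0
    r = _cosine_radius(zl, z_mla_local, lesion_len_snap, r_prox, r_min, r_dist)
    r[i_mla_local] = r_min
    areas = np.empty(n_total)
    areas[start : end + 1] = math.pi * r**2
    areas[:start] = math.pi * r_prox**2
    areas[end + 1 :] = math.pi * r_dist**2
    mla_frame = start + i_mla_local

    # --- lipid pool and cap profile ------------------------------------
    lipid_arc = float(row["mean_lipid_arc_deg"])
    n_lip = int(np.clip(round(float(row["lipid_length_mm"]) / spacing_mm), 1, n_lesion))
    lip_first = int(np.clip(i_mla_local - (2 * n_lip) // 3, 0, n_lesion - n_lip))
    lipid_frames = set(range(start + lip_first, start + lip_first + n_lip))
    lipid_start_deg = float(rng.uniform(0.0, 360.0))
    min_fct = float(row["min_fct_um"])
    mean_fct = float(row["mean_fct_um"])
    n_samples = n_lip * N_CAP_SAMPLES
    fill = (n_samples * mean_fct - min_fct) / max(n_samples - 1, 1)
    # the thinnest cap sits on the lipid frame nearest the MLA (proximal side)
    min_cap_frame = min(max(lipid_frames), mla_frame) if lipid_frames else mla_frame
    if min_cap_frame not in lipid_frames:
        min_cap_frame = max(lipid_frames)

    # --- calcific / macrophage / crystal / microchannel placement ------
    def pick_frames(n_pick: int, exclude: set = frozenset()) -> set:
        candidates = [i for i in range(start, end + 1) if i not in exclude]
        n_pick = min(n_pick, len(candidates))
        return set(rng.choice(candidates, size=n_pick, replace=False)) if n_pick else set()

    calc_frames: set = set()
    calc_arc = 0.0
    if row.get("calcific_present"):
        calc_arc = float(row.get("mean_calcific_arc_deg") or 60.0)
        calc_frames = pick_frames(max(1, int(0.15 * n_lesion)))
    lined_frames: set = set()
    if row.get("lined_macrophages"):
        lined_frames = pick_frames(max(1, int(0.2 * n_lesion)))
    spotted_frames: set = set()
    if row.get("spotted_macrophages"):
        spotted_frames = pick_frames(max(1, int(0.2 * n_lesion)))
    crystal_frames: set = set()
    if row.get("crystal_present"):
        crystal_frames = pick_frames(max(1, int(0.1 * n_lesion)))
    micro_frames: set = set()
    if row.get("microchannel_present"):
        first = int(rng.integers(start, end - 2))
        micro_frames = {first, first + 1, first + 2}

    # --- rupture site(s) -------------------------------------------------
    rupture_frames: list[int] = []
    n_sites = int(row.get("n_rupture_sites", 1))
    n_rup = max(1, int(round(float(row["rupture_length_mm"]) / spacing_mm)))
    rupture_arc = float(row["rupture_arc_deg"])
    rupture_depth = float(row["rupture_depth_mm"])
    site_lens = [n_rup] if n_sites == 1 else [max(1, n_rup // 2), max(1, n_rup - n_rup // 2)]
    cursor = mla_frame - n_rup // 2
    for k, sl in enumerate(site_lens):
        first = int(np.clip(cursor, start, end - sl + 1))
        rupture_frames.extend(range(first, first + sl))
        cursor = first + sl + 2  # gap so sites stay distinct
    rupture_frames = sorted(set(rupture_frames))
    peak_rupture = rupture_frames[len(rupture_frames) // 2]

    # --- thrombus quadrants ----------------------------------------------
    total_quadrants = 4 * n_lesion
    n_thrombus_q = int(round(float(row["thrombus_score_pct"]) / 100.0 * total_quadrants))
    if row.get("thrombus_present") and n_thrombus_q == 0:
        n_thrombus_q = 1
    if not row.get("thrombus_present", True):
        n_thrombus_q = 0
    quadrant_slots = [(f, q) for f in range(start, end + 1) for q in range(4)]
    thrombus_slots = set(
        map(tuple, rng.permutation(quadrant_slots)[:n_thrombus_q].tolist())
    )

    theta = np.linspace(0.0, 360.0, N_RADIUS_SAMPLES, endpoint=False)
    frames = []
    sample_count = 0
    for i in range(n_total):
        in_lesion = start <= i <= end
        arcs: list[ArcSpan] = []
        cap = None
        if i in lipid_frames:
            arcs.append(ArcSpan(lipid_start_deg, (lipid_start_deg + lipid_arc) % 360.0, "lipid"))
            vals = [fill] * N_CAP_SAMPLES
            if i == min_cap_frame:
                vals[0] = min_fct
            cap = vals
            sample_count += N_CAP_SAMPLES
        if i in calc_frames:
            s = float(rng.uniform(0, 360))
            arcs.append(ArcSpan(s, (s + calc_arc) % 360.0, "calcific"))
        if i in lined_frames:
            s = float(rng.uniform(0, 360))
            arcs.append(ArcSpan(s, (s + 45.0) % 360.0, "macrophage_lined"))
        if i in spotted_frames:
            s = float(rng.uniform(0, 360))
            arcs.append(ArcSpan(s, (s + 30.0) % 360.0, "macrophage_spotted"))

        rupture = in_lesion and i in rupture_frames
        lumen_radius = approx_radius = None
        depth_i = None
        area_i = areas[i]
        if rupture:
            # cavity bulge over the rupture arc, deepest at the site peak
            depth_i = rupture_depth if i == peak_rupture else 0.5 * rupture_depth
            mid = (lipid_start_deg + lipid_arc / 2.0) % 360.0
            s = (mid - rupture_arc / 2.0) % 360.0
            arcs.append(ArcSpan(s, (s + rupture_arc) % 360.0, "rupture"))
            r0 = math.sqrt(area_i / math.pi)
            approx_radius = np.full(N_RADIUS_SAMPLES, r0)
            within = (theta - s) % 360.0 <= rupture_arc
            bump = np.zeros(N_RADIUS_SAMPLES)
            t = ((theta - s) % 360.0) / max(rupture_arc, 1e-9)
            bump[within] = depth_i * np.sin(math.pi * t[within]) ** 2
            # renormalize so the painted maximum equals the target depth
            if bump.max() > 0:
                bump *= depth_i / bump.max()
            lumen_radius = approx_radius + bump
            area_i = area_i + 0.5 * np.sum(
                (lumen_radius**2 - approx_radius**2)
            ) * (2 * math.pi / N_RADIUS_SAMPLES)

        quadrants = [
            in_lesion and (i, q) in thrombus_slots for q in range(4)
        ]
        if any(quadrants):
            qs = [q for q in range(4) if quadrants[q]]
            s = qs[0] * 90.0
            arcs.append(ArcSpan(s, (s + 90.0 * len(qs)) % 360.0, "thrombus"))

        kwargs = dict(
            frame_index=i,
            z_mm=float(z[i]),
            lumen_area_mm2=float(area_i),
            arcs=arcs,
            cap_thickness_um=cap,
            rupture_present=rupture,
            approximated_lumen_radius=tuple(approx_radius) if rupture else None,
            rupture_depth_mm=depth_i,
            thrombus_quadrants=quadrants,
            microchannel_diameter_um=float(rng.uniform(100, 280)) if i in micro_frames else None,
            cholesterol_crystal=i in crystal_frames,
        )
        if rupture:
            kwargs["lumen_radius"] = tuple(lumen_radius)
        if group == "PR-NV":
            burden = 0.50 if in_lesion else 0.25
            kwargs["eem_area_mm2"] = float(area_i / (1.0 - burden))
        else:
            thickness = 0.7 if in_lesion else 0.2
            r_lum = math.sqrt(area_i / math.pi)
            kwargs["neointima_thickness_mm"] = thickness
            kwargs["stent_area_mm2"] = float(math.pi * (r_lum + thickness) ** 2)
        frames.append(FrameAnnotation(**kwargs))

    return Pullback(
        frames=frames,
        frame_spacing_mm=spacing_mm,
        group=group,
        metadata={"generator": "synthetic", "seed": seed},
    )
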