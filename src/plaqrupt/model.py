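"""Per-pullback analysis model.

``PlaqueAnalysis(pullback).fit()`` runs the full single-lesion pipeline —
delimitation, MLA search, segment split, radius gradients, rupture-site
classification and tissue morphometry — and returns a
:class:`PlaqueAnalysisResults` carrying the lesion record, the morphometry
and the rupture sites, with a ``summary()`` table and flat-row export used
by the cohort tables.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Optional

import pandas as pd

from .annotation import Pullback, ThresholdConfig
from .lesion import LesionRecord, RuptureSite, analyze_lesion_geometry
from .morphometry import MorphometryResult, compute_morphometry

__all__ = ["PlaqueAnalysis", "PlaqueAnalysisResults"]


class PlaqueAnalysisResults:
    """Results of a single-pullback analysis."""

    def __init__(
        self,
        lesion: LesionRecord,
        morphometry: MorphometryResult,
        rupture_sites: list[RuptureSite],
        thresholds: ThresholdConfig,
    ):
        self.lesion = lesion
        self.morphometry = morphometry
        self.rupture_sites = rupture_sites
        self.thresholds = thresholds

    def to_row(self) -> dict:
        """Flat per-lesion metric row (cohort-table input)."""
        row = {
            "lesion_length_mm": self.lesion.lesion_length_mm,
            "mla_mm2": self.lesion.mla_mm2,
            "prox_ref_area_mm2": self.lesion.prox_ref_area_mm2,
            "dist_ref_area_mm2": self.lesion.dist_ref_area_mm2,
            "area_stenosis_pct": self.lesion.area_stenosis_pct,
            "rg_upstream": self.lesion.rg_upstream,
            "rg_downstream": self.lesion.rg_downstream,
        }
        m = asdict(self.morphometry)
        m["tcfa"] = self.morphometry.phenotype == "TCFA"
        m["thcfa"] = self.morphometry.phenotype == "ThCFA"
        row.update(m)
        row["n_rupture_sites"] = len(self.rupture_sites)
        if self.rupture_sites:
            main = max(self.rupture_sites, key=lambda s: s.peak_arc_deg)
            row["rupture_longitudinal_class"] = main.longitudinal_class
            row["rupture_circumferential_class"] = main.circumferential_class
            row["rupture_distance_to_mla_mm"] = main.distance_to_mla_mm
        return row

    def summary(self) -> str:
        l, m = self.lesion, self.morphometry
        rows = [
            ("lesion frames", f"{l.start_frame}..{l.end_frame}"),
            ("lesion length (mm)", f"{l.lesion_length_mm:.1f}"),
            ("MLA (mm^2)", f"{l.mla_mm2:.2f} at frame {l.mla_frame}"),
            ("area stenosis (%)", f"{l.area_stenosis_pct:.1f}"),
            ("phenotype", m.phenotype),
            ("min / mean FCT (um)",
             f"{m.min_fct_um:.0f} / {m.mean_fct_um:.0f}" if m.min_fct_um is not None else "-"),
            ("mean lipid arc (deg)", f"{m.mean_lipid_arc_deg:.1f}"),
            ("lipid index", f"{m.lipid_index:.2f}"),
            ("rupture sites", f"{len(self.rupture_sites)}"),
            ("rupture length/depth/arc",
             f"{m.rupture_length_mm:.1f} mm / {m.rupture_depth_mm:.2f} mm / {m.rupture_arc_deg:.0f} deg"),
            ("thrombus score (%)", f"{m.thrombus_score_pct:.1f}"),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


class PlaqueAnalysis:
    """Single-pullback analysis model (statsmodels-style fit())."""

    def __init__(
        self,
        pullback: Pullback,
        thresholds: Optional[ThresholdConfig] = None,
        pullback_ref: str = "",
    ):
        self.pullback = pullback
        self.thresholds = thresholds or ThresholdConfig()
        self.pullback_ref = pullback_ref

    def fit(self) -> PlaqueAnalysisResults:
        lesion, sites = analyze_lesion_geometry(
            self.pullback, self.thresholds, self.pullback_ref
        )
        morph = compute_morphometry(
            self.pullback, lesion.start_frame, lesion.end_frame,
            n_rupture_sites=len(sites), thresholds=self.thresholds,
        )
        return PlaqueAnalysisResults(lesion, morph, sites, self.thresholds)


def analyze_cohort(
    pullbacks: list[Pullback], thresholds: Optional[ThresholdConfig] = None
) -> pd.DataFrame:
    """Per-lesion metric table for a list of pullbacks."""
    rows = []
    for k, pb in enumerate(pullbacks):
        res = PlaqueAnalysis(pb, thresholds, pullback_ref=str(k)).fit()
        row = res.to_row()
        row["group"] = pb.group
        rows.append(row)
    df = pd.DataFrame(rows)
    df.index.name = "lesion"
    return df
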