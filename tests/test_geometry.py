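"""Idealized geometry builder: profiles, wall layers, export, mean spec."""

import math

import numpy as np
import pandas as pd
import pytest

from plaqrupt.annotation import equivalent_radius
from plaqrupt.geometry import (
    IdealizedGeometry,
    LesionSpec,
    StentSpec,
    build_geometry,
    build_lumen_profile,
    build_wall,
    export_geometry,
    load_profile_csv,
    mean_lesion_spec,
)


def native_mean_spec(**overrides):
    """Cohort-mean native lesion: reference areas 9.21/7.78, MLA 2.93 mm^2."""
    kwargs = dict(
        prox_ref_diameter_mm=2 * equivalent_radius(9.21),
        dist_ref_diameter_mm=2 * equivalent_radius(7.78),
        min_lumen_diameter_mm=2 * equivalent_radius(2.93),
        lesion_length_mm=16.3,
        cap_min_um=49.0,
        cap_mean_um=186.0,
        lipid_arc_deg=150.5,
        lipid_length_mm=6.1,
    )
    kwargs.update(overrides)
    return LesionSpec(**kwargs)


def stented_mean_spec(**overrides):
    """Cohort-mean neoatherosclerotic lesion (MLA 2.00 mm^2) with a stent."""
    kwargs = dict(
        prox_ref_diameter_mm=2 * equivalent_radius(5.80),
        dist_ref_diameter_mm=2 * equivalent_radius(4.96),
        min_lumen_diameter_mm=2 * equivalent_radius(2.00),
        lesion_length_mm=14.8,
        cap_min_um=60.0,
        cap_mean_um=232.0,
        lipid_arc_deg=167.3,
        lipid_length_mm=7.8,
        stent=StentSpec(stent_diameter_mm=2.6),
    )
    kwargs.update(overrides)
    return LesionSpec(**kwargs)


class TestLumenProfile:
    def test_mla_area_exact(self):
        geom = build_geometry(native_mean_spec())
        _, mla = geom.mla()
        assert mla == pytest.approx(2.93, rel=1e-3)

    def test_minimum_at_mla_position(self):
        spec = native_mean_spec(mla_axial_position_mm=6.0)
        z, r = build_lumen_profile(spec, 201)
        assert z[np.argmin(r)] == pytest.approx(6.0, abs=0.1)

    def test_straight_tube_when_no_stenosis(self):
        spec = LesionSpec(
            prox_ref_diameter_mm=3.0, dist_ref_diameter_mm=3.0,
            min_lumen_diameter_mm=2.999999, lesion_length_mm=10.0,
        )
        _, r = build_lumen_profile(spec, 101)
        assert np.ptp(r) < 1e-5

    def test_c1_continuity(self):
        z, r = build_lumen_profile(native_mean_spec(), 2001)
        slope = np.diff(r) / np.diff(z)
        assert np.max(np.abs(np.diff(slope))) < 5e-3  # no slope jumps

    def test_mirror_symmetry(self):
        spec = LesionSpec(
            prox_ref_diameter_mm=3.0, dist_ref_diameter_mm=3.0,
            min_lumen_diameter_mm=1.5, lesion_length_mm=10.0,
        )
        _, r = build_lumen_profile(spec, 201)
        assert np.allclose(r, r[::-1], atol=1e-12)

    def test_too_few_stations_rejected(self):
        with pytest.raises(ValueError):
            build_lumen_profile(native_mean_spec(), 11)

    def test_mla_position_outside_rejected(self):
        with pytest.raises(ValueError):
            native_mean_spec(mla_axial_position_mm=20.0)


class TestWall:
    def test_cap_minimum_equals_spec(self):
        geom = build_geometry(native_mean_spec())
        _, cap_min = geom.min_cap_station()
        assert cap_min * 1000 == pytest.approx(49.0, rel=1e-6)

    def test_thinnest_cap_proximal_to_mla(self):
        geom = build_geometry(native_mean_spec())
        z_cap, _ = geom.min_cap_station()
        z_mla, _ = geom.mla()
        assert z_cap < z_mla

    def test_layer_ordering(self):
        geom = build_geometry(stented_mean_spec())
        assert np.all(geom.lumen_radius_mm < geom.cap_outer_radius_mm)
        assert np.all(geom.cap_outer_radius_mm <= geom.eem_radius_mm + 1e-12)

    def test_remodeling_index_one_gives_reference_eem(self):
        spec = native_mean_spec(remodeling_index=1.0,
                                prox_ref_eem_area_mm2=12.0,
                                dist_ref_eem_area_mm2=12.0)
        z, r = build_lumen_profile(spec, 201)
        geom = build_wall(spec, z, r)
        i_mla = int(np.argmin(geom.lumen_radius_mm))
        r_eem_expected = equivalent_radius(12.0)
        assert geom.eem_radius_mm[i_mla] == pytest.approx(r_eem_expected, rel=1e-3)

    def test_stent_ring_count(self):
        geom = build_geometry(stented_mean_spec())
        assert len(geom.strut_z_mm) == math.floor(14.8 / 1.0) + 1

    def test_cap_min_above_mean_rejected(self):
        with pytest.raises(ValueError):
            build_geometry(native_mean_spec(cap_min_um=300.0, cap_mean_um=186.0))

    def test_lumen_volume_matches_quadrature(self):
        geom = build_geometry(native_mean_spec(), n_stations=801)
        z_f = np.linspace(0, 16.3, 20001)
        r_f = np.interp(z_f, geom.z_mm, geom.lumen_radius_mm)
        v_f = np.trapezoid(math.pi * r_f**2, z_f)
        assert geom.lumen_volume_mm3() == pytest.approx(v_f, rel=1e-3)


class TestMeanSpec:
    def test_identical_lesions_reproduce_themselves(self):
        df = pd.DataFrame({
            "prox_ref_area_mm2": [9.0] * 3,
            "dist_ref_area_mm2": [7.0] * 3,
            "mla_mm2": [3.0] * 3,
            "lesion_length_mm": [15.0] * 3,
            "min_fct_um": [50.0] * 3,
            "mean_fct_um": [180.0] * 3,
            "mean_lipid_arc_deg": [150.0] * 3,
            "lipid_length_mm": [6.0] * 3,
        })
        spec = mean_lesion_spec(df, "PR-NV")
        assert spec.min_lumen_diameter_mm == pytest.approx(2 * equivalent_radius(3.0))
        assert spec.lesion_length_mm == 15.0

    def test_two_lesion_average(self):
        df = pd.DataFrame({
            "prox_ref_area_mm2": [9.0, 9.0],
            "dist_ref_area_mm2": [7.0, 7.0],
            "mla_mm2": [3.0, 3.0],
            "lesion_length_mm": [10.0, 20.0],
            "min_fct_um": [40.0, 60.0],
            "mean_fct_um": [160.0, 200.0],
            "mean_lipid_arc_deg": [140.0, 160.0],
            "lipid_length_mm": [5.0, 7.0],
        })
        spec = mean_lesion_spec(df, "PR-NV")
        assert spec.lesion_length_mm == 15.0
        assert spec.cap_min_um == 50.0

    def test_stent_diameter_defaults_to_mean_reference(self):
        df = pd.DataFrame({
            "prox_ref_area_mm2": [5.8], "dist_ref_area_mm2": [4.96],
            "mla_mm2": [2.0], "lesion_length_mm": [14.8],
            "min_fct_um": [60.0], "mean_fct_um": [232.0],
            "mean_lipid_arc_deg": [167.0], "lipid_length_mm": [7.8],
        })
        spec = mean_lesion_spec(df, "PR-NA")
        assert spec.stent is not None
        d_expected = equivalent_radius(5.8) + equivalent_radius(4.96)
        assert spec.stent.stent_diameter_mm == pytest.approx(d_expected)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            mean_lesion_spec(pd.DataFrame(), "PR-NV")


class TestExport:
    def test_profile_csv_roundtrip(self, tmp_path):
        geom = build_geometry(native_mean_spec())
        path = export_geometry(geom, tmp_path / "g.csv", "profile-csv")
        geom2 = load_profile_csv(path)
        assert np.allclose(geom2.lumen_radius_mm, geom.lumen_radius_mm)
        assert np.allclose(geom2.cap_thickness_mm, geom.cap_thickness_mm)

    def test_stl_mesh_watertight(self, tmp_path):
        import trimesh

        geom = build_geometry(native_mean_spec(), n_stations=41)
        path = export_geometry(geom, tmp_path / "g.stl", "stl")
        mesh = trimesh.load(path)
        assert mesh.is_watertight
        assert mesh.is_winding_consistent

    def test_straight_tube_mesh_volume(self, tmp_path):
        import trimesh

        spec = LesionSpec(
            prox_ref_diameter_mm=2.0, dist_ref_diameter_mm=2.0,
            min_lumen_diameter_mm=1.999999, lesion_length_mm=10.0,
        )
        geom = build_geometry(spec, n_stations=41)
        path = export_geometry(geom, tmp_path / "tube.stl", "stl")
        mesh = trimesh.load(path)
        assert abs(mesh.volume) == pytest.approx(math.pi * 1.0**2 * 10.0, rel=0.02)

    def test_vtk_export_readable(self, tmp_path):
        geom = build_geometry(native_mean_spec(), n_stations=41)
        path = export_geometry(geom, tmp_path / "g.vtk", "vtk")
        text = path.read_text()
        assert text.startswith("# vtk DataFile")
        assert "POLYGONS" in text


def test_find_mla_roundtrip_on_built_geometry():
    """Frames sampled from a built geometry recover the spec MLA."""
    from plaqrupt.annotation import FrameAnnotation, Pullback
    from plaqrupt.lesion import find_mla

    geom = build_geometry(native_mean_spec(), n_stations=801)
    z_frames = np.arange(0.0, 16.3, 0.4)
    frames = [
        FrameAnnotation(
            frame_index=i, z_mm=float(z),
            lumen_area_mm2=float(math.pi * geom.radius_at(z) ** 2),
        )
        for i, z in enumerate(z_frames)
    ]
    pb = Pullback(frames=frames)
    mla_frame, mla = find_mla(pb, 0, len(frames) - 1)
    z_mla_spec, mla_spec = geom.mla()
    assert abs(frames[mla_frame].z_mm - z_mla_spec) <= 0.4 + 1e-9
    assert mla == pytest.approx(mla_spec, rel=0.01)
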