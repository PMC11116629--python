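"""Synthetic generator: geometry, rendering and cohort contracts."""

import hashlib
import math
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from heartregen.synth import (
    GroupSpec,
    HeartModel,
    NoiseParams,
    chord_offset_for_area_fraction,
    default_scenario,
    draw_distractor_positions,
    heart_geometry_at,
    load_scenario,
    render_frame,
    render_video,
    save_scenario,
    segment_area_fraction,
    simulate_cohort,
    well_name,
)
from conftest import small_scenario

NOISELESS = NoiseParams(background_level=0.0, gaussian_sd=0.0, n_distractors=0)


class TestGeometry:
    def test_zero_contraction_is_identity(self):
        m = HeartModel(contraction_fraction=0.0)
        for t in (0.0, 0.1, 1.37):
            a, b = heart_geometry_at(m, t)
            assert (a, b) == m.diastolic_semi_axes

    def test_peak_systole_scales_axes_by_one_minus_c(self):
        # sin term at its maximum: 2*pi*f*t + phi = pi/2
        m = HeartModel(contraction_fraction=0.2, phase=0.0)
        t = 0.25 / m.beat_frequency_hz
        a, b = heart_geometry_at(m, t)
        assert a == pytest.approx(0.8 * m.diastolic_semi_axes[0])
        assert b == pytest.approx(0.8 * m.diastolic_semi_axes[1])

    def test_default_rate_fits_ten_beats_in_acquisition(self):
        m = HeartModel()
        assert m.beat_frequency_hz * 2.8 == pytest.approx(10.0, abs=0.01)

    @given(
        c=st.floats(0.0, 0.95),
        bpm=st.floats(60.0, 400.0),
        phase=st.floats(0.0, 2 * math.pi),
    )
    @settings(max_examples=50, deadline=None)
    def test_minimum_over_period_and_periodicity(self, c, bpm, phase):
        m = HeartModel(contraction_fraction=c, heart_rate_bpm=bpm, phase=phase)
        period = 60.0 / bpm
        t = np.linspace(0, period, 2001)
        a, b = heart_geometry_at(m, t)
        assert np.all(a > 0) and np.all(b > 0)
        assert a.min() == pytest.approx(m.diastolic_semi_axes[0] * (1 - c), rel=1e-4)
        a2, _ = heart_geometry_at(m, t + period)
        np.testing.assert_allclose(a2, a, rtol=1e-9)

    @given(frac=st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_chord_offset_inverts_segment_area(self, frac):
        d = chord_offset_for_area_fraction(frac)
        assert segment_area_fraction(d) == pytest.approx(frac, abs=1e-9)

    def test_invalid_model_parameters_rejected(self):
        with pytest.raises(ValueError):
            HeartModel(diastolic_semi_axes=(0.0, 10.0))
        with pytest.raises(ValueError):
            HeartModel(contraction_fraction=1.0)
        with pytest.raises(ValueError):
            HeartModel(fhf_area_fraction=1.2)


class TestRenderFrame:
    def test_mcherry_with_empty_fhf_is_background_only(self):
        m = HeartModel(recombined=True, fhf_area_fraction=0.0)
        frame = render_frame(m, 0.0, "mCherry", (128, 128), NOISELESS)
        assert frame.max() == 0

    @pytest.mark.parametrize("t", [0.0, 0.07, 0.14])
    def test_bfp_crescent_matches_analytic_sector_area(self, t):
        m = HeartModel(recombined=True, bfp_area_fraction=0.45, bulbus_radius=0.0)
        a, b = heart_geometry_at(m, t)
        count = int((render_frame(m, t, "BFP", (128, 128), NOISELESS) > 0).sum())
        analytic = 0.45 * math.pi * a * b
        assert count == pytest.approx(analytic, rel=0.02)

    def test_full_ellipse_area_for_unrecombined_heart(self):
        m = HeartModel(bulbus_radius=0.0)
        a, b = heart_geometry_at(m, 0.0)
        count = int((render_frame(m, 0.0, "BFP", (128, 128), NOISELESS) > 0).sum())
        assert count == pytest.approx(math.pi * a * b, rel=0.02)

    def test_mcherry_survival_patch_area(self):
        m = HeartModel(recombined=True, mcherry_survival=0.1)
        a, b = heart_geometry_at(m, 0.0)
        count = int((render_frame(m, 0.0, "mCherry", (128, 128), NOISELESS) > 0).sum())
        assert count == pytest.approx(0.1 * 0.55 * math.pi * a * b, rel=0.15)

    def test_distractors_form_components_outside_ventricle(self, rng):
        m = HeartModel()
        noise = NoiseParams(background_level=100.0, gaussian_sd=0.0, n_distractors=6)
        positions = draw_distractor_positions(m, (128, 128), 6, rng)
        # render a channel with no compartment signal so only distractors remain
        blank = m.with_(recombined=True, fhf_area_fraction=0.0)
        frame = render_frame(blank, 0.0, "mCherry", (128, 128), noise, distractor_positions=positions)
        labels, n = ndimage.label(frame > 150)
        assert n >= 6
        cx, cy = m.center_xy
        a0, b0 = m.diastolic_semi_axes
        for y, x in np.argwhere(frame > 150):
            assert ((x - cx) / a0) ** 2 + ((y - cy) / b0) ** 2 > 1.0

    def test_rejects_nonpositive_frame_shape(self):
        with pytest.raises(ValueError):
            render_frame(HeartModel(), 0.0, "BFP", (0, 64), NOISELESS)

    def test_noise_requires_rng(self):
        with pytest.raises(ValueError):
            render_frame(HeartModel(), 0.0, "BFP", (128, 128), NoiseParams())


class TestCohort:
    def test_file_and_row_counts(self, tmp_path):
        sc = small_scenario(n_larvae=1, seed=5)
        res = simulate_cohort(sc, tmp_path / "c")
        assert len(list((tmp_path / "c").glob("*.tif"))) == 3 * 3 * 2
        assert len(res.metadata) == 18
        assert len(res.ground_truth) == 3 * 3  # one row per larva-timepoint

    def test_refuses_to_overwrite_without_force(self, tmp_path):
        sc = small_scenario(n_larvae=1)
        simulate_cohort(sc, tmp_path / "c")
        with pytest.raises(FileExistsError):
            simulate_cohort(sc, tmp_path / "c")
        simulate_cohort(sc, tmp_path / "c", force=True)  # ok

    def test_identical_seed_gives_byte_identical_outputs(self, tmp_path):
        sc = small_scenario(n_larvae=1, seed=9)
        r1 = simulate_cohort(sc, tmp_path / "a")
        r2 = simulate_cohort(sc, tmp_path / "b")
        files1 = sorted(p.name for p in (tmp_path / "a").glob("*.tif"))
        assert files1 == sorted(p.name for p in (tmp_path / "b").glob("*.tif"))
        for name in files1:
            h1 = hashlib.sha256((tmp_path / "a" / name).read_bytes()).hexdigest()
            h2 = hashlib.sha256((tmp_path / "b" / name).read_bytes()).hexdigest()
            assert h1 == h2, name
        assert r1.metadata.equals(r2.metadata)
        assert r1.ground_truth.equals(r2.ground_truth)

    def test_ground_truth_encodes_configured_trajectory(self, small_cohort):
        gt = small_cohort.ground_truth
        means = gt.groupby(["group", "timepoint"])["true_bfp_area_um2"].mean()
        configured = {"TP1": 0.45, "TP2": 0.65, "TP3": 0.85}
        for tp, want in configured.items():
            ratio = means["ablated", tp] / means["negative_control", tp]
            # n=3 per group at CV 10% -> Monte-Carlo SE of the ratio ~8%
            assert ratio == pytest.approx(want, rel=0.25)
        # ablated mCherry survives at ~3% of the not-ablated sector
        mch = gt.groupby("group")["true_mcherry_area_um2"].mean()
        assert mch["ablated"] / mch["not_ablated"] == pytest.approx(0.03, rel=0.2)
        assert mch["negative_control"] == 0.0

    def test_systolic_diameter_never_exceeds_diastolic(self, small_cohort):
        gt = small_cohort.ground_truth
        assert (gt["true_dmin_px"] <= gt["true_dmax_px"]).all()

    def test_wells_are_stable_across_timepoints(self, small_cohort):
        meta = small_cohort.metadata
        per_well = meta.groupby("well")[["group"]].nunique()
        assert (per_well["group"] == 1).all()
        assert meta.groupby("well")["timepoint"].nunique().eq(3).all()

    def test_well_naming(self):
        assert well_name(0) == "A1"
        assert well_name(13) == "B2"
        with pytest.raises(ValueError):
            well_name(96)


class TestScenario:
    def test_yaml_roundtrip(self, tmp_path):
        sc = small_scenario(n_larvae=2, seed=4)
        path = tmp_path / "scenario.yaml"
        save_scenario(sc, path)
        assert load_scenario(path) == sc

    def test_validation(self):
        with pytest.raises(ValueError):
            GroupSpec(name="g", n_larvae=0)
        with pytest.raises(ValueError):
            GroupSpec(name="g", bfp_ratio_by_timepoint={"TP1": 2.0})
        with pytest.raises(ValueError):
            default_scenario(n_larvae=2).__class__(groups=())

    def test_effect_multiplier_scales_increments(self):
        g = GroupSpec(name="g", bfp_ratio_by_timepoint={"TP1": 0.45, "TP2": 0.65, "TP3": 0.85}, effect_multiplier=0.5)
        traj = g.ratio_trajectory(("TP1", "TP2", "TP3"))
        assert traj["TP1"] == pytest.approx(0.45)
        assert traj["TP2"] == pytest.approx(0.55)
        assert traj["TP3"] == pytest.approx(0.65)
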