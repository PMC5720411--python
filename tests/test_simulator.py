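import numpy as np
import pytest

from transitdose import (
    analyze_session,
    apply_misalignment,
    breast_edge_position,
    forward_transit,
    make_breast_slice,
    make_cylinder_slice,
    profile_dose,
    radiological_path,
    session_report,
    simulate_cohort,
)
from transitdose.geometry import FanLine, chord_through


class TestMakeCylinderSlice:
    @pytest.mark.parametrize("r", [6.0, 8.25, 10.7, 14.5])
    def test_area_matches_circle(self, r):
        sl = make_cylinder_slice(r, spacing=0.25)
        area = sl.grid.sum() * sl.spacing**2
        assert area == pytest.approx(np.pi * r * r, rel=0.01)

    def test_diameter_radiological_path(self):
        sl = make_cylinder_slice(6.0, spacing=0.25)
        assert radiological_path(sl, (0, -8), (0, 8)) == pytest.approx(
            12.0, abs=0.125
        )

    def test_offset_translates_central_chord(self, beam):
        sl = make_cylinder_slice(8.25, spacing=0.25, offset_d=3.0)
        ch = chord_through(sl, FanLine.from_iso(0.0, beam), beam)
        assert ch.d1 == pytest.approx(3.0, abs=0.2)

    def test_too_small_radius_rejected(self):
        with pytest.raises(ValueError):
            make_cylinder_slice(0.3, spacing=0.25)


class TestMakeBreastSlice:
    def test_three_density_levels(self):
        sl = make_breast_slice(lung_density=0.3)
        assert set(np.unique(sl.grid)) == {0.0, 0.3, 1.0}

    def test_unit_lung_density_makes_w_equal_w_prime(self, beam):
        sl = make_breast_slice(lung_density=1.0)
        ch = chord_through(sl, FanLine.from_iso(6.0, beam), beam)
        assert ch.w_prime == pytest.approx(ch.w, abs=2 * sl.spacing)

    def test_lung_shortens_radiological_thickness(self, breast_slice, beam):
        ch = chord_through(breast_slice, FanLine.from_iso(6.0, beam), beam)
        # ~12 cm of lung at 0.3 inside a 14 cm chord
        assert ch.w - ch.w_prime == pytest.approx(12.0 * 0.7, abs=0.5)

    def test_fan_line_beyond_apex_is_outside(self, breast_slice, beam):
        ch = chord_through(breast_slice, FanLine.from_iso(-5.0, beam), beam)
        assert not ch.inside

    def test_inconsistent_geometry_rejected(self):
        with pytest.raises(ValueError):
            make_breast_slice(apex_radius=3.0, apex_offset=5.0)
        with pytest.raises(ValueError):
            make_breast_slice(chest_depth=0.5, lung_margin=1.0)


class TestForwardTransit:
    def test_zero_noise_round_trip(self, cylinder_825, beam, calib):
        prof = forward_transit(cylinder_825, beam, calib, noise_2sd=0.0)
        dp = profile_dose(prof, cylinder_825, beam, calib)
        ok = ~dp.excluded
        assert np.abs(dp.dose[ok] / 1.8 - 1.0).max() < 1e-3

    def test_central_sample_consistent_with_midpoint_inversion(
        self, cylinder_825, beam, calib
    ):
        from transitdose import correlation_eval, inverse_square, scatter_eval

        prof = forward_transit(cylinder_825, beam, calib, noise_2sd=0.0)
        st = float(np.interp(0.0, prof.positions, prof.signals))
        w, d, r = (prof.meta["axis_w_prime"], prof.meta["axis_d"],
                   prof.meta["axis_r"])
        expected = (
            1.8 * correlation_eval(calib[0], w)
            / scatter_eval(calib[1], d, r) / inverse_square(beam.sad, d)
        )
        assert st == pytest.approx(expected, rel=2e-3)

    def test_seeded_noise_is_reproducible(self, cylinder_825, beam, calib):
        a = forward_transit(cylinder_825, beam, calib, noise_2sd=0.5, seed=5)
        b = forward_transit(cylinder_825, beam, calib, noise_2sd=0.5, seed=5)
        c = forward_transit(cylinder_825, beam, calib, noise_2sd=0.5, seed=6)
        assert np.array_equal(a.signals, b.signals)
        assert not np.array_equal(a.signals, c.signals)

    def test_noise_level_matches_request(self, cylinder_825, beam, calib):
        clean = forward_transit(cylinder_825, beam, calib, noise_2sd=0.0)
        noisy = forward_transit(cylinder_825, beam, calib, noise_2sd=0.5,
                                seed=12)
        rel = noisy.signals / clean.signals - 1.0
        assert 2.0 * np.std(rel) * 100.0 == pytest.approx(0.5, abs=0.15)


class TestGenerateCalibrationSet:
    def test_deterministic_given_seed(self, calib):
        a = __import__("transitdose").generate_calibration_set(
            calib, noise_2sd=0.5, seed=3
        )
        b = __import__("transitdose").generate_calibration_set(
            calib, noise_2sd=0.5, seed=3
        )
        assert [(s.w, s.st) for s in a.correlation] == [
            (s.w, s.st) for s in b.correlation
        ]


class TestApplyMisalignment:
    def test_zero_shift_identity(self, breast_slice, beam, calib):
        p = forward_transit(breast_slice, beam, calib, noise_2sd=0.0)
        out = apply_misalignment(p, 0.0)
        assert np.allclose(out.signals, p.signals, equal_nan=True)

    def test_signal_mass_conserved_on_common_support(
        self, breast_slice, beam, calib
    ):
        p = forward_transit(breast_slice, beam, calib, noise_2sd=0.0)
        out = apply_misalignment(p, 1.0)
        # compare over the translated common support
        ok = np.isfinite(out.signals)
        orig = np.interp(p.positions[ok] - 1.0, p.positions, p.signals)
        assert np.sum(out.signals[ok]) == pytest.approx(np.sum(orig), rel=1e-6)

    def test_edge_moves_by_the_shift(self, breast_slice, beam, calib):
        p = forward_transit(breast_slice, beam, calib, noise_2sd=0.0)
        e0 = breast_edge_position(p)
        e2 = breast_edge_position(apply_misalignment(p, 2.0))
        assert e2 - e0 == pytest.approx(2.0, abs=0.1)


class TestSimulateCohort:
    def test_degenerate_cohort_has_no_shifts(self, breast_slice, beam, calib):
        sessions = simulate_cohort(
            breast_slice, beam, calib, n_sessions=3,
            setup_sd_mm=0.0, systematic_mm=0.0, noise_2sd=0.0, seed=1,
        )
        assert all(s.truth["shift_cm"] == 0.0 for s in sessions)

    def test_shift_distribution_recovers_parameters(
        self, breast_slice, beam, calib
    ):
        sessions = simulate_cohort(
            breast_slice, beam, calib, n_sessions=300,
            setup_sd_mm=3.3, systematic_mm=1.5, noise_2sd=0.0, seed=2,
        )
        shifts_mm = np.array([s.truth["shift_cm"] for s in sessions]) * 10.0
        assert shifts_mm.mean() == pytest.approx(1.5, abs=0.5)
        assert shifts_mm.std(ddof=1) == pytest.approx(3.3, abs=0.5)

    def test_alignment_shrinks_r_spread(self, breast_slice, beam, calib):
        """With setup errors present, correcting the misalignment must
        reduce the spread of the QA ratios (alignment-on vs -off)."""
        sessions = simulate_cohort(
            breast_slice, beam, calib, n_sessions=40,
            setup_sd_mm=5.0, systematic_mm=0.0, noise_2sd=0.5, seed=9,
        )
        ref = sessions[0].truth["reference_edge_cm"]
        aligned, unaligned = [], []
        for k, s in enumerate(sessions):
            aligned.append(analyze_session(
                s.profile, breast_slice, beam, calib, dm_tps=1.8,
                reference_edge=ref, session_id=f"s{k}"))
            unaligned.append(analyze_session(
                s.profile, breast_slice, beam, calib, dm_tps=1.8,
                align=False, session_id=f"s{k}"))
        rep_on = session_report(aligned, tolerance=5.0)
        rep_off = session_report(unaligned, tolerance=5.0)
        assert rep_on.sd_r_percent < rep_off.sd_r_percent
        assert rep_on.mean_r == pytest.approx(1.0, abs=0.02)
        assert rep_on.fraction_within_percent >= rep_off.fraction_within_percent
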