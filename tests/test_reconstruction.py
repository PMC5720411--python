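import math

import numpy as np
import pytest

from transitdose import (
    PhantomSlice,
    PhysicsConstants,
    attenuation_factor,
    correlation_eval,
    exclude_interfaces,
    fanline_c_factor,
    forward_transit,
    inverse_square,
    make_breast_slice,
    make_cylinder_slice,
    midpoint_dose,
    offaxis_dose,
    profile_dose,
    scatter_eval,
)
from transitdose.geometry import ChordGeometry


class TestMidpointDose:
    def test_inverts_correlation_at_isocenter(self, calib):
        # with d = 0 the formula reduces to st / F(w)
        st = correlation_eval(calib[0], 14.0) * 1.8
        assert midpoint_dose(st, 14.0, 0.0, 8.3, calib) == pytest.approx(1.8)

    def test_forward_inverse_round_trip_with_offset(self, calib):
        dm, w, d, r = 1.8, 16.5, 3.0, 8.3
        st = (
            dm
            * correlation_eval(calib[0], w)
            / scatter_eval(calib[1], d, r)
            / inverse_square(100.0, d)
        )
        assert midpoint_dose(st, w, d, r, calib) == pytest.approx(dm)

    def test_linearity_in_signal(self, calib):
        one = midpoint_dose(1.0, 16.5, 2.0, 8.3, calib)
        assert midpoint_dose(2.0, 16.5, 2.0, 8.3, calib) == pytest.approx(2 * one)


class TestOffaxisDose:
    def test_unit_dose_when_signal_equals_correlation(self, calib):
        wo = 12.0
        assert offaxis_dose(correlation_eval(calib[0], wo), wo, calib) == (
            pytest.approx(1.0)
        )

    def test_equals_midpoint_at_zero_offset(self, calib):
        for r in (6.0, 10.7):
            assert offaxis_dose(1.3, 18.0, calib) == pytest.approx(
                midpoint_dose(1.3, 18.0, 0.0, r, calib)
            )

    def test_zero_signal_is_zero_dose(self, calib):
        assert offaxis_dose(0.0, 12.0, calib) == 0.0


class TestAttenuationFactor:
    @pytest.mark.parametrize(
        "w2, expected",
        [(0.0, 1.0), (10.0, math.exp(-0.273)), (-10.0, math.exp(0.273))],
    )
    def test_signed_exponential(self, w2, expected):
        assert attenuation_factor(w2, PhysicsConstants()) == pytest.approx(expected)

    def test_constant_must_be_positive(self):
        with pytest.raises(ValueError):
            PhysicsConstants(mu_en_over_rho=0.0)


class TestFanlineCFactor:
    def test_reduces_to_offaxis_form_on_degenerate_geometry(self, calib, beam):
        chord = ChordGeometry(w=16.5, w_prime=16.5, d=0.0, d1=0.0, d2=0.0,
                              w2_prime=0.0, r=8.3)
        c = fanline_c_factor(chord, calib, PhysicsConstants(), beam)
        expected = scatter_eval(calib[1], 0.0, 8.3) / correlation_eval(
            calib[0], 16.5
        )
        assert c == pytest.approx(expected)

    def test_central_axis_degenerates_to_midpoint_equation(self, calib, beam):
        # on the axis d1 = d, d2 = 0: D = Sto * C must equal the midpoint formula
        w, d, r = 16.5, 2.0, 8.3
        chord = ChordGeometry(w=w, w_prime=w, d=d, d1=d, d2=0.0,
                              w2_prime=0.0, r=r)
        c = fanline_c_factor(chord, calib, PhysicsConstants(), beam)
        sto = 1.23
        assert sto * c == pytest.approx(midpoint_dose(sto, w, d, r, calib))

    def test_term_by_term_product(self, calib, beam):
        # independent brute-force evaluation of the four factors
        chord = ChordGeometry(w=16.5, w_prime=16.5, d=2.0, d1=2.0, d2=-3.0,
                              w2_prime=-3.0, r=8.3)
        const = PhysicsConstants()
        f = 1.0 + 1.487e-3 * 2.0
        f_w = 5.819e-4 * 16.5**2 + 2.880e-2 * 16.5 + 5.480e-1
        inv_sq = (102.0 / 100.0) ** 2
        fan_div = (102.0 / 99.0) ** 2
        expo = math.exp(-2.73e-2 * -3.0)
        expected = f / f_w * inv_sq * fan_div * expo
        assert fanline_c_factor(chord, calib, const, beam) == pytest.approx(expected)

    def test_degenerate_source_distance_rejected(self, calib, beam):
        chord = ChordGeometry(w=10, w_prime=10, d=0, d1=-60.0, d2=-50.0, r=8.3)
        with pytest.raises(ValueError, match="SAD"):
            fanline_c_factor(chord, calib, PhysicsConstants(), beam)


class TestExcludeInterfaces:
    def _uniform_line(self, n=101, x0=0.0, x1=10.0):
        x = np.linspace(x0, x1, n)
        return np.column_stack([x, np.zeros(n)])

    def test_uniform_slice_all_false(self):
        sl = PhantomSlice(np.ones((41, 81)), 0.25, origin=(-10.0, -5.0))
        mask = exclude_interfaces(sl, self._uniform_line())
        assert not mask.any()

    def test_single_interface_masks_margin_window(self):
        # density step at x = 5: margin 1 flags exactly (4, 6)
        grid = np.ones((41, 81))
        grid[:, 60:] = 0.3  # x >= 5 given origin -10, spacing 0.25
        sl = PhantomSlice(grid, 0.25, origin=(-10.0, -5.0))
        pts = self._uniform_line()
        mask = exclude_interfaces(sl, pts, margin=1.0)
        x = pts[:, 0]
        inside = (x > 4.2) & (x < 5.8)  # interface smeared over one cell
        outside = (x < 3.8) | (x > 6.2)
        assert mask[inside].all()
        assert not mask[outside].any()

    def test_zero_margin_flags_only_crossing(self):
        grid = np.ones((41, 81))
        grid[:, 60:] = 0.3
        sl = PhantomSlice(grid, 0.25, origin=(-10.0, -5.0))
        pts = self._uniform_line()
        mask = exclude_interfaces(sl, pts, margin=0.0)
        assert mask.sum() <= 3
        assert np.abs(pts[mask, 0] - 5.0).max() < 0.5


class TestProfileDose:
    def test_round_trip_constant_dose(self, cylinder_825, beam, calib):
        prof = forward_transit(cylinder_825, beam, calib, true_dose=1.8,
                               noise_2sd=0.0)
        dp = profile_dose(prof, cylinder_825, beam, calib)
        ok = ~dp.excluded
        assert ok.sum() > 100
        assert np.allclose(dp.dose[ok], 1.8, rtol=1e-3)

    def test_round_trip_shaped_dose(self, cylinder_825, beam, calib):
        # a wedge-like lateral dose gradient survives the round trip
        shape = lambda x: 1.8 * (1.0 + 0.02 * np.asarray(x))
        prof = forward_transit(cylinder_825, beam, calib, true_dose=shape,
                               noise_2sd=0.0)
        dp = profile_dose(prof, cylinder_825, beam, calib)
        ok = ~dp.excluded
        assert np.allclose(dp.dose[ok], shape(dp.positions[ok]), rtol=1e-3)

    def test_central_axis_agrees_with_midpoint_equation(
        self, cylinder_825, beam, calib
    ):
        prof = forward_transit(cylinder_825, beam, calib, true_dose=1.8,
                               noise_2sd=0.0)
        dp = profile_dose(prof, cylinder_825, beam, calib)
        i = int(np.argmin(np.abs(dp.positions)))
        st = float(np.interp(0.0, prof.positions, prof.signals))
        dm = midpoint_dose(st, dp.meta["axis_w_prime"], dp.meta["axis_d"],
                           dp.meta["axis_r"], calib)
        assert dp.dose[i] == pytest.approx(dm, rel=1e-3)

    def test_lung_interface_points_excluded(self, breast_slice, beam, calib):
        prof = forward_transit(breast_slice, beam, calib, true_dose=1.8,
                               noise_2sd=0.0)
        dp = profile_dose(prof, breast_slice, beam, calib)
        # tissue/lung boundary sits at the chest wall + 1 cm recess (x = 5)
        near = np.abs(dp.positions - 5.0) < 0.8
        assert dp.excluded[near].all()
        assert (dp.exclusion_reason[near & (dp.exclusion_reason == "interface")]
                .size > 0)

    def test_all_air_slice_yields_empty_profile(self, beam, calib):
        sl = PhantomSlice(np.zeros((60, 60)), 0.25, origin=(-7.5, -7.5))
        prof = forward_transit(
            make_cylinder_slice(6.0), beam, calib, noise_2sd=0.0
        )
        dp = profile_dose(prof, sl, beam, calib)
        assert dp.excluded.all()
        assert "diagnostic" in dp.meta

    def test_out_of_body_points_have_nan_dose(self, breast_slice, beam, calib):
        prof = forward_transit(breast_slice, beam, calib, true_dose=1.8,
                               noise_2sd=0.0)
        dp = profile_dose(prof, breast_slice, beam, calib)
        oob = dp.exclusion_reason == "out-of-body"
        assert oob.any()
        assert np.isnan(dp.dose[oob]).all()
        valid = ~dp.excluded
        assert np.isfinite(dp.dose[valid]).all()
        assert (dp.c_factor[valid] > 0).all()
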