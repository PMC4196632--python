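"""JND propagation into value error: oracles, dual routes, Weber decompositions."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from timerr import (
    RewardOffer,
    TimeNoiseParams,
    TimerrParams,
    jnd_subjective_time,
    subjective_value,
    sv_error_combined,
    sv_error_immediate,
    sv_error_time_only,
    weber_decomposition_fixed_r,
    weber_decomposition_fixed_t,
    weber_fraction_surface,
)
from timerr.noise import sv_error_combined_regrouped


def combined_error_oracle(r, t, T, a, k, c, l):
    """Exact-rational evaluation of the aligned-JND composition, term by term.

    Independent of the library code path: subjective time, the two JNDs and
    the three error terms are rebuilt here with Fraction arithmetic.
    """
    r, t, T, a, k, c, l = (Fraction(x) for x in (r, t, T, a, k, c, l))
    st_ = t / (1 + t / T)
    delta_r = l * r
    delta_st = k * st_ + c
    slope = r / T + a
    return delta_r * (1 - st_ / T) + slope * delta_st + delta_r * delta_st / T


class TestTimeJnd:
    @pytest.mark.parametrize(
        "st_, k, c, expected",
        [
            (0.0, 0.1, 0.05, 0.05),
            (10.0 / 6.0, 0.1, 0.05, 1.0 / 6.0 + 0.05),
            (3.7, 0.0, 0.0, 0.0),
        ],
    )
    def test_affine(self, st_, k, c, expected):
        noise = TimeNoiseParams(k=k, c=c)
        assert jnd_subjective_time(st_, noise) == pytest.approx(expected, rel=1e-12)

    def test_negative_subjective_time_rejected(self, noise):
        with pytest.raises(ValueError):
            jnd_subjective_time(-0.1, noise)


class TestTimeOnlyError:
    def test_immediate_reward(self, env):
        noise = TimeNoiseParams(k=0.1, c=0.1)
        err = sv_error_time_only(RewardOffer(r=5.0, t=0.0), env, noise)
        assert err.delta_sv == pytest.approx(0.1 * (0.5 + 0.5), rel=1e-12)

    def test_noiseless(self, env):
        err = sv_error_time_only(RewardOffer(r=5.0, t=3.0), env, TimeNoiseParams(k=0.0))
        assert err.delta_sv == 0.0

    def test_proportional_to_value_drop_when_no_readout_error(self, env):
        noise = TimeNoiseParams(k=0.1, c=0.0)
        offer = RewardOffer(r=5.0, t=2.0)
        drop = 5.0 - subjective_value(offer, env)
        err = sv_error_time_only(offer, env, noise)
        assert err.delta_sv == pytest.approx(0.1 * drop, rel=1e-12)
        assert err.delta_sv == pytest.approx(1.0 / 6.0, rel=1e-12)

    @given(
        r=st.floats(0.0, 100.0),
        t=st.floats(0.0, 1e3),
        T_ime=st.floats(0.1, 1e3),
        a_est=st.floats(0.0, 5.0),
        k=st.floats(0.0, 1.0),
        c=st.floats(0.0, 1.0),
    )
    @settings(derandomize=True, max_examples=200)
    def test_two_routes_agree(self, r, t, T_ime, a_est, k, c):
        """Slope×JND route equals the read-out + value-drop regrouping."""
        p = TimerrParams(T_ime=T_ime, a_est=a_est)
        offer = RewardOffer(r=r, t=t)
        direct = sv_error_time_only(offer, p, TimeNoiseParams(k=k, c=c)).delta_sv
        d = r / T_ime + a_est
        regrouped = c * d + k * (r - subjective_value(offer, p))
        assert abs(direct - regrouped) <= 1e-12 * max(1.0, abs(direct))


class TestImmediateError:
    def test_zero_magnitude_keeps_rate_term(self, env):
        noise = TimeNoiseParams(k=0.1, c=0.1)
        err = sv_error_immediate(0.0, env, noise)
        assert err.delta_sv == pytest.approx(0.1 * 0.5, rel=1e-12)

    def test_with_magnitude_noise(self, env):
        noise = TimeNoiseParams(k=0.1, c=0.1, l=0.05)
        err = sv_error_immediate(5.0, env, noise, include_magnitude_noise=True)
        # r·(l·(1 + c/T) + c/T) + c·a_est
        assert err.delta_sv == pytest.approx(5 * (0.05 * 1.01 + 0.01) + 0.05, rel=1e-12)

    @pytest.mark.parametrize("flag", [False, True])
    def test_affine_in_magnitude(self, env, noise, flag):
        d0 = sv_error_immediate(0.0, env, noise, include_magnitude_noise=flag).delta_sv
        d1 = sv_error_immediate(3.0, env, noise, include_magnitude_noise=flag).delta_sv
        d2 = sv_error_immediate(6.0, env, noise, include_magnitude_noise=flag).delta_sv
        assert d2 - d1 == pytest.approx(d1 - d0, rel=1e-12)


class TestCombinedError:
    def test_exact_rational_oracle(self, env):
        args = (5, 2, 10, Fraction(1, 2), Fraction(1, 10), Fraction(1, 20), Fraction(1, 20))
        expected = combined_error_oracle(*args)
        noise = TimeNoiseParams(k=0.1, c=0.05, l=0.05)
        got = sv_error_combined(RewardOffer(r=5.0, t=2.0), env, noise)
        assert got.delta_sv == pytest.approx(float(expected), rel=1e-12)
        assert float(expected) == pytest.approx(1033 / 2400, rel=1e-15)

    def test_components_sum(self, env, noise):
        err = sv_error_combined(RewardOffer(r=5.0, t=2.0), env, noise)
        total = sum(err.components.values())
        assert total == pytest.approx(err.delta_sv, rel=1e-12)
        assert set(err.components) == {"magnitude", "time", "cross"}

    def test_reduces_to_time_only_without_magnitude_noise(self, env):
        nz = TimeNoiseParams(k=0.1, c=0.05, l=0.0)
        for t in (0.0, 1.0, 7.0, 40.0):
            offer = RewardOffer(r=5.0, t=t)
            assert sv_error_combined(offer, env, nz).delta_sv == pytest.approx(
                sv_error_time_only(offer, env, nz).delta_sv, rel=1e-12
            )

    def test_reduces_to_immediate_at_zero_delay(self, env, noise):
        for r in (0.0, 1.0, 5.0, 20.0):
            assert sv_error_combined(RewardOffer(r=r, t=0.0), env, noise).delta_sv == (
                pytest.approx(
                    sv_error_immediate(r, env, noise, include_magnitude_noise=True).delta_sv,
                    rel=1e-12,
                )
            )

    def test_vanishes_without_noise(self, env):
        nz = TimeNoiseParams(k=0.0, c=0.0, l=0.0)
        assert sv_error_combined(RewardOffer(r=5.0, t=2.0), env, nz).delta_sv == 0.0

    @given(
        r=st.floats(0.0, 100.0),
        t=st.floats(0.0, 1e3),
        T_ime=st.floats(0.1, 1e3),
        a_est=st.floats(0.0, 5.0),
        k=st.floats(0.0, 1.0),
        c=st.floats(0.0, 1.0),
        l=st.floats(0.0, 1.0),
    )
    @settings(derandomize=True, max_examples=1000)
    def test_regrouped_route_agrees(self, r, t, T_ime, a_est, k, c, l):
        """Term-by-term expansion vs the SV-grouped form: the same polynomial."""
        p = TimerrParams(T_ime=T_ime, a_est=a_est)
        nz = TimeNoiseParams(k=k, c=c, l=l)
        offer = RewardOffer(r=r, t=t)
        direct = sv_error_combined(offer, p, nz).delta_sv
        regrouped = sv_error_combined_regrouped(offer, p, nz)
        assert abs(direct - regrouped) <= 1e-12 * max(1.0, abs(direct))


class TestWeberDecompositions:
    def test_fixed_r_reconstruction(self, env, noise):
        dec = weber_decomposition_fixed_r(5.0, env, noise)
        for t in (0.0, 1.0, 5.0, 50.0):
            offer = RewardOffer(r=5.0, t=t)
            sv = subjective_value(offer, env)
            direct = sv_error_combined(offer, env, noise).delta_sv
            assert dec.predict(sv) == pytest.approx(direct, rel=1e-10)

    def test_fixed_t_reconstruction(self, env, noise):
        dec = weber_decomposition_fixed_t(2.0, env, noise)
        for r in (0.5, 1.0, 5.0, 20.0):
            offer = RewardOffer(r=r, t=2.0)
            sv = subjective_value(offer, env)
            direct = sv_error_combined(offer, env, noise).delta_sv
            assert dec.predict(sv) == pytest.approx(direct, rel=1e-10)

    def test_fixed_t_zero_delay_matches_immediate(self, env, noise):
        dec = weber_decomposition_fixed_t(0.0, env, noise)
        for r in (0.5, 5.0, 20.0):
            expected = sv_error_immediate(r, env, noise, include_magnitude_noise=True).delta_sv
            assert dec.predict(r) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("axis", ["delay", "magnitude"])
    def test_collinearity_of_value_and_error(self, env, noise, axis):
        """(SV, δSV) pairs fall on one straight line along either axis."""
        if axis == "delay":
            offers = [RewardOffer(r=5.0, t=t) for t in (0.0, 0.5, 2.0, 9.0, 30.0)]
        else:
            offers = [RewardOffer(r=r, t=2.0) for r in (0.5, 1.0, 2.0, 5.0, 20.0)]
        sv = np.array([subjective_value(o, env) for o in offers])
        dsv = np.array([sv_error_combined(o, env, noise).delta_sv for o in offers])
        coeffs, residuals, *_ = np.polyfit(sv, dsv, 1, full=True)
        assert residuals[0] <= 1e-10

    def test_degenerate_discounting_rejected(self):
        p = TimerrParams(T_ime=10.0, a_est=0.0)
        with pytest.raises(ValueError):
            weber_decomposition_fixed_r(0.0, p, TimeNoiseParams(k=0.1))

    def test_matched_weber_fractions_collapse(self):
        """k = l, c = 0, a_est = 0: timing and magnitude noise cancel in the slope."""
        p = TimerrParams(T_ime=10.0, a_est=0.0)
        nz = TimeNoiseParams(k=0.05, c=0.0, l=0.05)
        dec = weber_decomposition_fixed_r(5.0, p, nz)
        for t in (0.0, 1.0, 5.0, 50.0):
            offer = RewardOffer(r=5.0, t=t)
            direct = sv_error_combined(offer, p, nz).delta_sv
            assert dec.predict(subjective_value(offer, p)) == pytest.approx(direct, rel=1e-10)

    def test_weber_fraction_at(self, env, noise):
        dec = weber_decomposition_fixed_r(5.0, env, noise)
        sv = subjective_value(RewardOffer(r=5.0, t=2.0), env)
        assert dec.weber_fraction_at(sv) == pytest.approx(dec.predict(sv) / sv, rel=1e-12)
        with pytest.raises(ValueError):
            dec.weber_fraction_at(0.0)


class TestWeberFractionSurface:
    def test_columns_and_shape(self, noise):
        params_grid = [TimerrParams(T_ime=10.0, a_est=0.5)]
        table = weber_fraction_surface([1.0, 5.0], [0.0, 2.0], params_grid, noise)
        assert len(table) == 4
        assert {
            "r", "t", "T_ime", "a_est", "k", "c", "l",
            "ST", "SV", "delta_sv", "weber_fraction_change", "weber_fraction_magnitude",
        } <= set(table.columns)
        # at t = 0 there is no value change to reference
        assert table.loc[table.t == 0.0, "weber_fraction_change"].isna().all()
        assert table.loc[table.t > 0.0, "weber_fraction_change"].notna().all()

    def test_change_fraction_is_slope_when_pure_scalar_timing(self, env):
        nz = TimeNoiseParams(k=0.1, c=0.0, l=0.0)
        table = weber_fraction_surface([5.0], [0.5, 2.0, 10.0, 100.0], [env], nz)
        np.testing.assert_allclose(table["weber_fraction_change"], 0.1, rtol=1e-12)

    def test_monotonic_in_environment(self, noise):
        t_grid = [TimerrParams(T_ime=T, a_est=0.5) for T in (1.0, 3.0, 10.0, 30.0, 100.0)]
        tab = weber_fraction_surface([5.0], [0.0], t_grid, noise)
        assert np.all(np.diff(tab["weber_fraction_magnitude"]) < 0), (
            "longer lookback must sharpen magnitude perception"
        )
        a_grid = [TimerrParams(T_ime=10.0, a_est=a) for a in (0.0, 0.5, 1.0, 2.0)]
        tab = weber_fraction_surface([5.0], [0.0], a_grid, noise)
        assert np.all(np.diff(tab["weber_fraction_magnitude"]) > 0), (
            "richer reward history must blur magnitude perception"
        )
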