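"""PMF handling, VACF attempt periods and TST rates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twistpore import synthetic as syn, tst_kinetics as tk
from twistpore.constants import KB_KCAL
from twistpore.errors import NoOscillationError, ProfileError


def _gaussian_well(depth=6.0, x0=0.0, width=1.0, span=8.0, step=0.05):
    x = np.arange(-span, span + step, step)
    return tk.PMFProfile(x, -depth * np.exp(-((x - x0) ** 2) / (2 * width**2)))


class TestNormalize:
    def test_constant_profile_becomes_zero(self):
        x = np.linspace(0, 10, 50)
        prof = tk.normalize_pmf(tk.PMFProfile(x, np.full(50, 4.2)), (0, 3))
        np.testing.assert_allclose(prof.free_energy, 0.0, atol=1e-12)

    def test_shift_invariance(self):
        prof = _gaussian_well()
        shifted = tk.PMFProfile(prof.coordinate, prof.free_energy + 5.0)
        a = tk.normalize_pmf(prof, (-8, -5))
        b = tk.normalize_pmf(shifted, (-8, -5))
        np.testing.assert_allclose(a.free_energy, b.free_energy, atol=1e-12)

    def test_well_depth_preserved(self):
        prof = tk.normalize_pmf(_gaussian_well(depth=6.0), (-8, -5))
        ext = tk.locate_extrema(prof)
        depths = [v for _, v, kind in ext if kind == "min"]
        assert min(depths) == pytest.approx(-6.0, abs=0.01)

    def test_empty_overlap_rejected(self):
        with pytest.raises(ProfileError):
            tk.normalize_pmf(_gaussian_well(), (100, 110))


class TestExtremaAndBarriers:
    def test_single_well(self):
        ext = tk.locate_extrema(_gaussian_well(depth=6.0))
        minima = [e for e in ext if e[2] == "min"]
        assert len(minima) == 1
        assert minima[0][1] == pytest.approx(-6.0, abs=0.01)
        assert minima[0][0] == pytest.approx(0.0, abs=0.1)

    def test_double_well_hop_barrier(self):
        """Wells at −6.0/−6.4 with a −2.5 saddle give the 3.5 kcal/mol hop."""
        prof = syn.potassium_pmf()
        assert tk.rate_determining_barrier(prof) == pytest.approx(3.5, abs=0.02)

    def test_sodium_like_barrier(self):
        prof = syn.sodium_pmf()
        assert tk.rate_determining_barrier(prof) == pytest.approx(8.9, abs=0.02)

    def test_smoothing_preserves_extremum_count_at_high_snr(self):
        prof = syn.potassium_pmf(noise_sd=0.05, seed=3)
        n_raw = len(tk.locate_extrema(prof, smoothing_window=5, min_prominence=0.5))
        n_clean = len(tk.locate_extrema(syn.potassium_pmf(), smoothing_window=1))
        assert n_raw == n_clean == 3

    def test_monotone_segment_barrier_is_endpoint_difference(self):
        x = np.linspace(-2, 6, 200)
        g = np.where(x < 0, -5.0 * np.exp(-(x**2)), -5.0 + 1.5 * x)
        prof = tk.PMFProfile(
            x, g, annotations={"L1": (-0.5, 0.5), "L2": (3.0, 4.0)}
        )
        # monotone rise between the layers: barrier = value at the L2
        # interval minimum (its left edge, x = 3) minus the L1 minimum
        barrier = tk.rate_determining_barrier(prof)
        assert barrier == pytest.approx((-5.0 + 1.5 * 3.0) - (-5.0), rel=0.05)

    def test_barrier_shift_invariant(self):
        prof = syn.potassium_pmf()
        shifted = tk.PMFProfile(
            prof.coordinate,
            prof.free_energy + 7.7,
            annotations=prof.annotations,
        )
        assert tk.rate_determining_barrier(shifted) == pytest.approx(
            tk.rate_determining_barrier(prof), abs=1e-9
        )

    def test_barrier_grid_refinement_stable(self):
        coarse = syn.potassium_pmf()
        fine = syn.gen_pmf(
            [10.0, 13.35], [-6.0, -6.4], [-2.5], grid_step=0.01,
            annotations=coarse.annotations,
        )
        assert tk.rate_determining_barrier(fine) == pytest.approx(
            tk.rate_determining_barrier(coarse), abs=0.02
        )

    def test_missing_annotation_rejected(self):
        with pytest.raises(ProfileError):
            tk.rate_determining_barrier(_gaussian_well())


class TestAttemptPeriod:
    def test_pure_cosine_second_zero_at_three_quarters_period(self):
        t0 = 0.4
        dt = 0.005
        series = syn.gen_oscillator_velocities(t0, damping_ratio=0.0, timestep=dt)
        tau = tk.attempt_period_from_vacf(series)
        assert tau == pytest.approx(0.75 * t0, abs=dt)

    def test_light_damping_within_5_percent(self):
        t0 = 0.4
        series = syn.gen_oscillator_velocities(
            t0, damping_ratio=0.05, noise_sd=0.01, seed=5
        )
        tau = tk.attempt_period_from_vacf(series)
        assert tau == pytest.approx(0.75 * t0, rel=0.05)

    def test_white_noise_rejected(self):
        rng = np.random.default_rng(0)
        series = tk.VelocitySeries(0.01, rng.normal(size=4000))
        with pytest.raises(NoOscillationError):
            tk.attempt_period_from_vacf(series)


class TestRates:
    def test_zero_barrier_rate(self):
        assert tk.permeation_rate(0.0, 1.0, 300.0) == pytest.approx(1e12)

    def test_unit_exponent(self):
        # barrier = k_B * 300 exactly -> rate = e^-1 * 1e12
        assert tk.permeation_rate(KB_KCAL * 300, 1.0, 300.0) == pytest.approx(
            np.exp(-1) * 1e12, rel=1e-12
        )

    def test_matches_arbitrary_precision_on_random_tuples(self):
        """12 significant digits against a sympy high-precision oracle."""
        import sympy

        rng = np.random.default_rng(1234)
        for _ in range(100):
            dg = rng.uniform(0.0, 15.0)
            tau = rng.uniform(0.05, 5.0)
            temp = rng.uniform(250.0, 400.0)
            ours = tk.permeation_rate(dg, tau, temp)
            exact = (
                sympy.exp(-sympy.Float(dg, 30) / (sympy.Float(KB_KCAL, 30) * temp))
                / (sympy.Float(tau, 30) * sympy.Float(1e-12, 30))
            )
            assert ours == pytest.approx(float(exact.evalf(30)), rel=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        dg1=st.floats(0.1, 10.0),
        delta=st.floats(0.1, 5.0),
        tau=st.floats(0.1, 2.0),
    )
    def test_rate_decreasing_in_barrier(self, dg1, delta, tau):
        assert tk.permeation_rate(dg1 + delta, tau) < tk.permeation_rate(dg1, tau)

    def test_selectivity_from_barrier_difference(self):
        """Equal attempt periods, 3.5 vs 8.9 kcal/mol at 300 K -> ~8.6e3."""
        k1 = tk.permeation_rate(3.5, 1.0, 300.0)
        k2 = tk.permeation_rate(8.9, 1.0, 300.0)
        sr = tk.selectivity_ratio(k1, k2)
        assert sr == pytest.approx(np.exp(5.4 / (KB_KCAL * 300.0)), rel=1e-9)
        assert sr == pytest.approx(8.6e3, rel=0.01)

    def test_selectivity_reciprocal(self):
        assert tk.selectivity_ratio(2.0, 5.0) * tk.selectivity_ratio(5.0, 2.0) == 1.0

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ProfileError):
            tk.selectivity_ratio(0.0, 1.0)


class TestVelocityIO:
    def test_roundtrip(self, tmp_path):
        series = syn.gen_oscillator_velocities(0.4, noise_sd=0.1, seed=2)
        path = tk.write_velocity(series, tmp_path / "v.dat")
        back = tk.read_velocity(path)
        assert back.timestep == series.timestep
        np.testing.assert_allclose(back.values, series.values, rtol=1e-6)
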