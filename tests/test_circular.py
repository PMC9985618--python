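"""Unit and property tests for the circular-statistics primitives."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from magtaxis.circular import (
    AngleSample,
    BootstrapCI,
    bootstrap_r_ci,
    ci_contains,
    mean_vector,
    rayleigh_p,
    rayleigh_test,
    rayleigh_z,
    vonmises_kde,
)


def circ_diff(a: float, b: float) -> float:
    """Smallest absolute angular difference in degrees."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


class TestAngleSample:
    def test_normalizes_into_circle(self):
        s = AngleSample([370.0, -10.0, 720.5])
        assert np.allclose(s.angles, [10.0, 350.0, 0.5])

    def test_rejects_bad_weights(self):
        with pytest.raises(ValueError):
            AngleSample([0.0, 90.0], weights=[1.0])
        with pytest.raises(ValueError):
            AngleSample([0.0, 90.0], weights=[-1.0, 2.0])
        with pytest.raises(ValueError):
            AngleSample([0.0, 90.0], weights=[0.0, 0.0])


class TestMeanVector:
    @pytest.mark.parametrize(
        "angles, mu, r",
        [
            ([0.0, 90.0], 45.0, math.sqrt(0.5)),
            ([30.0, 30.0, 30.0], 30.0, 1.0),
            ([10.0], 10.0, 1.0),
        ],
    )
    def test_known_samples(self, angles, mu, r):
        s = mean_vector(AngleSample(angles))
        assert s.n == len(angles)
        assert s.mu_deg == pytest.approx(mu, abs=1e-9)
        assert s.r == pytest.approx(r, abs=1e-12)

    def test_perfect_cancellation_leaves_mu_undefined(self):
        s = mean_vector(AngleSample([0.0, 90.0, 180.0, 270.0]))
        assert s.r == 0.0
        assert s.mu_deg is None
        assert not s.mu_defined

    def test_weights_select_direction(self):
        s = mean_vector(AngleSample([0.0, 90.0], weights=[2.0, 0.0]))
        assert s.mu_deg == pytest.approx(0.0, abs=1e-9)
        assert s.r == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mean_vector(AngleSample([]))

    @settings(derandomize=True, max_examples=50)
    @given(
        angles=st.lists(st.floats(0, 360, exclude_max=True), min_size=1, max_size=30),
        delta=st.floats(-720, 720, allow_nan=False),
    )
    def test_rotation_equivariance(self, angles, delta):
        base = mean_vector(AngleSample(angles))
        rotated = mean_vector(AngleSample(np.asarray(angles) + delta))
        assert rotated.r == pytest.approx(base.r, abs=1e-9)
        if base.r > 1e-6:
            assert circ_diff(rotated.mu_deg, base.mu_deg + delta) < 1e-6


class TestRayleigh:
    @pytest.mark.parametrize(
        "n, r, z_2dp",
        [(26, 0.301, 2.36), (24, 0.304, 2.22), (28, 0.228, 1.46)],
    )
    def test_statistic_from_plate_summaries(self, n, r, z_2dp):
        assert round(rayleigh_z(n, r), 2) == z_2dp

    def test_statistic_validation(self):
        assert rayleigh_z(17, 0.0) == 0.0
        with pytest.raises(ValueError):
            rayleigh_z(0, 0.5)
        with pytest.raises(ValueError):
            rayleigh_z(10, 1.5)

    def test_p_uniform_limit(self):
        assert rayleigh_p(0.0, 12) == 1.0

    def test_p_monotone_decreasing_in_z(self):
        for n in (5, 26, 100):
            zs = np.linspace(0.0, 0.9 * n, 200)
            ps = [rayleigh_p(z, n) for z in zs]
            assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_p_calibrated_against_uniform_monte_carlo(self):
        """Analytic p at n=8 matches the rejection rate of uniform simulations."""
        rng = np.random.default_rng(1234)
        angles = rng.uniform(0, 2 * np.pi, size=(20_000, 8))
        r = np.abs(np.exp(1j * angles).mean(axis=1))
        z = 8 * r**2
        rejected = np.mean([rayleigh_p(zi, 8) < 0.05 for zi in z])
        assert rejected == pytest.approx(0.05, abs=0.01)

    def test_composed_test_on_degenerate_samples(self):
        res = rayleigh_test(AngleSample([77.0] * 10))
        assert res.r == pytest.approx(1.0)
        assert res.z == pytest.approx(10.0)
        assert res.p == pytest.approx(rayleigh_p(10.0, 10))
        res = rayleigh_test(AngleSample([0.0, 120.0, 240.0]))
        assert res.r < 1e-12
        assert res.p == pytest.approx(1.0)

    def test_constructed_sample_reproduces_plate_level_statistics(self):
        """A 26-angle sample tuned to r = 0.301 gives Z ~ 2.36, p ~ 0.094.

        The sample is 26 equally spaced offsets around 305 deg shrunk by a
        scale factor; the scale is solved by bisection against mean_vector,
        which acts as the independent oracle for the construction.
        """
        offsets = np.linspace(-180.0, 180.0, 26, endpoint=False)

        def r_of(scale: float) -> float:
            return mean_vector(AngleSample(305.0 + scale * offsets)).r

        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if r_of(mid) > 0.301:
                lo = mid
            else:
                hi = mid
        sample = AngleSample(305.0 + lo * offsets)
        res = rayleigh_test(sample)
        assert res.r == pytest.approx(0.301, abs=1e-9)
        assert round(res.z, 2) == 2.36
        assert round(res.p, 3) == 0.094

    def test_rejects_under_uniform_at_nominal_rate(self):
        """Type-I error of the full test is 5% +- 1% for several n."""
        rng = np.random.default_rng(77)
        for n in (10, 26, 100):
            angles = rng.uniform(0, 2 * np.pi, size=(20_000, n))
            r = np.abs(np.exp(1j * angles).mean(axis=1))
            rate = np.mean([rayleigh_p(n * ri**2, n) < 0.05 for ri in r])
            assert rate == pytest.approx(0.05, abs=0.01)


class TestVonMisesKDE:
    def test_single_point_matches_closed_form(self):
        for bw in (0.5, 5.0, 40.0):
            d = vonmises_kde(AngleSample([90.0]), bandwidth=bw)
            expected = stats.vonmises.pdf(np.deg2rad(d.grid_deg - 90.0), bw)
            assert np.allclose(d.density, expected, atol=1e-12)

    def test_peak_at_data_angle(self):
        d = vonmises_kde(AngleSample([90.0]), bandwidth=40.0)
        peak = d.grid_deg[np.argmax(d.density)]
        assert circ_diff(peak, 90.0) <= 360.0 / len(d.grid_deg)

    def test_flat_limit_for_vanishing_bandwidth(self):
        d = vonmises_kde(AngleSample([13.0, 222.0]), bandwidth=1e-8)
        assert np.allclose(d.density, 1.0 / (2 * np.pi), atol=1e-6)

    @pytest.mark.parametrize("bw", [0.1, 1.0, 40.0, 200.0])
    @pytest.mark.parametrize("n", [1, 5, 100])
    def test_integrates_to_one(self, bw, n):
        rng = np.random.default_rng(n)
        d = vonmises_kde(AngleSample(rng.uniform(0, 360, n)), bandwidth=bw)
        integral = d.density.mean() * 2 * np.pi  # periodic trapezoid
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_validation(self):
        with pytest.raises(ValueError):
            vonmises_kde(AngleSample([1.0]), bandwidth=0.0)
        with pytest.raises(ValueError):
            vonmises_kde(AngleSample([1.0]), grid_size=8)


def enumerate_bootstrap_quantiles(angles, conf=0.95):
    """Exact CI endpoints from the full n^n resample distribution."""
    rad = np.deg2rad(np.asarray(angles, dtype=float))
    n = len(rad)
    rs = sorted(
        abs(np.exp(1j * np.array(combo)).sum()) / n
        for combo in itertools.product(rad, repeat=n)
    )
    total = n**n
    lo = rs[math.ceil(total * (1 - conf) / 2) - 1]
    hi = rs[math.floor(total * (1 + conf) / 2) - 1]
    return lo, hi


class TestBootstrap:
    def test_degenerate_sample_gives_unit_interval(self):
        ci = bootstrap_r_ci(AngleSample([42.0] * 5), n_reps=1_000, seed=0)
        assert ci.lower == pytest.approx(1.0)
        assert ci.upper == pytest.approx(1.0)

    def test_two_angle_support(self):
        # resamples of {0, 90} have r in {1, sqrt(1/2)} only
        ci = bootstrap_r_ci(AngleSample([0.0, 90.0]), n_reps=5_000, seed=1)
        assert math.sqrt(0.5) - 1e-12 <= ci.lower <= ci.upper <= 1.0

    @pytest.mark.parametrize(
        "angles", [[0.0, 90.0, 180.0], [10.0, 100.0, 190.0, 280.0], [5.0, 20.0, 300.0]]
    )
    def test_matches_exhaustive_enumeration(self, angles):
        lo, hi = enumerate_bootstrap_quantiles(angles)
        ci = bootstrap_r_ci(AngleSample(angles), n_reps=100_000, seed=7)
        assert ci.lower == pytest.approx(lo, abs=0.02)
        assert ci.upper == pytest.approx(hi, abs=0.02)

    def test_seed_reproducibility(self):
        s = AngleSample([0.0, 45.0, 200.0, 310.0, 100.0])
        a = bootstrap_r_ci(s, n_reps=2_000, seed=99)
        b = bootstrap_r_ci(s, n_reps=2_000, seed=99)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_r_ci(AngleSample([5.0]), n_reps=1_000)
        with pytest.raises(ValueError):
            bootstrap_r_ci(AngleSample([0.0, 1.0]), n_reps=10)


class TestCIContains:
    @pytest.mark.parametrize(
        "lower, upper, contained",
        [(0.128, 0.547, True), (0.086, 0.467, True), (0.40, 0.60, False)],
    )
    def test_zero_field_directedness_verdicts(self, lower, upper, contained):
        ci = BootstrapCI(lower=lower, upper=upper, n_reps=100_000)
        got, verdict = ci_contains(ci, 0.301)
        assert got is contained
        if contained:
            assert verdict == "not significantly more directed"
        else:
            assert verdict == "significantly more directed (p < 0.05)"
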