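import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memperm import (
    DiffusivityProfile,
    EstimationError,
    FreeEnergyProfile,
    ThermoState,
    UmbrellaWindow,
    compute_permeability,
    compute_resistivity,
    detect_water_edge,
    estimate_window_diffusivity,
    interpolate_profiles,
    propagate_uncertainty,
    symmetrize_diffusivity,
)
from memperm.transport import (
    PS_PER_A_TO_S_PER_CM,
    autocorrelation,
    integrate_acf_to_zero_crossing,
)


def _profile(z, W):
    return FreeEnergyProfile(np.asarray(z, float), np.asarray(W, float),
                             reference_convention="water_zero")


def _diff(z, D):
    return DiffusivityProfile(np.asarray(z, float), np.asarray(D, float))


class TestDiffusivityEstimator:
    def test_exponential_acf_closed_form(self):
        """Injecting C(t) = σ²·e^(−t/τ) into the integration step must give
        D = var²/∫C = σ²/τ.  A pure exponential never crosses zero, so the
        estimator truncates at the 1%-of-variance floor, losing exactly that
        fraction of the integral."""
        sigma2, tau, dt = 0.24, 24.0, 0.01
        t = dt * np.arange(int(50 * tau / dt))
        acf = sigma2 * np.exp(-t / tau)
        integral = integrate_acf_to_zero_crossing(acf, dt)
        D = sigma2**2 / integral
        assert D == pytest.approx(sigma2 / tau, rel=0.015)

    def test_ou_window_recovery(self, ou_window):
        """OU window with D = 0.01 Å²/ps: the positional-autocorrelation
        estimator recovers D within 10%."""
        z_mean, D = estimate_window_diffusivity(ou_window)
        assert abs(z_mean) < 0.05
        assert D == pytest.approx(0.01, rel=0.10)

    def test_time_rescaling_halves_D(self, rng):
        x = np.cumsum(rng.normal(size=5000)) * 0.01 + rng.normal(size=5000)
        t1 = 0.05 * np.arange(1, 5001)
        w1 = UmbrellaWindow(0.0, 2.5, t1, x, discard_fraction=0.0)
        w2 = UmbrellaWindow(0.0, 2.5, 2 * t1, x, discard_fraction=0.0)
        _, D1 = estimate_window_diffusivity(w1)
        _, D2 = estimate_window_diffusivity(w2)
        assert D2 == pytest.approx(D1 / 2, rel=1e-12)

    def test_zero_variance_rejected(self):
        w = UmbrellaWindow(0.0, 2.5, 0.05 * np.arange(1, 101),
                           np.full(100, 1.0), discard_fraction=0.0)
        with pytest.raises(EstimationError):
            estimate_window_diffusivity(w)

    def test_acf_lag0_is_variance(self, rng):
        x = rng.normal(size=10_000)
        acf = autocorrelation(x)
        assert acf[0] == pytest.approx(np.var(x), rel=1e-10)


class TestInterpolation:
    def test_default_spacing_is_one_angstrom(self):
        p = _profile(np.linspace(0, 10, 201), np.zeros(201))
        d = _diff([0.0, 10.0], [0.01, 0.01])
        z, _, _ = interpolate_profiles(p, d)
        assert np.diff(z) == pytest.approx(1.0)

    def test_identity_on_target_grid(self):
        z = np.arange(0.0, 11.0)
        W = np.sin(z)
        p = _profile(z, W)
        d = _diff(z, np.full_like(z, 0.02))
        zi, Wi, Di = interpolate_profiles(p, d, spacing=1.0)
        np.testing.assert_allclose(Wi, W, atol=1e-12)
        np.testing.assert_allclose(Di, 0.02)

    def test_linear_ramp_midpoints(self):
        z = np.arange(0.0, 11.0, 2.0)
        p = _profile(z, 3.0 * z)
        d = _diff(z, 0.01 + 0.001 * z)
        zi, Wi, Di = interpolate_profiles(p, d, spacing=1.0)
        np.testing.assert_allclose(Wi, 3.0 * zi, atol=1e-12)
        np.testing.assert_allclose(Di, 0.01 + 0.001 * zi, atol=1e-15)

    def test_extrapolation_refused(self):
        p = _profile(np.linspace(0, 10, 11), np.zeros(11))
        d = _diff([0.0, 10.0], [0.01, 0.01])
        with pytest.raises(ValueError, match="exceeds"):
            interpolate_profiles(p, d, bounds=(0.0, 20.0))


class TestResistivity:
    def test_flat_profile(self, thermo):
        z = np.arange(0.0, 36.0)
        res = compute_resistivity(_profile(z, np.zeros_like(z)),
                                  _diff([0.0, 35.0], [0.01, 0.01]), thermo)
        np.testing.assert_allclose(res.integrand, 100.0)
        np.testing.assert_allclose(res.cumulative_R, 100.0 * res.z_grid)

    def test_gaussian_barrier_matches_dense_quadrature(self, thermo):
        """Headgroup-barrier-sized Gaussian on constant D: fine-grid
        trapezoid in the implementation vs a 10⁴-point analytic oracle."""
        amp, width = 1.94, 3.0
        W = lambda z: amp * np.exp(-z**2 / (2 * width**2))
        z = np.linspace(-15, 15, 3001)
        res = compute_resistivity(_profile(z, W(z)), _diff([-15, 15], [0.02, 0.02]),
                                  thermo, spacing=0.01)
        zq = np.linspace(-15, 15, 10_001)
        oracle = np.trapezoid(np.exp(thermo.beta * W(zq)) / 0.02, zq)
        assert res.total_R == pytest.approx(oracle, rel=1e-3)

    def test_constant_shift_multiplies_R(self, thermo, rng):
        z = np.arange(0.0, 21.0)
        W = rng.normal(scale=0.5, size=len(z))
        d = _diff(z, np.full_like(z, 0.05))
        c = 1.3
        r0 = compute_resistivity(_profile(z, W), d, thermo).total_R
        r1 = compute_resistivity(_profile(z, W + c), d, thermo).total_R
        assert r1 / r0 == pytest.approx(np.exp(thermo.beta * c), rel=1e-12)

    def test_integrand_peak_tracks_W_peak(self, thermo, rng):
        """With constant D the permeation resistance is dominated by the
        free-energy component: argmax integrand == argmax W."""
        z = np.arange(0.0, 31.0)
        W = np.sin(z / 5.0) + rng.normal(scale=0.1, size=len(z))
        res = compute_resistivity(_profile(z, W), _diff(z, np.full_like(z, 0.01)),
                                  thermo)
        assert np.argmax(res.integrand) == np.argmax(np.interp(res.z_grid, z, W))

    def test_cumulative_R_nondecreasing(self, thermo, rng):
        z = np.arange(0.0, 31.0)
        W = rng.normal(scale=2.0, size=len(z))
        res = compute_resistivity(_profile(z, W), _diff(z, np.full_like(z, 0.01)),
                                  thermo)
        assert np.all(np.diff(res.cumulative_R) > 0)


class TestPermeability:
    def test_flat_closed_form(self, thermo):
        """W ≡ 0, constant D, half-width L: P = D/L = 2.857 cm/s."""
        z = np.arange(0.0, 36.0)
        res = compute_resistivity(_profile(z, np.zeros_like(z)),
                                  _diff([0.0, 35.0], [0.01, 0.01]), thermo)
        perm = compute_permeability(res, mode="half")
        expected = (0.01 * 1e-4) / (35.0 * 1e-8)
        assert perm.P == pytest.approx(expected, rel=1e-9)
        assert perm.log10_P == pytest.approx(np.log10(expected), abs=1e-9)

    def test_full_mode_doubles_symmetric_half(self, thermo):
        z_half = np.arange(0.0, 21.0)
        W = -3.0 * np.exp(-z_half**2 / 18.0)
        z_full = np.arange(-20.0, 21.0)
        W_full = -3.0 * np.exp(-z_full**2 / 18.0)
        d_half = _diff([0.0, 20.0], [0.02, 0.02])
        d_full = _diff([-20.0, 20.0], [0.02, 0.02])
        R_half = compute_resistivity(_profile(z_half, W), d_half, thermo).total_R
        R_full = compute_resistivity(_profile(z_full, W_full), d_full, thermo).total_R
        assert R_full == pytest.approx(2 * R_half, rel=1e-12)

    def test_scaling_D_scales_P(self, thermo, rng):
        z = np.arange(0.0, 26.0)
        W = rng.normal(scale=1.0, size=len(z))
        P = []
        for c in (1.0, 3.5):
            d = _diff(z, np.full_like(z, 0.01 * c))
            res = compute_resistivity(_profile(z, W), d, thermo)
            P.append(compute_permeability(res).P)
        assert P[1] / P[0] == pytest.approx(3.5, rel=1e-12)

    @given(bump=st.floats(0.1, 3.0), loc=st.integers(2, 18))
    @settings(deadline=None, max_examples=25)
    def test_monotonicity_under_W_increase(self, bump, loc):
        """Raising W anywhere inside the bounds never increases P."""
        thermo = ThermoState(303.0)
        z = np.arange(0.0, 21.0)
        W = np.zeros_like(z)
        d = _diff(z, np.full_like(z, 0.05))
        P0 = compute_permeability(compute_resistivity(_profile(z, W), d, thermo)).P
        W2 = W.copy()
        W2[loc] += bump
        P1 = compute_permeability(compute_resistivity(_profile(z, W2), d, thermo)).P
        assert P1 <= P0

    def test_invalid_mode(self, thermo):
        z = np.arange(0.0, 11.0)
        res = compute_resistivity(_profile(z, np.zeros_like(z)),
                                  _diff(z, np.full_like(z, 0.01)), thermo)
        with pytest.raises(ValueError):
            compute_permeability(res, mode="both")


class TestWaterEdgeDetection:
    def test_flat_tail_detected(self):
        z = np.arange(0.0, 31.0)
        W = np.where(z < 20, -5.0 + 0.25 * z, 0.0)
        edge = detect_water_edge(_profile(z, W))
        assert 19.0 <= edge <= 22.0

    def test_no_plateau_falls_back_to_grid_end(self):
        z = np.arange(0.0, 21.0)
        edge = detect_water_edge(_profile(z, 5.0 - 0.25 * z + 1.0))
        assert edge == pytest.approx(20.0)


class TestUncertaintyPropagation:
    def test_identical_replicas_zero_stderr(self, thermo):
        z = np.arange(0.0, 16.0)
        reps = np.tile(np.sin(z / 3.0), (5, 1))
        s = propagate_uncertainty(reps, z, _diff(z, np.full_like(z, 0.02)), thermo)
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_replicas(self, thermo):
        """Replicas W ± δ: by the exponential-shift identity,
        std(log10 P) = (βδ/ln 10)·std(±1)."""
        z = np.arange(0.0, 16.0)
        W = np.zeros_like(z)
        delta = 0.3
        reps = np.vstack([W + delta, W - delta, W + delta, W - delta])
        s = propagate_uncertainty(reps, z, _diff(z, np.full_like(z, 0.02)), thermo)
        spread = np.std([1.0, -1.0, 1.0, -1.0], ddof=1)
        assert s == pytest.approx(thermo.beta * delta / np.log(10) * spread, rel=1e-9)

    def test_single_replica_rejected(self, thermo):
        z = np.arange(0.0, 6.0)
        with pytest.raises(ValueError):
            propagate_uncertainty(np.zeros((1, 6)), z,
                                  _diff(z, np.full_like(z, 0.02)), thermo)


class TestSymmetrizeDiffusivity:
    def test_mirror_and_average(self):
        d = _diff([0.0, 5.0, 10.0], [0.01, 0.02, 0.05])
        s = symmetrize_diffusivity(d)
        np.testing.assert_allclose(s.points_z, [-10, -5, 0, 5, 10])
        np.testing.assert_allclose(s.points_D, [0.05, 0.02, 0.01, 0.02, 0.05])
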