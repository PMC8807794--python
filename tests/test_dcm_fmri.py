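"""DCM forward model: integration, noise scaling, likelihood, fixtures."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from powerpost.dcm_fmri import (
    DCMModel,
    DCMSpec,
    add_noise_at_snr,
    block_inputs,
    dcm_log_likelihood,
    integrate_dcm,
)
from powerpost.exceptions import DegenerateSignalError, DivergenceError, ShapeError


def _one_region_spec(a=-0.4, c=0.3, n_scans=60):
    inputs = block_inputs(n_scans * 2.0, u1_period=40.0, u2_period=120.0)[:, :1]
    return DCMSpec(
        name="one",
        A=np.array([[a]]),
        B=np.zeros((1, 1, 1)),
        C=np.array([[c]]),
        D=np.zeros((1, 1, 1)),
        inputs=inputs,
        TR=2.0,
        n_scans=n_scans,
        input_dt=0.5,
    )


class TestIntegration:
    def test_no_drive_stays_at_baseline(self):
        """Zero inputs coupling and zero initial state: BOLD is exactly 0%."""
        spec = _one_region_spec(c=0.0)
        sig = integrate_dcm(spec)
        np.testing.assert_array_equal(sig, np.zeros_like(sig))

    def test_zero_c_b_d_is_baseline_even_with_inputs(self, short_specs):
        spec = short_specs[4]
        sig = integrate_dcm(spec, B=np.zeros_like(spec.B), C=np.zeros_like(spec.C),
                            D=np.zeros_like(spec.D))
        np.testing.assert_array_equal(sig, 0.0)

    def test_modulatory_term_deletion_matches_linear_model(self, short_specs):
        """Zeroing B and D of the bilinear/nonlinear specs reproduces the
        linear model m1 exactly (same A, C backbone)."""
        m1 = integrate_dcm(short_specs[0])
        for spec in short_specs[1:]:
            stripped = integrate_dcm(
                spec, B=np.zeros_like(spec.B), D=np.zeros_like(spec.D)
            )
            np.testing.assert_array_equal(stripped, m1)

    def test_matches_scipy_reference_integration(self):
        """Full pipeline oracle: one-region linear DCM integrated by
        scipy's adaptive RK45 on the identical state equations."""
        spec = _one_region_spec()
        k = spec.hemo.resolved()
        kappa, gamma, tau, alpha, rho, V0, k1, k2, k3 = k

        def u_of(t):
            idx = min(int(t / spec.input_dt), spec.inputs.shape[0] - 1)
            return spec.inputs[idx, 0]

        def rhs(t, yv):
            x, s, f, v, q = yv
            du = u_of(t)
            return [
                spec.A[0, 0] * x + spec.C[0, 0] * du,
                x - kappa * s - gamma * (f - 1.0),
                s,
                (f - v ** (1.0 / alpha)) / tau,
                (f * (1.0 - (1.0 - rho) ** (1.0 / f)) / rho - v ** (1.0 / alpha) * q / v) / tau,
            ]

        t_scan = np.arange(spec.n_scans) * spec.TR
        sol = solve_ivp(
            rhs, (0.0, t_scan[-1]), [0, 0, 1, 1, 1], t_eval=t_scan,
            rtol=1e-9, atol=1e-11, max_step=0.5,
        )
        v, q = sol.y[3], sol.y[4]
        ref = 100.0 * V0 * (k1 * (1 - q) + k2 * (1 - q / v) + k3 * (1 - v))
        ours = integrate_dcm(spec, method="rk4")[:, 0]
        assert np.sqrt(np.mean((ours - ref) ** 2)) < 1e-3

    def test_rk4_converges_under_step_halving(self, fixture_specs):
        for spec in fixture_specs:
            a = integrate_dcm(spec, method="rk4")
            b = integrate_dcm(spec, method="rk4", dt=0.25)
            assert np.sqrt(np.mean((a - b) ** 2)) < 1e-3, spec.name

    def test_euler_step_halving_regression_bound(self, short_specs):
        # first-order default integrator: coarse bound documenting its error
        for spec in short_specs:
            a = integrate_dcm(spec)
            b = integrate_dcm(spec, dt=0.25)
            assert np.sqrt(np.mean((a - b) ** 2)) < 0.5, spec.name

    def test_deterministic_bitwise(self, short_specs):
        a = integrate_dcm(short_specs[2])
        b = integrate_dcm(short_specs[2])
        np.testing.assert_array_equal(a, b)

    def test_unstable_connectivity_raises(self):
        spec = _one_region_spec(a=+5.0, c=1.0)
        with pytest.raises(DivergenceError):
            integrate_dcm(spec)


class TestNoise:
    def test_snr_one_noise_sd_matches_signal_sd(self, m1_dataset):
        sig_sd = m1_dataset.signal.std(axis=0)
        noise = m1_dataset.observed - m1_dataset.signal
        ratio = noise.std(axis=0) / sig_sd
        assert np.all((ratio > 0.93) & (ratio < 1.07))

    def test_infinite_snr_limit(self, short_specs):
        sig = integrate_dcm(short_specs[0])
        ds = add_noise_at_snr(sig, snr=1e9, seed=0)
        assert np.max(np.abs(ds.observed - ds.signal)) < 1e-6 * np.max(np.abs(sig))

    def test_zero_variance_signal_rejected(self):
        with pytest.raises(DegenerateSignalError):
            add_noise_at_snr(np.zeros((10, 2)), snr=1.0)

    def test_deterministic_given_seed(self, short_specs):
        sig = integrate_dcm(short_specs[0])
        a = add_noise_at_snr(sig, 1.0, seed=5)
        b = add_noise_at_snr(sig, 1.0, seed=5)
        np.testing.assert_array_equal(a.observed, b.observed)


class TestLikelihood:
    def test_zero_residual_unit_variance(self, short_specs):
        spec = short_specs[0]
        model = DCMModel(spec, np.zeros((spec.n_scans, spec.n_regions)))
        theta = model.true_params(noise_sd=np.ones(spec.n_regions))
        pred = model.predict(theta)
        model_on_pred = DCMModel(spec, pred)
        n = spec.n_scans * spec.n_regions
        expected = -0.5 * n * np.log(2 * np.pi)
        assert model_on_pred.log_likelihood(theta) == pytest.approx(expected, rel=1e-12)

    def test_quadratic_residual_scaling(self, short_specs):
        """At fixed precision, doubling every residual adds 3x the original
        quadratic term (4x - 1x) to the negative log-likelihood."""
        spec = short_specs[0]
        rng = np.random.default_rng(1)
        pred_model = DCMModel(spec, np.zeros((spec.n_scans, spec.n_regions)))
        theta = pred_model.true_params(noise_sd=np.ones(spec.n_regions))
        pred = pred_model.predict(theta)
        e = rng.normal(0, 0.5, pred.shape)
        ll_1 = dcm_log_likelihood(spec, theta, pred + e)
        ll_2 = dcm_log_likelihood(spec, theta, pred + 2 * e)
        ll_0 = dcm_log_likelihood(spec, theta, pred)
        quad = ll_0 - ll_1  # = lambda/2 sum e^2
        assert ll_1 - ll_2 == pytest.approx(3.0 * quad, rel=1e-9)

    def test_true_parameters_beat_perturbed(self, short_specs):
        """At SNR 1 the likelihood at the generating parameters exceeds that
        at a +0.5 Hz perturbation of a self-connection in >= 95/100 noise
        realizations."""
        spec = short_specs[0]
        sig = integrate_dcm(spec)
        model0 = DCMModel(spec, sig)
        theta = model0.true_params(noise_sd=sig.std(axis=0))
        perturbed = theta.copy()
        perturbed[0] = np.log(2.0)  # self connection -0.5 exp(a): -0.5 -> -1.0 Hz
        wins = 0
        for seed in range(100):
            ds = add_noise_at_snr(sig, 1.0, seed=seed)
            m = DCMModel(spec, ds.observed)
            wins += m.log_likelihood(theta) > m.log_likelihood(perturbed)
        assert wins >= 95

    def test_divergent_parameters_give_neg_inf(self, short_specs):
        spec = short_specs[0]
        model = DCMModel(spec, np.zeros((spec.n_scans, spec.n_regions)))
        theta = model.true_params(noise_sd=np.ones(spec.n_regions))
        theta[0] = 30.0  # self-connection parameter exp(30): instant blow-up
        assert model.log_likelihood(theta) == -np.inf

    def test_wrong_observed_shape_rejected(self, short_specs):
        with pytest.raises(ShapeError):
            DCMModel(short_specs[0], np.zeros((7, 3)))


class TestFixtures:
    def test_m1_is_linear(self, fixture_specs):
        m1 = fixture_specs[0]
        assert np.all(m1.B == 0) and np.all(m1.D == 0)

    def test_only_m5_is_nonlinear(self, fixture_specs):
        assert np.any(fixture_specs[4].D != 0)
        for spec in fixture_specs[1:4]:
            assert np.all(spec.D == 0)

    def test_bilinear_models_have_modulation(self, fixture_specs):
        for spec in fixture_specs[1:4]:
            assert np.any(spec.B != 0)

    def test_all_integrate_without_divergence(self, fixture_specs):
        for spec in fixture_specs:
            sig = integrate_dcm(spec)
            assert np.all(np.isfinite(sig))
            assert sig.shape == (720, 3)

    def test_acquisition_parameters(self, fixture_specs):
        for spec in fixture_specs:
            assert spec.TR == 2.0
            assert spec.n_scans == 720
            assert spec.input_dt == 0.5  # 2.0 Hz input sampling

    def test_yaml_round_trip(self, tmp_path, short_specs):
        path = tmp_path / "spec.yaml"
        short_specs[4].save_yaml(path)
        back = DCMSpec.load_yaml(path)
        np.testing.assert_array_equal(back.A, short_specs[4].A)
        np.testing.assert_array_equal(back.D, short_specs[4].D)
        np.testing.assert_array_equal(
            integrate_dcm(back), integrate_dcm(short_specs[4])
        )


def test_gibbs_step_preserves_likelihood_coherence(short_specs):
    """The noise-block update returns a log-likelihood identical to a fresh
    evaluation at the returned state (trace cache coherence)."""
    spec = short_specs[0]
    sig = integrate_dcm(spec)
    ds = add_noise_at_snr(sig, 1.0, seed=3)
    model = DCMModel(spec, ds.observed)
    rng = np.random.default_rng(0)
    theta = model.prior_sampler(rng)
    new_theta, ll, lp = model.gibbs_step(theta, beta=0.7, rng=rng)
    assert ll == pytest.approx(model.log_likelihood(new_theta), rel=1e-12)
    assert lp == pytest.approx(model.log_prior(new_theta), rel=1e-12)
    # only the trailing noise coordinates may change
    np.testing.assert_array_equal(theta[:-3], new_theta[:-3])
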