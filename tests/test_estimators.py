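"""Unit and property tests for the EA/BAR/TI/MBAR estimators."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

from fepbench.estimators import (
    ReducedPotentialSet,
    WindowSamples,
    bar_estimate,
    ea_estimate,
    mbar_bootstrap_se,
    mbar_estimate,
    ti_estimate,
    windows_from_potentials,
)
from fepbench.exceptions import InputError
from fepbench.synthgen import (
    GaussianWorkSpec,
    HarmonicAlchemySpec,
    sample_gaussian_work,
    sample_harmonic_alchemy,
)

from conftest import UNIT_KT


class TestEA:
    def test_constant_samples_return_the_constant(self):
        est = ea_estimate([2.0, 2.0, 2.0], 300.0)
        assert est.value == pytest.approx(2.0, abs=1e-12)
        assert est.method == "EA"

    def test_two_sample_hand_value(self):
        # -ln((1 + e^-1)/2) = 0.380 at kT = 1
        est = ea_estimate([0.0, 1.0], UNIT_KT)
        assert est.value == pytest.approx(0.3798854930417224, abs=1e-9)

    def test_gaussian_closed_form(self):
        # <exp(-dU)> for N(mu, s^2) gives dG = mu - s^2/(2 kT)
        rng = np.random.default_rng(7)
        mu, sigma, n = 3.0, 1.0, 40000
        est = ea_estimate(rng.normal(mu, sigma, n), UNIT_KT)
        assert est.value == pytest.approx(mu - sigma**2 / 2.0, abs=3 * est.se)

    def test_overflow_guarded(self):
        est = ea_estimate([-1e6, -1e6 + 1.0], UNIT_KT)
        assert np.isfinite(est.value)
        assert est.value < -9e5

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            ea_estimate([], 300.0)


class TestBAR:
    def test_mirror_symmetry(self):
        window = WindowSamples(0.0, 1.0, [3.0, 3.0], [-3.0, -3.0])
        est = bar_estimate(window, UNIT_KT)
        assert est.value == pytest.approx(3.0, abs=1e-5)
        assert est.method == "BAR"
        assert est.meta["se_kind"] == "asymptotic"

    def test_symmetric_two_sample_window(self):
        # Oracle: the Bennett residual is antisymmetric around 0.5 for
        # fwd={0,1}, rev={0,-1}, so the root is exactly 0.5.
        window = WindowSamples(0.0, 1.0, [0.0, 1.0], [0.0, -1.0])
        est = bar_estimate(window, UNIT_KT, tol=1e-9)
        assert est.value == pytest.approx(0.5, abs=1e-8)

    def test_antisymmetry(self):
        rng = np.random.default_rng(11)
        w_f = rng.normal(2.0, 1.5, 80)
        w_r = rng.normal(-1.0, 1.5, 50)
        fwd = bar_estimate(WindowSamples(0, 1, w_f, w_r), UNIT_KT, tol=1e-9)
        rev = bar_estimate(WindowSamples(0, 1, w_r, w_f), UNIT_KT, tol=1e-9)
        assert fwd.value == pytest.approx(-rev.value, abs=1e-7)
        assert fwd.se == pytest.approx(rev.se, rel=1e-6)

    def test_recovers_crooks_consistent_dg(self):
        window, implied = sample_gaussian_work(
            GaussianWorkSpec(mu_f=4.0, sigma=2.0, n_f=10000, n_r=10000,
                             temperature=UNIT_KT, seed=5)
        )
        est = bar_estimate(window, UNIT_KT)
        assert est.value == pytest.approx(implied, abs=3 * est.se)


class TestTI:
    def test_constant_derivative(self):
        est = ti_estimate([0.0, 1.0], [4.2, 4.2])
        assert est.value == pytest.approx(4.2)
        assert est.meta["quadrature"] == "trapezoid"

    def test_three_point_trapezoid(self):
        assert ti_estimate([0, 0.5, 1], [0, 1, 2]).value == pytest.approx(1.0)

    def test_cubic_on_study_schedule_within_truncation_bound(self):
        from fepbench.constants import LAMBDA_SCHEDULE

        lam = np.asarray(LAMBDA_SCHEDULE)
        est = ti_estimate(lam, 3.0 * lam**2)
        # Trapezoid error bound for f''=6lambda: sum h^3/12 * max|f''|
        bound = float(np.sum(np.diff(lam) ** 3 / 12.0 * 6.0))
        assert abs(est.value - 1.0) <= bound + 1e-12

    def test_unordered_lambdas_rejected(self):
        with pytest.raises(InputError):
            ti_estimate([0.0, 0.5, 0.4], [1, 2, 3])


def _two_state_set(seed=3, n=150):
    return sample_harmonic_alchemy(
        HarmonicAlchemySpec(k0=1.0, k1=4.0, lambda_schedule=(0.0, 1.0),
                            n_per_state=n, temperature=UNIT_KT, seed=seed)
    )


class TestMBAR:
    def test_identical_states_give_zero(self):
        res = sample_harmonic_alchemy(
            HarmonicAlchemySpec(k0=2.0, k1=2.0, lambda_schedule=(0.0, 1.0),
                                n_per_state=100, temperature=UNIT_KT, seed=2)
        )
        est = mbar_estimate(res.rps).endpoint
        assert est.value == pytest.approx(0.0, abs=max(3 * est.se, 1e-9))

    def test_two_state_reduces_to_bar(self):
        res = _two_state_set()
        mbar = mbar_estimate(res.rps, tol=1e-10)
        window = windows_from_potentials(res.rps)[0]
        bar = bar_estimate(window, UNIT_KT, tol=1e-10)
        assert mbar.endpoint.value == pytest.approx(bar.value, abs=1e-6)

    def test_harmonic_toy_exact_value(self):
        res = sample_harmonic_alchemy(
            HarmonicAlchemySpec(k0=1.0, k1=4.0, n_per_state=100,
                                temperature=UNIT_KT, seed=9)
        )
        est = mbar_estimate(res.rps).endpoint
        assert res.exact_dg == pytest.approx(0.5 * np.log(4.0))
        assert est.value == pytest.approx(res.exact_dg, abs=3 * est.se)

    def test_matches_independent_convex_optimisation(self):
        """Self-consistent iteration vs a direct scipy minimisation of the
        MBAR log-likelihood: two independent routes, same optimum."""
        res = sample_harmonic_alchemy(
            HarmonicAlchemySpec(n_per_state=60, temperature=UNIT_KT, seed=21)
        )
        rps = res.rps
        u = rps.u  # kT = 1 at UNIT_KT
        counts = rps.state_counts().astype(float)
        log_n = np.log(counts)
        ntot = counts.sum()

        def objective(f_free):
            f = np.concatenate([[0.0], f_free])
            per_snap = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
            return per_snap.sum() / ntot - float(counts @ f) / ntot

        def gradient(f_free):
            f = np.concatenate([[0.0], f_free])
            log_denom = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
            w = np.exp(log_n[:, None] + f[:, None] - u - log_denom[None, :])
            return (w.sum(axis=1) - counts)[1:] / ntot

        opt = minimize(objective, np.zeros(rps.n_states - 1), jac=gradient,
                       method="BFGS", options={"gtol": 1e-12})
        oracle_endpoint = opt.x[-1]
        ours = mbar_estimate(rps, tol=1e-10).endpoint.value
        assert ours == pytest.approx(oracle_endpoint, abs=1e-6)

    def test_telescoping_matches_windowwise_bar(self):
        res = sample_harmonic_alchemy(
            HarmonicAlchemySpec(n_per_state=100, temperature=UNIT_KT, seed=13)
        )
        mbar = mbar_estimate(res.rps)
        total, var = 0.0, 0.0
        for window in windows_from_potentials(res.rps):
            est = bar_estimate(window, UNIT_KT)
            total += est.value
            var += est.se**2
        combined = np.sqrt(var + (mbar.endpoint.se or 0.0) ** 2)
        assert mbar.endpoint.value == pytest.approx(total, abs=3 * combined)

    def test_invalid_inputs_rejected(self):
        res = _two_state_set()
        with pytest.raises(InputError):
            mbar_estimate(res.rps, tol=-1.0)
        with pytest.raises(InputError):
            ReducedPotentialSet(
                lambdas=[0.0, 1.0],
                u=res.rps.u,
                origin=np.zeros(res.rps.n_snapshots, dtype=int),  # state 1 empty
                temperature=UNIT_KT,
            )


class TestBootstrapSE:
    def test_zero_variance_samples_give_zero_se(self):
        u = np.zeros((2, 20))
        u[1, :] = 1.0
        rps = ReducedPotentialSet(
            lambdas=[0.0, 1.0], u=u,
            origin=np.repeat([0, 1], 10), temperature=UNIT_KT,
        )
        boot = mbar_bootstrap_se(rps, n_boot=20, seed=0)
        assert boot.se == pytest.approx(0.0, abs=1e-12)
        assert boot.n_failed == 0

    def test_same_seed_is_deterministic(self):
        res = _two_state_set(seed=4, n=60)
        a = mbar_bootstrap_se(res.rps, n_boot=30, seed=42)
        b = mbar_bootstrap_se(res.rps, n_boot=30, seed=42)
        assert a.se == b.se

    def test_se_shrinks_with_sample_size(self):
        small = _two_state_set(seed=6, n=100)
        big = _two_state_set(seed=6, n=200)
        se_small = mbar_bootstrap_se(small.rps, n_boot=60, seed=1).se
        se_big = mbar_bootstrap_se(big.rps, n_boot=60, seed=1).se
        ratio = se_big / se_small
        assert ratio == pytest.approx(1.0 / np.sqrt(2.0), rel=0.30)


class TestCrossEstimatorProperties:
    def test_ea_directions_bracket_bar_on_average(self):
        """Forward EA is biased high, negated backward EA biased low; BAR
        sits between them on Gaussian work pairs (checked over seeds)."""
        fwd, rev, bar = [], [], []
        for seed in range(40):
            window, _ = sample_gaussian_work(
                GaussianWorkSpec(mu_f=3.0, sigma=2.5, n_f=40, n_r=40,
                                 temperature=UNIT_KT, seed=seed)
            )
            fwd.append(ea_estimate(window.dU_forward, UNIT_KT).value)
            rev.append(-ea_estimate(window.dU_backward, UNIT_KT).value)
            bar.append(bar_estimate(window, UNIT_KT).value)
        assert np.mean(fwd) > np.mean(bar) > np.mean(rev)

    def test_all_four_agree_on_harmonic_toy(self):
        res = sample_harmonic_alchemy(
            HarmonicAlchemySpec(n_per_state=100, temperature=UNIT_KT, seed=17)
        )
        exact = res.exact_dg
        mbar = mbar_estimate(res.rps).endpoint
        assert mbar.value == pytest.approx(exact, abs=3 * mbar.se)

        windows = windows_from_potentials(res.rps)
        bar_total = sum(bar_estimate(w, UNIT_KT).value for w in windows)
        bar_var = sum(bar_estimate(w, UNIT_KT).se ** 2 for w in windows)
        assert bar_total == pytest.approx(exact, abs=3 * np.sqrt(bar_var))

        ea_total = sum(ea_estimate(w.dU_forward, UNIT_KT).value for w in windows)
        ea_var = sum(ea_estimate(w.dU_forward, UNIT_KT).se ** 2 for w in windows)
        assert ea_total == pytest.approx(exact, abs=3 * np.sqrt(ea_var))

        lam = res.rps.lambdas
        means = [float(np.mean(d)) for d in res.dudl]
        ses = [float(np.std(d, ddof=1) / np.sqrt(d.size)) for d in res.dudl]
        ti = ti_estimate(lam, means, ses)
        # allow for the (small) trapezoid truncation bias on this grid
        assert ti.value == pytest.approx(exact, abs=3 * ti.se + 0.01)
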