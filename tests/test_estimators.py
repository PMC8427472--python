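"""TI, MBAR, replica combination: oracle recovery and error structure."""

import math

import numpy as np
import pytest
from scipy.signal import lfilter

from alchemble import (
    FreeEnergyEstimate,
    GaussianDhdlSpec,
    HarmonicAlchemySpec,
    ReducedPotentialSet,
    WindowStat,
    ddg_from_legs,
    ensemble_combine,
    harmonic_replica_potentials,
    make_lambda_schedule,
    mbar_delta_g,
    mbar_ensemble,
    mbar_solve,
    replica_range_report,
    sample_gaussian_dhdl,
    sample_harmonic_alchemy,
    statistical_inefficiency,
    ti_ensemble,
    ti_integrate,
    window_mean_and_sem,
)


def _stats(means, sems, lambdas):
    return [
        WindowStat(lam=l, mean_dhdl=m, sem_dhdl=s, n_eff=100.0, n=100)
        for l, m, s in zip(lambdas, means, sems)
    ]


class TestWindowStats:
    def test_constant_series(self):
        st = window_mean_and_sem(np.full(50, 3.2), lam=0.5)
        assert st.mean_dhdl == pytest.approx(3.2)
        assert st.sem_dhdl == pytest.approx(0.0, abs=1e-12)

    def test_iid_series_has_unit_inefficiency(self, rng):
        g = statistical_inefficiency(rng.standard_normal(10_000))
        assert 0.8 <= g <= 1.3

    def test_ar1_inefficiency_matches_closed_form(self, rng):
        # g -> (1+rho)/(1-rho) = 9 for rho = 0.8
        x = lfilter([1.0], [1.0, -0.8], rng.standard_normal(100_000))
        assert statistical_inefficiency(x) == pytest.approx(9.0, rel=0.3)

    def test_neff_never_exceeds_n(self, rng):
        x = lfilter([1.0], [1.0, -0.5], rng.standard_normal(5_000))
        st = window_mean_and_sem(x)
        assert 1.0 <= st.n_eff <= st.n

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            window_mean_and_sem([1.0])


class TestTiIntegrate:
    def test_constant_integrand(self):
        sched = make_lambda_schedule(13)
        est = ti_integrate(_stats([2.5] * 13, [0.0] * 13, sched.lambdas), sched)
        assert est.value == pytest.approx(2.5)
        assert est.error == 0.0
        assert est.method == "TI"

    def test_trapezoid_error_weights(self):
        # equal sems s on 13 even windows: error = s*sqrt(2/24^2 + 11/12^2)
        sched = make_lambda_schedule(13)
        s = 0.3
        est = ti_integrate(_stats([0.0] * 13, [s] * 13, sched.lambdas), sched)
        expected = s * math.sqrt(2 * (1 / 24) ** 2 + 11 * (1 / 12) ** 2)
        assert est.error == pytest.approx(expected, rel=1e-12)

    def test_harmonic_oracle_recovery(self):
        spec = HarmonicAlchemySpec(k0=1.0, k1=4.0, temperature=300.0,
                                   n_samples_per_window=5000, n_replicas=5, seed=2)
        ens, _ = sample_harmonic_alchemy(spec)
        est = ti_ensemble(ens)
        from alchemble import ti_per_replica
        per_rep_err = np.mean([e.error for e in ti_per_replica(ens)])
        combined = math.hypot(est.error, per_rep_err)
        assert abs(est.value - 0.4132) < 3 * combined

    def test_spline_quadrature_reduces_discretization_bias(self):
        # smooth convex integrand: spline quadrature should be closer to
        # the exact integral than the trapezoid rule
        sched = make_lambda_schedule(13)
        kt = 1.0
        means = [kt * 3.0 / (2 * ((1 - l) + 4 * l)) for l in sched.lambdas]
        exact = kt / 2 * math.log(4.0)
        trap = ti_integrate(_stats(means, [0.0] * 13, sched.lambdas), sched)
        spline = ti_integrate(_stats(means, [0.0] * 13, sched.lambdas), sched,
                              quadrature="natural_spline")
        assert abs(spline.value - exact) < abs(trap.value - exact)

    def test_error_monotone_in_neff(self):
        # halving every sem (doubling n_eff fourfold) shrinks the error
        sched = make_lambda_schedule(5)
        base = ti_integrate(_stats([1.0] * 5, [0.4] * 5, sched.lambdas), sched)
        finer = ti_integrate(_stats([1.0] * 5, [0.2] * 5, sched.lambdas), sched)
        assert finer.error < base.error

    def test_grid_mismatch_rejected(self):
        sched = make_lambda_schedule(5)
        bad = _stats([0.0] * 5, [0.1] * 5, [0.0, 0.2, 0.4, 0.6, 1.0])
        with pytest.raises(ValueError):
            ti_integrate(bad, sched)

    def test_unsorted_input_rejected(self):
        sched = make_lambda_schedule(3)
        stats = _stats([0.0] * 3, [0.1] * 3, [0.0, 1.0, 0.5])
        with pytest.raises(ValueError):
            ti_integrate(stats, sched)


class TestMbar:
    def test_two_identical_states(self, rng):
        u = np.tile(0.5 * rng.standard_normal(200) ** 2, (2, 1))
        rp = ReducedPotentialSet(u_kn=u, counts=[100, 100])
        ests = mbar_solve(rp)
        assert ests[1].value == pytest.approx(0.0, abs=1e-9)

    def test_harmonic_oracle_recovery(self):
        spec = HarmonicAlchemySpec(k0=1.0, k1=4.0, temperature=300.0,
                                   n_samples_per_window=2000, n_replicas=1, seed=8)
        rp = harmonic_replica_potentials(spec)[0]
        est = mbar_delta_g(rp)
        assert abs(est.value - 0.4132) < 3 * est.error

    def test_converged_solution_satisfies_self_consistency(self):
        spec = HarmonicAlchemySpec(n_samples_per_window=300, n_replicas=1, seed=1)
        rp = harmonic_replica_potentials(spec)[0]
        from alchemble.estimators import _mbar_update
        from alchemble.constants import kt_kcal
        ests = mbar_solve(rp, tol=1e-12)
        f = np.array([e.value for e in ests]) / kt_kcal(rp.temperature)
        residual = np.max(np.abs(_mbar_update(f, rp.u_kn, np.log(rp.counts)) - f))
        assert residual < 1e-10

    def test_anchored_shift_invariance(self, rng):
        # adding a constant c to one state's reduced-energy row shifts its
        # anchored free energy by exactly c*kT
        x = rng.standard_normal(400)
        u = np.vstack([0.5 * x**2, 0.5 * 2.0 * x**2])
        rp = ReducedPotentialSet(u_kn=u, counts=[200, 200], temperature=300.0)
        base = mbar_solve(rp)[1].value
        c = 1.7
        rp_shift = ReducedPotentialSet(
            u_kn=np.vstack([u[0], u[1] + c]), counts=[200, 200], temperature=300.0
        )
        shifted = mbar_solve(rp_shift)[1].value
        from alchemble.constants import kt_kcal
        assert shifted - base == pytest.approx(c * kt_kcal(300.0), abs=1e-8)

    def test_per_sample_constant_leaves_differences_invariant(self, rng):
        x = rng.standard_normal(300)
        u = np.vstack([0.5 * x**2, 0.5 * 3.0 * x**2])
        rp = ReducedPotentialSet(u_kn=u, counts=[150, 150])
        base = mbar_solve(rp)[1].value
        rp2 = ReducedPotentialSet(u_kn=u + rng.standard_normal(300)[None, :],
                                  counts=[150, 150])
        assert mbar_solve(rp2)[1].value == pytest.approx(base, abs=1e-8)

    def test_zero_sample_state_rejected(self, rng):
        u = np.vstack([np.zeros(10), np.ones(10)])
        with pytest.raises(ValueError):
            mbar_solve(ReducedPotentialSet(u_kn=u, counts=[10, 0]))

    def test_nonconvergence_is_reported(self):
        spec = HarmonicAlchemySpec(n_samples_per_window=200, n_replicas=1, seed=1)
        rp = harmonic_replica_potentials(spec)[0]
        from alchemble import MbarConvergenceError
        with pytest.raises(MbarConvergenceError):
            mbar_solve(rp, tol=1e-14, max_iter=2)

    def test_ti_and_mbar_agree_on_harmonic_system(self):
        spec = HarmonicAlchemySpec(k0=1.0, k1=4.0, temperature=300.0,
                                   n_samples_per_window=2000, n_replicas=3, seed=5)
        ens, _ = sample_harmonic_alchemy(spec)
        ti = ti_ensemble(ens)
        mbar = mbar_ensemble(harmonic_replica_potentials(spec))
        combined = math.hypot(ti.error, mbar.error)
        assert abs(ti.value - mbar.value) < 3 * max(combined, 1e-3)


class TestEnsembleCombine:
    def test_identical_replicas(self):
        ests = [FreeEnergyEstimate(1.0, 0.1, "TI") for _ in range(3)]
        out = ensemble_combine(ests)
        assert out.value == 1.0 and out.replica_sd == 0.0 and out.error == 0.0

    def test_hand_computed_sd_and_sem(self):
        ests = [FreeEnergyEstimate(v, 0.0, "TI") for v in (0.0, 1.0, 2.0)]
        out = ensemble_combine(ests)
        assert out.value == pytest.approx(1.0)
        assert out.replica_sd == pytest.approx(1.0)
        assert out.error == pytest.approx(0.5774, abs=1e-4)

    def test_error_times_sqrt_n_equals_replica_sd(self):
        for vals in ([0.0, 1.0], [0.0, 1.0, 2.0, 3.0, 4.0], list(range(9))):
            out = ensemble_combine(
                [FreeEnergyEstimate(float(v), 0.0, "TI") for v in vals]
            )
            assert out.error * math.sqrt(len(vals)) == pytest.approx(out.replica_sd)

    def test_sem_scales_as_inverse_sqrt_n(self):
        # averaged over seeds, SEM(5 replicas) / SEM(20 replicas) ~ 2
        def mean_sem(n_rep, seeds):
            sems = []
            for seed in seeds:
                spec = GaussianDhdlSpec(
                    profile_coeffs=(1.0, -2.0), ar1_rho=0.3, sigma_within=0.5,
                    sigma_replica=0.4, n_samples_per_window=50,
                    n_replicas=n_rep, seed=seed,
                )
                sems.append(ti_ensemble(sample_gaussian_dhdl(spec)).error)
            return np.mean(sems)

        seeds = range(30)
        ratio = mean_sem(5, seeds) / mean_sem(20, seeds)
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_mixed_methods_rejected(self):
        with pytest.raises(ValueError):
            ensemble_combine(
                [FreeEnergyEstimate(1.0, 0.1, "TI"),
                 FreeEnergyEstimate(1.0, 0.1, "MBAR")]
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ensemble_combine([])


class TestDdgFromLegs:
    def test_subtraction_and_error_propagation(self):
        c = FreeEnergyEstimate(-10.0, 0.3, "TI")
        s = FreeEnergyEstimate(-8.0, 0.4, "TI")
        out = ddg_from_legs(c, s)
        assert out.value == pytest.approx(-2.0)
        assert out.error == pytest.approx(0.5)

    def test_identical_legs_give_zero_with_sqrt2_error(self):
        leg = FreeEnergyEstimate(-5.0, 0.2, "MBAR")
        out = ddg_from_legs(leg, leg)
        assert out.value == 0.0
        assert out.error == pytest.approx(0.2 * math.sqrt(2))

    def test_recovers_difference_of_harmonic_truths(self):
        spec_c = HarmonicAlchemySpec(k0=1.0, k1=4.0, temperature=300.0,
                                     n_samples_per_window=3000, n_replicas=5, seed=21)
        spec_s = HarmonicAlchemySpec(k0=1.0, k1=2.0, temperature=300.0,
                                     n_samples_per_window=3000, n_replicas=5, seed=22)
        ens_c, _ = sample_harmonic_alchemy(spec_c)
        ens_s, _ = sample_harmonic_alchemy(spec_s)
        ddg = ddg_from_legs(ti_ensemble(ens_c), ti_ensemble(ens_s))
        truth = spec_c.truth - spec_s.truth
        assert abs(ddg.value - truth) < 3 * max(ddg.error, 2e-3)
        assert ddg.per_replica is not None and len(ddg.per_replica) == 5

    def test_method_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ddg_from_legs(FreeEnergyEstimate(1.0, 0.1, "TI"),
                          FreeEnergyEstimate(1.0, 0.1, "MBAR"))

    def test_unequal_replica_counts_warn_and_fall_back(self):
        c = ensemble_combine([FreeEnergyEstimate(v, 0.0, "TI") for v in (1.0, 2.0)])
        s = ensemble_combine(
            [FreeEnergyEstimate(v, 0.0, "TI") for v in (0.0, 1.0, 2.0)]
        )
        with pytest.warns(UserWarning):
            out = ddg_from_legs(c, s)
        assert out.per_replica is None


class TestReplicaRangeReport:
    def test_range_is_max_minus_min(self):
        rep = replica_range_report([1.0, 2.0, 1.5])
        assert rep["range"] == pytest.approx(1.0)
        assert rep["mean_mbar_err"] is None

    def test_degenerate_replicas(self):
        rep = replica_range_report([2.0, 2.0, 2.0], mbar_errs=[0.1, 0.1, 0.1])
        assert rep["sd"] == 0.0 and rep["range"] == 0.0
        assert rep["mean_mbar_err"] == pytest.approx(0.1)

    def test_replica_sd_exceeds_mbar_error_under_replica_bias(self):
        # replica-level bias >> sampling noise: between-replica SD dwarfs
        # the per-replica MBAR asymptotic errors
        spec = HarmonicAlchemySpec(n_samples_per_window=500, n_replicas=5,
                                   seed=17, sigma_replica=0.5)
        ests = [mbar_delta_g(rp) for rp in harmonic_replica_potentials(spec)]
        rep = replica_range_report([e.value for e in ests],
                                   [e.error for e in ests])
        assert rep["sd"] > rep["mean_mbar_err"]

    def test_single_replica_rejected(self):
        with pytest.raises(ValueError):
            replica_range_report([1.0])


class TestBiasRecovery:
    def test_ti_estimator_is_unbiased_over_seeds(self):
        # mean TI estimate over 150 generator seeds within 2 SEM of truth
        spec0 = GaussianDhdlSpec(profile_coeffs=(1.0, 2.0, -1.5), ar1_rho=0.4,
                                 sigma_within=1.0, sigma_replica=0.3,
                                 n_samples_per_window=60, n_replicas=3)
        truth = spec0.truth
        vals = []
        for seed in range(150):
            spec = GaussianDhdlSpec(
                profile_coeffs=spec0.profile_coeffs, ar1_rho=spec0.ar1_rho,
                sigma_within=spec0.sigma_within, sigma_replica=spec0.sigma_replica,
                n_samples_per_window=spec0.n_samples_per_window,
                n_replicas=spec0.n_replicas, seed=seed,
            )
            vals.append(ti_ensemble(sample_gaussian_dhdl(spec)).value)
        vals = np.asarray(vals)
        sem = vals.std(ddof=1) / math.sqrt(vals.size)
        assert abs(vals.mean() - truth) < 2 * sem
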