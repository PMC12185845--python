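import numpy as np
import pytest

from calyxpath import constants, dctmd, synthetic
from calyxpath.traj_io import PullRecord


class TestWorkFromForce:
    def test_constant_force_gives_f_times_length(self):
        # 10 kJ/mol/nm over 1 nm of travel -> 10 kJ/mol
        v = 1.0  # m/s = 0.01 A/ps; 1 nm = 10 A takes 1000 ps
        t = np.linspace(0.0, 1000.0, 501)
        rec = PullRecord(times=t, values=np.full_like(t, 10.0),
                         velocity=v, kind="force")
        grid, w = dctmd.work_from_force(rec)
        assert grid[-1] == pytest.approx(10.0)
        assert w[-1] == pytest.approx(10.0, rel=1e-9)

    def test_sin_force_matches_analytic_integral(self):
        v = 1.0
        t = np.linspace(0.0, 1000.0, 2001)
        x = v * constants.M_PER_S_TO_A_PER_PS * t  # 0..10 A
        force_per_a = 2.0 * np.sin(x)  # kJ/mol/A
        rec = PullRecord(
            times=t, values=force_per_a * constants.ANGSTROM_PER_NM,
            velocity=v, kind="force",
        )
        grid, w = dctmd.work_from_force(rec)
        analytic = 2.0 * (1.0 - np.cos(grid))
        assert np.abs(w - analytic).max() < 1e-3  # trapezoid error bound

    def test_zero_force_zero_work(self):
        t = np.linspace(0.0, 100.0, 101)
        rec = PullRecord(times=t, values=np.zeros_like(t), velocity=1.0,
                         kind="force")
        _, w = dctmd.work_from_force(rec)
        np.testing.assert_allclose(w, 0.0)

    def test_non_uniform_sampling_rejected(self):
        t = np.array([0.0, 1.0, 2.0, 4.0])
        rec = PullRecord(times=t, values=np.ones_like(t), velocity=1.0,
                         kind="force")
        with pytest.raises(ValueError, match="non-uniform"):
            dctmd.work_from_force(rec)

    def test_ensemble_from_records_matches_direct_generation(self):
        spec = synthetic.PullSimSpec(n_replicas=4, t_total=500.0, seed=11)
        records, _ = synthetic.gen_pull_records(spec)
        ens = dctmd.build_ensemble(records, temperature=spec.temperature)
        ens2, _ = synthetic.gen_work_ensemble(spec, mode="langevin")
        # same noise stream -> same work curves up to integration detail
        np.testing.assert_allclose(ens.works, ens2.works, atol=1e-8)


class TestEstimateProfile:
    def test_identical_replicas_dissipation_free(self):
        grid = np.linspace(0.0, 10.0, 101)
        w = np.tile(np.sin(grid / 3.0) * 5.0, (4, 1))
        w -= w[:, :1]
        ens = dctmd.WorkEnsemble(grid=grid, works=w, velocity=1.0,
                                 temperature=300.0)
        prof = dctmd.estimate_profile(ens, smoothing_sigma=0.5)
        np.testing.assert_allclose(prof.dG, w[0] - w[0][0], atol=1e-10)
        np.testing.assert_allclose(prof.friction, 0.0, atol=1e-10)

    def test_identity_dG_plus_wdiss_is_wmean(self, small_gaussian_ensemble):
        _, ens, _ = small_gaussian_ensemble
        prof = dctmd.estimate_profile(ens)
        np.testing.assert_allclose(
            prof.dG + prof.w_diss, prof.w_mean, atol=1e-10
        )
        assert prof.dG[0] == 0.0 and prof.w_diss[0] == 0.0

    def test_constant_friction_recovered_within_10pct(self):
        spec = synthetic.PullSimSpec(
            potential=synthetic.HarmonicPotential(k=0.0),
            friction=synthetic.FrictionProfile(gamma0=2.0e12, bumps=[]),
            n_replicas=200, seed=0,
        )
        ens, truth = synthetic.gen_work_ensemble(spec, mode="gaussian_analytic")
        prof = dctmd.estimate_profile(ens)
        mask = (ens.grid >= 1.0) & (ens.grid <= spec.length - 1.0)
        gamma_hat = prof.friction[mask].mean()
        assert gamma_hat == pytest.approx(truth["gamma0"], rel=0.10)

    def test_langevin_double_well_recovery(self):
        spec = synthetic.PullSimSpec(n_replicas=200, seed=0)
        ens, truth = synthetic.gen_work_ensemble(spec, mode="langevin")
        prof = dctmd.estimate_profile(ens)
        rms = np.sqrt(np.mean((prof.dG - truth["dG"]) ** 2))
        assert rms < 2.0
        # friction peak co-locates with the planted high-friction window
        peak_x = prof.grid[np.argmax(prof.friction)]
        bump_centre = spec.friction.bumps[0][1]
        assert abs(peak_x - bump_centre) < 1.0

    def test_friction_non_negative_up_to_noise(self, small_gaussian_ensemble):
        spec, ens, truth = small_gaussian_ensemble
        prof = dctmd.estimate_profile(ens)
        assert prof.friction.min() > -0.05 * truth["gamma0"]

    def test_jarzynski_consistency_on_gaussian_ensemble(self):
        spec = synthetic.PullSimSpec(
            friction=synthetic.FrictionProfile(gamma0=2.0e11, bumps=[]),
            n_replicas=400, seed=2,
        )
        ens, _ = synthetic.gen_work_ensemble(spec, mode="gaussian_analytic")
        prof = dctmd.estimate_profile(ens)
        dg_jarz = dctmd.jarzynski_profile(ens)
        # cumulant and exponential-average agree within the (large)
        # jarzynski sampling error; low dissipation keeps that error modest
        assert np.abs(dg_jarz - prof.dG).max() < 2.0

    def test_parameter_errors(self, small_gaussian_ensemble):
        _, ens, _ = small_gaussian_ensemble
        with pytest.raises(ValueError):
            dctmd.WorkEnsemble(grid=ens.grid, works=ens.works, velocity=-1.0,
                               temperature=300.0)
        with pytest.raises(ValueError):
            dctmd.WorkEnsemble(grid=ens.grid, works=ens.works, velocity=1.0,
                               temperature=0.0)
        single = dctmd.WorkEnsemble(
            grid=ens.grid, works=ens.works[:1], velocity=1.0, temperature=300.0
        )
        with pytest.raises(ValueError, match="2 replicas"):
            dctmd.estimate_profile(single)


class TestBiasDecay:
    def test_friction_error_decreases_with_replicas(self):
        # averaged over seeds, the plateau-friction RMS error shrinks
        errors = {}
        for n in (50, 200, 800):
            errs = []
            for seed in range(16):
                spec = synthetic.PullSimSpec(
                    potential=synthetic.HarmonicPotential(k=0.0),
                    friction=synthetic.FrictionProfile(gamma0=2.0e12, bumps=[]),
                    n_replicas=n, t_total=1000.0, seed=seed,
                )
                ens, truth = synthetic.gen_work_ensemble(
                    spec, mode="gaussian_analytic"
                )
                prof = dctmd.estimate_profile(ens)
                mask = (ens.grid >= 1.0) & (ens.grid <= spec.length - 1.0)
                errs.append(
                    prof.friction[mask].mean() / truth["gamma0"] - 1.0
                )
            errors[n] = float(np.sqrt(np.mean(np.square(errs))))
        assert errors[50] > errors[200] > errors[800]


class TestNormality:
    def test_gaussian_ensemble_mostly_unflagged(self, small_gaussian_ensemble):
        _, ens, _ = small_gaussian_ensemble
        diag = dctmd.normality_diagnostic(ens)
        assert diag.flagged.mean() <= 0.05

    def test_exponential_work_flagged(self):
        rng = np.random.default_rng(0)
        grid = np.linspace(0.0, 10.0, 51)
        # strongly skewed work increments (exponential) accumulate skewness
        incs = rng.exponential(1.0, size=(64, 50)) * 5.0
        works = np.concatenate(
            (np.zeros((64, 1)), np.cumsum(incs, axis=1)), axis=1
        )
        ens = dctmd.WorkEnsemble(grid=grid, works=works, velocity=1.0,
                                 temperature=300.0)
        diag = dctmd.normality_diagnostic(ens)
        # skewness of a sum of k unit exponentials decays as 2/sqrt(k), so
        # the flags concentrate over the early part of the accumulation
        assert diag.flagged[1:8].mean() > 0.5
        assert diag.flagged[1:8].mean() > diag.flagged[25:].mean()

    def test_too_few_replicas_rejected(self, small_gaussian_ensemble):
        _, ens, _ = small_gaussian_ensemble
        small = dctmd.WorkEnsemble(
            grid=ens.grid, works=ens.works[:2], velocity=1.0, temperature=300.0
        )
        with pytest.raises(ValueError, match="8 replicas"):
            dctmd.normality_diagnostic(small)
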