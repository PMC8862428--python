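"""Fitting-layer tests: slope extraction, per-level hyperbolic fits, the
global activator fit (identifiability, oracle comparison, reductions),
bootstrap intervals, and the simulate-and-refit recovery harness."""

import itertools

import numpy as np
import pandas as pd
import pytest

import actikin as ak
from actikin.errors import (
    DegenerateDataError,
    DegenerateTimecourseError,
    DesignError,
    InvalidParameterError,
)
from actikin.fit import observations_to_frame


class TestRateExtraction:
    def test_exact_line_recovers_slope_over_molarity(self):
        ctx = ak.standard_context("detergent")
        e_uM = ak.transporter_molarity(ctx) * 1e6
        tc = ak.TimeCourse("detergent", 1.0, 0.0, 0,
                           times=(0.0, 5.0, 10.0, 15.0),
                           pi_conc=tuple(3.0 * t + 1.0 for t in (0.0, 5.0, 10.0, 15.0)))
        obs = ak.extract_rate(tc, ctx)
        assert obs.rate == pytest.approx(3.0 / e_uM)

    def test_roundtrip_from_noise_free_model(self, detergent_params):
        ctx = ak.standard_context("detergent")
        tc = ak.simulate_timecourse(
            detergent_params, ctx, 2.0, 10.0, ak.NoiseSpec(0.0, 0.0), seed=0
        )
        obs = ak.extract_rate(tc, ctx)
        expected = ak.specific_rate(detergent_params, 2.0, 10.0)
        assert obs.rate == pytest.approx(float(expected), rel=1e-10)

    def test_intercept_is_free_not_forced_through_origin(self):
        ctx = ak.standard_context("detergent")
        base = ak.TimeCourse("d", 1.0, 0.0, 0, (0.0, 5.0, 10.0, 15.0),
                             (0.0, 15.0, 30.0, 45.0))
        shifted = ak.TimeCourse("d", 1.0, 0.0, 0, (0.0, 5.0, 10.0, 15.0),
                                (7.0, 22.0, 37.0, 52.0))
        assert ak.extract_rate(base, ctx).rate == pytest.approx(
            ak.extract_rate(shifted, ctx).rate
        )

    def test_degenerate_times_rejected(self):
        ctx = ak.standard_context("detergent")
        tc = ak.TimeCourse("d", 1.0, 0.0, 0, (5.0, 5.0), (1.0, 2.0))
        with pytest.raises(DegenerateTimecourseError):
            ak.extract_rate(tc, ctx)


class TestMichaelisFit:
    def test_noise_free_recovery(self):
        p = ak.MichaelisParams(kcat=18.0, Km=0.82)
        atp = np.array([0.0, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0])
        df = pd.DataFrame({"atp": atp, "gssg": 0.0, "rate": ak.mm_rate(p, atp)})
        fit = ak.fit_michaelis(df)
        assert fit.params.kcat == pytest.approx(18.0, rel=1e-6)
        assert fit.params.Km == pytest.approx(0.82, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.converged

    def test_single_gssg_curve_equals_apparent_constants(self, detergent_params):
        # per-level hyperbolic fit of activator-model data returns the
        # apparent constants of the factorized form
        atp = np.array([0.0, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0])
        s = 20.0
        df = pd.DataFrame({
            "atp": atp, "gssg": s,
            "rate": ak.specific_rate(detergent_params, atp, np.full_like(atp, s)),
        })
        fit = ak.fit_michaelis(df)
        assert fit.params.kcat == pytest.approx(
            float(ak.kobs(detergent_params, s)), rel=1e-6
        )
        assert fit.params.Km == pytest.approx(
            float(ak.kt_app(detergent_params, s)), rel=1e-6
        )

    def test_all_zero_rates_rejected(self):
        df = pd.DataFrame({"atp": [0.0, 1.0, 2.0, 5.0], "gssg": 0.0, "rate": 0.0})
        with pytest.raises(DegenerateDataError):
            ak.fit_michaelis(df)

    def test_too_few_atp_levels_rejected(self):
        df = pd.DataFrame({"atp": [0.0, 1.0], "gssg": 0.0, "rate": [0.0, 5.0]})
        with pytest.raises(DesignError):
            ak.fit_michaelis(df)

    def test_mixed_gssg_requires_selector(self, noise_free_detergent_obs):
        with pytest.raises(DegenerateDataError):
            ak.fit_michaelis(noise_free_detergent_obs)
        fit = ak.fit_michaelis(noise_free_detergent_obs, gssg=0.0)
        assert fit.params.kcat == pytest.approx(17.58, rel=1e-6)


class TestGlobalActivatorFit:
    @pytest.mark.parametrize("condition", ak.CONDITIONS)
    def test_noise_free_identifiability_all_conditions(self, condition):
        truth = ak.REFERENCE_PARAMS[condition]
        obs = ak.simulate_dataset(
            truth, ak.standard_context(condition), ak.standard_design(condition),
            ak.NoiseSpec(0.0, 0.0), seed=0,
        )
        fit = ak.fit_activator_global(obs, seed=0)
        for name in ak.ActivatorParams.names():
            assert getattr(fit.params, name) == pytest.approx(
                getattr(truth, name), abs=5e-3
            ), name
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.converged and fit.n_points == 48

    def test_standard_errors_and_covariance_sane(self, noise_free_detergent_obs):
        fit = ak.fit_activator_global(noise_free_detergent_obs, seed=0)
        cov = fit.covariance
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) >= -1e-12)
        assert all(se >= 0 for se in fit.standard_errors.values())

    def test_optimizer_beats_brute_force_grid(self, nanodisc_params):
        """The multi-start optimum is at least as good as a coarse log-grid scan."""
        obs = ak.simulate_dataset(
            nanodisc_params, ak.standard_context("nanodiscs"),
            ak.standard_design("nanodiscs"), ak.NoiseSpec(0.05, 0.5), seed=21,
        )
        df = observations_to_frame(obs)
        means = df.groupby(["gssg", "atp"], as_index=False)["rate"].mean()
        atp, gssg, rate = (means[c].to_numpy() for c in ("atp", "gssg", "rate"))

        def ssr(p):
            return float(np.sum((ak.specific_rate(p, atp, gssg) - rate) ** 2))

        axes = [np.geomspace(getattr(nanodisc_params, n) / 3,
                             getattr(nanodisc_params, n) * 3, 5)
                for n in ak.ActivatorParams.names()]
        best_grid = min(
            ssr(ak.ActivatorParams(*vals)) for vals in itertools.product(*axes)
        )
        fit = ak.fit_activator_global(obs, seed=2)
        assert fit.ssr <= best_grid + 1e-9

    def test_reduction_alpha_beta_one_matches_pooled_michaelis(self):
        p = ak.ActivatorParams(k=12.0, K_T=0.9, K_S=10.0, alpha=1.0, beta=1.0)
        obs = ak.simulate_dataset(
            p, ak.standard_context("detergent"), ak.standard_design("detergent"),
            ak.NoiseSpec(0.0, 0.0), seed=4,
        )
        fit = ak.fit_activator_global(obs, seed=4)
        se = fit.standard_errors
        assert abs(fit.params.alpha - 1.0) <= max(2 * se["alpha"], 1e-3)
        assert abs(fit.params.beta - 1.0) <= max(2 * se["beta"], 1e-3)
        df = observations_to_frame(obs)
        df["gssg"] = 0.0  # pool all levels into one hyperbolic fit
        pooled = ak.fit_michaelis(df)
        assert fit.params.k == pytest.approx(pooled.params.kcat, rel=0.01)
        assert fit.params.K_T == pytest.approx(pooled.params.Km, rel=0.01)

    def test_per_curve_r_squared_reported_for_every_level(
        self, noise_free_detergent_obs
    ):
        fit = ak.fit_activator_global(noise_free_detergent_obs, seed=0)
        assert set(fit.r_squared_per_curve) == {0.0, 1.0, 2.5, 5.0, 10.0, 20.0}
        assert all(r <= 1.0 for r in fit.r_squared_per_curve.values())

    def test_missing_basal_series_rejected(self, noise_free_detergent_obs):
        df = observations_to_frame(noise_free_detergent_obs)
        with pytest.raises(DesignError):
            ak.fit_activator_global(df[df["gssg"] > 0])
        with pytest.raises(DesignError):
            ak.fit_activator_global(df[df["gssg"] == 0.0])


class TestDerivedCurves:
    def test_basal_row(self, noise_free_detergent_obs):
        fit = ak.fit_activator_global(noise_free_detergent_obs, seed=0)
        table = ak.derived_curves(fit, [0.0, 20.0])
        row0 = table[table["gssg_mM"] == 0.0].iloc[0]
        assert row0["kobs_per_min"] == pytest.approx(fit.params.k)
        assert row0["kt_app_mM"] == pytest.approx(fit.params.K_T)
        assert row0["fold_stimulation"] == pytest.approx(1.0)

    def test_reference_fold_and_kobs_values(self, proteoliposome_params):
        fit = ak.FitResult(
            model_kind="activator", params=proteoliposome_params,
            standard_errors={}, covariance=np.eye(5), r_squared=1.0, converged=True,
        )
        table = ak.derived_curves(fit, [20.0])
        row = table.iloc[-1]
        assert row["kobs_per_min"] == pytest.approx(107.2, abs=0.1)
        assert row["fold_rounded"] == 11


@pytest.fixture(scope="module")
def noisy_detergent_obs(detergent_params):
    return ak.simulate_dataset(
        detergent_params, ak.standard_context("detergent"),
        ak.standard_design("detergent"), ak.NoiseSpec(0.05, 0.5), seed=13,
    )


class TestBootstrap:
    def test_noise_free_intervals_collapse(self, noise_free_detergent_obs):
        ci = ak.bootstrap_uncertainty(noise_free_detergent_obs, n_boot=100, seed=0)
        width = (ci["ci_high"] - ci["ci_low"]) / ci["estimate"]
        assert np.all(width.to_numpy() <= 1e-6)
        assert ci.attrs["failure_fraction"] == 0.0

    def test_seed_determinism_and_coverage(self, detergent_params, noisy_detergent_obs):
        a = ak.bootstrap_uncertainty(noisy_detergent_obs, n_boot=100, seed=3)
        b = ak.bootstrap_uncertainty(noisy_detergent_obs, n_boot=100, seed=3)
        pd.testing.assert_frame_equal(a, b)
        # generator basal rate lies inside its bootstrap interval
        row = a[a["parameter"] == "k"].iloc[0]
        assert row["ci_low"] <= detergent_params.k <= row["ci_high"]

    def test_small_n_boot_rejected(self, noise_free_detergent_obs):
        with pytest.raises(InvalidParameterError):
            ak.bootstrap_uncertainty(noise_free_detergent_obs, n_boot=50)


class TestRecoveryExperiment:
    def test_noise_free_recovery_is_exact(self, proteoliposome_params):
        report = ak.recovery_experiment(
            proteoliposome_params, ak.standard_context("proteoliposomes"),
            ak.standard_design("proteoliposomes"), ak.NoiseSpec(0.0, 0.0),
            n_sims=1, seed=0,
        )
        assert report.passed
        assert all(abs(b) < 1e-6 for b in report.bias.values())
        assert all(f == 1.0 for f in report.fraction_within_tolerance.values())

    def test_invalid_n_sims_rejected(self, detergent_params):
        with pytest.raises(InvalidParameterError):
            ak.recovery_experiment(
                detergent_params, ak.standard_context("detergent"),
                ak.standard_design("detergent"), n_sims=0, seed=0,
            )
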