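"""Likelihood machinery, model fits, and model comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from pkpdkit.estimation import (
    PopPKEstimator,
    TumorGrowthEstimator,
    compare_models,
    fit_pd,
    fit_pk,
    loglik,
)
from pkpdkit.pk_model import PKParameters, Regimen, human_default_params, simulate
from pkpdkit.population import OmegaSpec, ResidualSpec
from pkpdkit.synthetic_data import (
    generate_monkey_pk_study,
    generate_xenograft_study,
    monkey_single_dose_design,
)
from pkpdkit.population import LLOQRule, pk_omega_defaults, pk_residual_defaults
from pkpdkit.tumor_pd import pd_default_params
from pkpdkit.workflow_io import DATASET_COLUMNS


def _make_dataset(params, doses, times, noise=None, seed=0, weights=None):
    """Small long-format concentration dataset simulated from the model."""
    rng = np.random.default_rng(seed)
    rows = []
    for sid, dose in enumerate(doses, start=1):
        weight = None if weights is None else weights[sid - 1]
        rows.append({"ID": sid, "TIME": 0.0, "AMT": dose, "DV": np.nan,
                     "EVID": 1, "MDV": 1, "CMT": 1, "WT": weight, "BLQ": 0})
        course = simulate(params, Regimen.single_dose(dose), np.asarray(times))
        conc = course.concentrations
        if noise:
            conc = conc * (1.0 + noise * rng.standard_normal(len(conc)))
        for t, c in zip(times, conc):
            rows.append({"ID": sid, "TIME": t, "AMT": np.nan, "DV": c,
                         "EVID": 0, "MDV": 0, "CMT": 1, "WT": weight, "BLQ": 0})
    return pd.DataFrame(rows)


class TestLoglik:
    times = [1.0, 8.0, 24.0, 96.0, 240.0, 504.0]

    def test_matches_closed_form_gaussian(self, human_params):
        """Pooled -2LL equals the closed-form sum
        sum[ln(2 pi s^2 f^2) + (y-f)^2/(s^2 f^2)] for proportional error."""
        df = _make_dataset(human_params, [360.0], self.times, noise=0.1, seed=1)
        sigma = 0.15
        value = loglik(human_params, df, None, ResidualSpec(sigma, 0.0),
                       method="pooled")
        obs = df[df.EVID == 0]
        pred = simulate(human_params, Regimen.single_dose(360.0),
                        obs.TIME.to_numpy()).concentrations
        var = (sigma * pred) ** 2
        expected = np.sum(np.log(2 * np.pi * var) + (obs.DV.to_numpy() - pred) ** 2 / var)
        assert value == pytest.approx(expected, rel=1e-9)

    def test_duplicated_observations_double_the_value(self, human_params):
        df = _make_dataset(human_params, [360.0], self.times, noise=0.1, seed=2)
        doubled = pd.concat([df, df[df.EVID == 0]], ignore_index=True)
        single = loglik(human_params, df, None, ResidualSpec(0.15, 0.0))
        double = loglik(human_params, doubled, None, ResidualSpec(0.15, 0.0))
        assert double == pytest.approx(2.0 * single, rel=1e-9)

    def test_laplace_agrees_with_gauss_hermite(self, human_params):
        """Laplace marginal -2LL vs 32-node Gauss-Hermite quadrature on a
        two-subject toy set with one random effect: within 0.1 units."""
        times = [2.0, 24.0, 168.0, 504.0]
        df = _make_dataset(human_params, [100.0, 360.0], times, noise=0.12, seed=3)
        omega = OmegaSpec({"CL": 20.0})
        residual = ResidualSpec(0.12, 0.0)
        value = loglik(human_params, df, omega, residual, method="laplace")

        # independent quadrature oracle
        nodes, weights = np.polynomial.hermite_e.hermegauss(32)
        sd = omega.sd("CL")
        total = 0.0
        for sid, group in df[df.EVID == 0].groupby("ID"):
            dose = float(df[(df.ID == sid) & (df.EVID == 1)].AMT.iloc[0])
            y = group.DV.to_numpy()
            t = group.TIME.to_numpy()
            like = 0.0
            for z, w in zip(nodes, weights):
                eta = sd * z
                ind = human_params.replace(CL=human_params.CL * math.exp(eta))
                f = simulate(ind, Regimen.single_dose(dose), t).concentrations
                var = (residual.proportional_sd * f) ** 2
                log_density = -0.5 * np.sum(np.log(2 * np.pi * var)
                                            + (y - f) ** 2 / var)
                like += w * math.exp(log_density)
            like /= math.sqrt(2 * math.pi)
            total += -2.0 * math.log(like)
        assert value == pytest.approx(total, abs=0.1)

    def test_invariant_to_time_unit_rescaling(self, human_params):
        """Expressing times in days with correspondingly rescaled flow
        parameters leaves the likelihood unchanged."""
        df = _make_dataset(human_params, [360.0], self.times, noise=0.1, seed=4)
        res = ResidualSpec(0.15, 0.0)
        base = loglik(human_params, df, None, res)
        df_days = df.copy()
        df_days["TIME"] = df_days["TIME"] / 24.0
        daily = human_params.replace(CL=human_params.CL * 24, Q=human_params.Q * 24,
                                     Vmax=human_params.Vmax * 24)
        rescaled = loglik(daily, df_days, None, res)
        assert rescaled == pytest.approx(base, rel=1e-6)


class TestFitPK:
    def test_noise_free_self_consistency(self, human_params):
        """A rich noise-free dataset is recovered to within 0.1%."""
        times = [0.5, 2, 8, 24, 72, 168, 336, 504, 756, 1007]
        df = _make_dataset(human_params, [30.0, 100.0, 360.0, 1000.0], times)
        result = fit_pk(df, human_params, method="pooled", rse_method="none",
                        estimate_sigma=False, weight_scaling=False)
        for name in ("CL", "V1", "Q", "V2", "Vmax", "Km"):
            assert result.estimates[name] == pytest.approx(
                getattr(human_params, name), rel=1e-3), name

    def test_linear_limit_ratio_identifiable(self, human_params):
        """With all concentrations far below Km only Vmax/Km is identified;
        the fitted ratio returns to the truth from a distorted start."""
        times = [1.0, 8, 24, 72, 168, 336, 504, 756]
        low = _make_dataset(human_params, [0.02, 0.05], times, noise=0.02, seed=5)
        start = human_params.replace(Vmax=human_params.Vmax * 5,
                                     Km=human_params.Km * 2)
        result = fit_pk(low, start, estimate=("Vmax", "Km"), method="pooled",
                        rse_method="none", estimate_sigma=False,
                        weight_scaling=False)
        truth_ratio = human_params.Vmax / human_params.Km
        fitted_ratio = result.estimates["Vmax"] / result.estimates["Km"]
        assert fitted_ratio == pytest.approx(truth_ratio, rel=0.10)

    def test_sandwich_rse_reported(self, human_params):
        times = [1.0, 8, 24, 96, 336, 756]
        df = _make_dataset(human_params, [100.0, 360.0], times, noise=0.1, seed=6)
        result = fit_pk(df, human_params, estimate=("CL", "V1"), method="pooled",
                        rse_method="sandwich", weight_scaling=False)
        assert set(result.rse_percent) == {"CL", "V1"}
        assert all(v > 0 for v in result.rse_percent.values())

    def test_objective_not_worse_than_start(self, human_params):
        times = [1.0, 8, 24, 96, 336]
        df = _make_dataset(human_params, [100.0, 360.0], times, noise=0.15, seed=7)
        start = human_params.replace(CL=human_params.CL * 1.5)
        sigma = ResidualSpec(0.15, 0.0)
        result = fit_pk(df, start, estimate=("CL", "V1"), method="pooled",
                        residual_init=sigma, rse_method="none",
                        estimate_sigma=False, weight_scaling=False)
        initial = loglik(start, df, None, sigma)
        assert result.objective <= initial + 1e-6

    def test_sklearn_estimator_protocol(self, human_params):
        est = PopPKEstimator(init=human_params, estimate=("CL", "V1"),
                             rse_method="none", weight_scaling=False)
        assert est.get_params()["estimate"] == ("CL", "V1")
        cloned = clone(est)
        times = [1.0, 24.0, 168.0, 504.0]
        df = _make_dataset(human_params, [360.0], times, noise=0.05, seed=8)
        cloned.fit(df)
        assert hasattr(cloned, "params_")
        preds = cloned.predict(df)
        assert len(preds) == (df.EVID == 0).sum()
        assert np.all(preds >= 0)


class TestFitPD:
    def test_vehicle_only_recovers_growth_parameters(self, mouse_params,
                                                     tumor_params):
        """Noise-free vehicle data pins Base, K_G and lam to within 1%;
        drug-effect parameters stay at their initial values."""
        from pkpdkit.population import OmegaSpec, ResidualSpec
        from pkpdkit.synthetic_data import XenograftRules

        zero_omega = OmegaSpec({"Base": 0, "K_G": 0, "K_D": 0})
        data = generate_xenograft_study(
            tumor_params, mouse_params, zero_omega, ResidualSpec(1e-9, 0.0),
            XenograftRules(baseline_range=None), 11, arms=(0.0,), n_per_arm=3)
        start = tumor_params.replace(Base=150.0, K_G=0.25, lam=0.3)
        result = fit_pd(data, mouse_params, start,
                        estimate=("Base", "K_G", "lam"), rse_method="none",
                        estimate_sigma=False)
        assert result.estimates["Base"] == pytest.approx(177.0, rel=0.01)
        assert result.estimates["K_G"] == pytest.approx(0.338, rel=0.01)
        assert result.estimates["lam"] == pytest.approx(0.172, rel=0.01)
        assert result.params.EC50 == start.EC50  # untouched at init

    def test_missing_vehicle_arm_warns(self, mouse_params, tumor_params):
        from pkpdkit.population import OmegaSpec, ResidualSpec
        from pkpdkit.synthetic_data import XenograftRules

        zero_omega = OmegaSpec({"Base": 0, "K_G": 0, "K_D": 0})
        data = generate_xenograft_study(
            tumor_params, mouse_params, zero_omega, ResidualSpec(0.05, 0.0),
            XenograftRules(baseline_range=None), 12, arms=(25.0,), n_per_arm=2)
        with pytest.warns(UserWarning, match="vehicle"):
            fit_pd(data, mouse_params, tumor_params, estimate=("Base",),
                   rse_method="none", estimate_sigma=False)

    def test_progression_term_detected_by_likelihood_ratio(self, mouse_params,
                                                           tumor_params):
        """Data simulated with the progression factor: freeing lam drops the
        objective by more than the 6.63 significance threshold in nearly all
        replicates (pooled-compatible generator settings: no between-subject
        variability, published residual noise)."""
        from pkpdkit.population import OmegaSpec, ResidualSpec
        from pkpdkit.synthetic_data import XenograftRules

        rules = XenograftRules(baseline_range=None)
        zero_omega = OmegaSpec({"Base": 0, "K_G": 0, "K_D": 0})
        wins = 0
        n_rep = 6
        for i in range(n_rep):
            data = generate_xenograft_study(
                tumor_params, mouse_params, zero_omega,
                ResidualSpec(0.256, 0.0), rules, 100 + i)
            no_lam = tumor_params.replace(lam=1e-12)
            reduced = fit_pd(data, mouse_params, no_lam,
                             estimate=("Base", "K_G", "K_D", "EC50"),
                             rse_method="none")
            full = fit_pd(data, mouse_params, tumor_params,
                          estimate=("Base", "K_G", "K_D", "EC50", "lam"),
                          rse_method="none")
            decision = compare_models(reduced, full, 1)
            wins += decision["significant"]
        assert wins >= n_rep - 1


class TestCompareModels:
    def _fit(self, objective, names):
        from pkpdkit.estimation import FitResult

        return FitResult(estimates={}, params=None, objective=objective,
                         convergence="converged", free_names=names)

    def test_threshold_at_df1(self):
        reduced = self._fit(106.64, ("CL",))
        full = self._fit(100.0, ("CL", "V1"))
        assert compare_models(reduced, full, 1)["significant"]

    def test_zero_delta_not_significant(self):
        reduced = self._fit(100.0, ("CL",))
        full = self._fit(100.0, ("CL", "V1"))
        assert not compare_models(reduced, full, 1)["significant"]

    def test_df2_threshold_is_chi2_quantile(self):
        result = compare_models(self._fit(100.0, ("CL",)),
                                self._fit(95.0, ("CL", "V1", "Q")), 2)
        assert result["threshold"] == pytest.approx(9.21, abs=0.005)

    def test_non_nested_fits_refused(self):
        with pytest.raises(ValueError):
            compare_models(self._fit(1.0, ("CL", "Q")), self._fit(0.0, ("CL", "V1")), 1)
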