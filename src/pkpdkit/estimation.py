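"""Maximum-likelihood estimation of the PK and tumor-growth models.

Fits the structural models to long-format study data with a hierarchical
(nonlinear mixed-effects) likelihood.  The marginal likelihood over the
per-subject lognormal random effects is approximated by the Laplace
method — the mode of each subject's joint density is located and the
curvature at the mode supplies the Gaussian correction — which is the
standard approximation family that conditional-estimation methods in
pharmacometric software belong to.  A naive-pooled mode (random effects
pinned at zero, no prior term) is available as a fast fallback and is the
workhorse of the simulation-based parameter-recovery checks.

Estimators follow the scikit-learn protocol: construct with
hyperparameters, ``fit(X)`` on a long-format DataFrame, inspect fitted
``*_`` attributes, ``get_params``/``set_params`` for composition with
model selection utilities.  The module-level :func:`fit_pk`,
:func:`fit_pd`, :func:`loglik` and :func:`compare_models` are thin
wrappers over them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .pk_model import AllometricRule, DoseEvent, PKParameters, Regimen, scale_params, simulate
from .population import OmegaSpec, ResidualSpec
from .tumor_pd import PDParameters, simulate_tumor

__all__ = [
    "FitResult",
    "ObservationRecord",
    "EstimationError",
    "PopPKEstimator",
    "TumorGrowthEstimator",
    "loglik",
    "fit_pk",
    "fit_pd",
    "compare_models",
]

#: fixed additive SD (mg/L) folded into the variance of LLOQ-imputed points
BLQ_ADDITIVE_SD = 0.039

_PK_NAMES = ("CL", "V1", "Q", "V2", "Vmax", "Km")
_PD_NAMES = ("Base", "K_G", "K_D", "K_io", "EC50", "EC50_KD", "lam")


class EstimationError(RuntimeError):
    """Raised when a likelihood evaluation is impossible for a dataset."""


@dataclass(frozen=True)
class ObservationRecord:
    """One observation row after parsing (plumbing for diagnostics)."""

    subject: int
    time: float
    value: float
    kind: str  # "concentration" | "tumor"
    blq: bool = False


@dataclass
class FitResult:
    """Outcome of a model fit.

    ``estimates`` maps every free parameter (structural, variability,
    residual) to its estimate; ``params`` is the fitted structural
    parameter object; ``objective`` the final -2 log-likelihood;
    ``rse_percent`` per-parameter relative standard errors (empty when not
    requested or not available); ``eta_shrinkage`` per-random-effect
    shrinkage (Laplace fits only).
    """

    estimates: dict[str, float]
    params: object
    objective: float
    convergence: str
    free_names: tuple[str, ...]
    rse_percent: dict[str, float] = field(default_factory=dict)
    eta_shrinkage: dict[str, float] = field(default_factory=dict)
    n_obs: int = 0
    n_subjects: int = 0
    omega: OmegaSpec | None = None
    residual: ResidualSpec | None = None

    def __post_init__(self) -> None:
        if self.convergence == "converged" and not np.isfinite(self.objective):
            raise ValueError("objective must be finite on success")


@dataclass(frozen=True)
class _Subject:
    sid: int
    regimen: Regimen
    times: np.ndarray
    y: np.ndarray
    blq: np.ndarray
    weight: float | None


# ---------------------------------------------------------------------------
# fast fixed-step-free integrators for the fitting hot path (odeint has far
# less per-call overhead than solve_ivp; accuracy is set by rtol/atol)

def _pk_conc_fast(p: PKParameters, regimen: Regimen, times: np.ndarray,
                  rtol: float, atol: float) -> np.ndarray:
    from scipy.integrate import ODEintWarning, odeint

    def rhs(y, t):
        a1, a2 = y
        c = a1 / p.V1 if a1 > 0 else 0.0
        mm = p.Vmax * c / (p.Km + c)
        return (-(p.CL / p.V1) * a1 - mm - (p.Q / p.V1) * a1 + (p.Q / p.V2) * a2,
                (p.Q / p.V1) * a1 - (p.Q / p.V2) * a2)

    horizon = max(times[-1] if len(times) else 0.0, regimen.last_dose_time)
    breakpoints = sorted({e.time for e in regimen.events if e.time <= horizon} | {horizon})
    state = np.zeros(2)
    out = np.empty(len(times))
    if len(times):
        out[times == 0.0] = 0.0  # pre-dose state at t=0
    t_cur = 0.0
    for i, t_next in enumerate(breakpoints):
        if t_next > t_cur:
            last = i == len(breakpoints) - 1
            mask = (times >= t_cur) & ((times <= t_next) if last else (times < t_next))
            t_eval = np.concatenate([[t_cur], times[mask], [t_next]])
            with warnings.catch_warnings():
                # extreme trial parameters can exhaust the solver; the
                # resulting poor fit is rejected by the objective itself
                warnings.simplefilter("ignore", ODEintWarning)
                sol = odeint(rhs, state, t_eval, rtol=rtol, atol=atol, mxstep=500000)
            if mask.any():
                out[mask] = sol[1:-1, 0] / p.V1
            state = sol[-1]
        t_cur = t_next
        for e in regimen.events:
            if e.time == t_next:
                state[0] += e.amount
                at = times == t_next
                if at.any():
                    out[at] = state[0] / p.V1
    return np.maximum(out, 0.0)


def _tumor_vol_fast(pd_params: PDParameters, pk: PKParameters, regimen: Regimen,
                    times: np.ndarray, rtol: float, atol: float) -> np.ndarray:
    from scipy.integrate import ODEintWarning, odeint

    lam_h = pd_params.lam_per_hour

    def rhs(y, t):
        a1, a2, i_state, vol = y
        c = a1 / pk.V1 if a1 > 0 else 0.0
        mm = pk.Vmax * c / (pk.Km + c)
        da1 = -(pk.CL / pk.V1) * a1 - mm - (pk.Q / pk.V1) * a1 + (pk.Q / pk.V2) * a2
        da2 = (pk.Q / pk.V1) * a1 - (pk.Q / pk.V2) * a2
        di = pd_params.K_io * (1.0 - pd_params.Emax_g * c / (pd_params.EC50 + c)) \
            - pd_params.K_io * i_state
        kill = pd_params.K_D * pd_params.Emax_d * c / (pd_params.EC50_KD + c)
        dv = pd_params.K_G * (1.0 + lam_h * t) * i_state - kill * vol
        return (da1, da2, di, dv)

    horizon = max(times[-1] if len(times) else 0.0, regimen.last_dose_time)
    breakpoints = sorted({e.time for e in regimen.events if e.time <= horizon} | {horizon})
    state = np.array([0.0, 0.0, 1.0, pd_params.Base])
    out = np.empty(len(times))
    if len(times):
        out[times == 0.0] = pd_params.Base  # pre-dose state at t=0
    t_cur = 0.0
    for i, t_next in enumerate(breakpoints):
        if t_next > t_cur:
            last = i == len(breakpoints) - 1
            mask = (times >= t_cur) & ((times <= t_next) if last else (times < t_next))
            t_eval = np.concatenate([[t_cur], times[mask], [t_next]])
            with warnings.catch_warnings():
                # extreme trial parameters can exhaust the solver; the
                # resulting poor fit is rejected by the objective itself
                warnings.simplefilter("ignore", ODEintWarning)
                sol = odeint(rhs, state, t_eval, rtol=rtol, atol=atol, mxstep=500000)
            if mask.any():
                out[mask] = sol[1:-1, 3]
            state = sol[-1]
        t_cur = t_next
        for e in regimen.events:
            if e.time == t_next:
                state[0] += e.amount
                at = times == t_next
                if at.any():
                    out[at] = state[3]
    return np.maximum(out, 0.0)


def _parse_subjects(dataset: pd.DataFrame, kind: str) -> list[_Subject]:
    required = {"ID", "TIME", "AMT", "DV", "EVID"}
    missing = required - set(dataset.columns)
    if missing:
        raise EstimationError(f"dataset lacks required columns: {sorted(missing)}")
    mdv = dataset["MDV"] if "MDV" in dataset.columns else pd.Series(0, index=dataset.index)
    blq_col = dataset["BLQ"] if "BLQ" in dataset.columns else pd.Series(0, index=dataset.index)
    subjects = []
    for sid, group in dataset.groupby("ID", sort=True):
        doses = group[group["EVID"] == 1]
        # route is irrelevant at unit bioavailability; doses are boluses
        events = tuple(DoseEvent(float(r.TIME), float(r.AMT)) for r in doses.itertuples())
        obs_mask = (group["EVID"] == 0) & (mdv.loc[group.index] == 0)
        obs = group[obs_mask].sort_values("TIME", kind="stable")
        if len(obs) == 0:
            raise EstimationError(f"subject {sid} has no usable observations")
        weight = None
        if "WT" in group.columns:
            w = group["WT"].dropna()
            if len(w):
                weight = float(w.iloc[0])
        subjects.append(
            _Subject(
                sid=int(sid),
                regimen=Regimen(events, cycle_length=504.0),
                times=obs["TIME"].to_numpy(dtype=float),
                y=obs["DV"].to_numpy(dtype=float),
                blq=blq_col.loc[obs.index].to_numpy(dtype=float).astype(bool),
                weight=weight,
            )
        )
    return subjects


def _obs_variance(pred: np.ndarray, blq: np.ndarray, residual: ResidualSpec) -> np.ndarray:
    var = (residual.proportional_sd * pred) ** 2 + residual.additive_sd**2
    if blq.any():
        add_blq = max(residual.additive_sd, BLQ_ADDITIVE_SD)
        var = np.where(blq, (residual.proportional_sd * pred) ** 2 + add_blq**2, var)
    return var


def _gaussian_neg2ll(y: np.ndarray, pred: np.ndarray, var: np.ndarray) -> float:
    if np.any(var <= 0) or not np.all(np.isfinite(var)):
        return np.inf
    return float(np.sum(np.log(2.0 * np.pi * var) + (y - pred) ** 2 / var))


class _PKLikelihood:
    """Per-subject predictions and conditional -2LL for the PK model."""

    def __init__(self, subjects: Sequence[_Subject], residual: ResidualSpec,
                 rule: AllometricRule | None, rtol: float, atol: float,
                 integrator: str = "fast"):
        self.subjects = subjects
        self.residual = residual
        self.rule = rule
        self.rtol = rtol
        self.atol = atol
        self.integrator = integrator

    def individual_params(self, anchor: PKParameters, subject: _Subject,
                          eta: Mapping[str, float]) -> PKParameters:
        params = anchor
        if self.rule is not None and subject.weight is not None:
            params = scale_params(anchor, self.rule, subject.weight)
        if eta:
            params = params.replace(
                **{k: getattr(params, k) * math.exp(v) for k, v in eta.items()}
            )
        return params

    def predict(self, anchor: PKParameters, subject: _Subject,
                eta: Mapping[str, float]) -> np.ndarray:
        params = self.individual_params(anchor, subject, eta)
        unique, inverse = np.unique(subject.times, return_inverse=True)
        if self.integrator == "fast":
            conc = _pk_conc_fast(params, subject.regimen, unique,
                                 self.rtol, self.atol)
        else:
            conc = simulate(params, subject.regimen, unique,
                            rtol=self.rtol, atol=self.atol).concentrations
        return conc[inverse]

    def conditional_neg2ll(self, anchor: PKParameters, subject: _Subject,
                           eta: Mapping[str, float], residual: ResidualSpec) -> float:
        pred = self.predict(anchor, subject, eta)
        if not np.all(np.isfinite(pred)):
            t_bad = subject.times[~np.isfinite(pred)][0]
            raise EstimationError(
                f"non-finite prediction for subject {subject.sid} at t={t_bad:g} h"
            )
        return _gaussian_neg2ll(subject.y, pred, _obs_variance(pred, subject.blq, residual))


class _PDLikelihood:
    """Per-subject predictions for the tumor model, cached per regimen."""

    def __init__(self, subjects: Sequence[_Subject], residual: ResidualSpec,
                 mouse_pk: PKParameters, rtol: float, atol: float,
                 integrator: str = "fast"):
        self.subjects = subjects
        self.residual = residual
        self.mouse_pk = mouse_pk
        self.rtol = rtol
        self.atol = atol
        self.integrator = integrator
        # mice sharing a regimen and obs-grid-union can share one simulation
        self._grid: dict[tuple, np.ndarray] = {}
        for s in subjects:
            key = self._regimen_key(s.regimen)
            grid = self._grid.get(key, np.array([]))
            self._grid[key] = np.union1d(grid, np.union1d(s.times, [0.0]))

    @staticmethod
    def _regimen_key(regimen: Regimen) -> tuple:
        return tuple((e.time, e.amount) for e in regimen.events)

    def predict(self, pd_params: PDParameters, subject: _Subject,
                eta: Mapping[str, float], cache: dict | None = None) -> np.ndarray:
        params = pd_params
        if eta:
            params = params.replace(
                **{k: getattr(params, k) * math.exp(v) for k, v in eta.items()}
            )
        key = (self._regimen_key(subject.regimen), tuple(sorted(eta.items())))
        if cache is not None and not eta and key in cache:
            grid, vols = cache[key]
        else:
            grid = self._grid[self._regimen_key(subject.regimen)]
            if self.integrator == "fast":
                vols = _tumor_vol_fast(params, self.mouse_pk, subject.regimen, grid,
                                       self.rtol, self.atol)
            else:
                course = simulate_tumor(params, self.mouse_pk, subject.regimen, grid,
                                        rtol=self.rtol, atol=self.atol)
                vols = course.volume
            if cache is not None and not eta:
                cache[key] = (grid, vols)
        return np.interp(subject.times, grid, vols)

    def conditional_neg2ll(self, pd_params: PDParameters, subject: _Subject,
                           eta: Mapping[str, float], residual: ResidualSpec,
                           cache: dict | None = None) -> float:
        pred = self.predict(pd_params, subject, eta, cache)
        if not np.all(np.isfinite(pred)):
            t_bad = subject.times[~np.isfinite(pred)][0]
            raise EstimationError(
                f"non-finite prediction for subject {subject.sid} at t={t_bad:g} h"
            )
        return _gaussian_neg2ll(subject.y, pred, _obs_variance(pred, subject.blq, residual))


def _laplace_subject(cond_fn, omega: OmegaSpec, d_names: tuple[str, ...]) -> float:
    """-2 ln of the Laplace-approximated marginal likelihood for one subject.

    ``cond_fn(eta_vec)`` returns the conditional -2LL at the random-effect
    vector.  The joint exponent h(eta) adds the lognormal prior; the
    approximation is h(eta_hat) + ln det H - d ln 2pi with H the Hessian
    of h/2 at the mode.
    """
    sds = np.array([omega.sd(n) for n in d_names])
    if np.any(sds <= 0):
        raise EstimationError("Laplace approximation requires positive omega for "
                              "every random effect; drop zero-CV effects instead")

    def h(eta: np.ndarray) -> float:
        prior = np.sum(np.log(2.0 * np.pi * sds**2) + (eta / sds) ** 2)
        return cond_fn(eta) + prior

    d = len(d_names)
    res = optimize.minimize(h, np.zeros(d), method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 200})
    eta_hat = res.x
    # central-difference Hessian of h/2
    step = 1e-4
    hess = np.zeros((d, d))
    f0 = h(eta_hat)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = step
            ej = np.zeros(d); ej[j] = step
            if i == j:
                hess[i, i] = (h(eta_hat + ei) - 2 * f0 + h(eta_hat - ei)) / step**2 / 2
            else:
                val = (h(eta_hat + ei + ej) - h(eta_hat + ei - ej)
                       - h(eta_hat - ei + ej) + h(eta_hat - ei - ej)) / (4 * step**2) / 2
                hess[i, j] = hess[j, i] = val
    sign, logdet = np.linalg.slogdet(hess)
    if sign <= 0:
        # non-positive curvature at the located mode: fall back to the prior
        # curvature, which upper-bounds the integral's spread
        logdet = float(np.sum(np.log(1.0 / sds**2)))
    return f0 + logdet - d * math.log(2.0 * math.pi), eta_hat


def loglik(
    params,
    dataset: pd.DataFrame,
    omega: OmegaSpec | None,
    residual: ResidualSpec,
    *,
    kind: str = "concentration",
    method: str = "laplace",
    mouse_pk: PKParameters | None = None,
    rule: AllometricRule | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """-2 log-likelihood of a parameter set for a long-format dataset.

    With ``omega`` absent or all-zero (or ``method="pooled"``) this is the
    exact Gaussian -2LL at zero random effects; otherwise the marginal
    likelihood over the per-subject random effects is approximated by the
    Laplace method.
    """
    subjects = _parse_subjects(dataset, kind)
    if kind == "concentration":
        lik = _PKLikelihood(subjects, residual, rule, rtol, atol, integrator="accurate")
        cond = lambda s, eta: lik.conditional_neg2ll(params, s, eta, residual)
    elif kind == "tumor":
        if mouse_pk is None:
            raise ValueError("mouse_pk is required for tumor datasets")
        lik = _PDLikelihood(subjects, residual, mouse_pk, rtol, atol, integrator="accurate")
        cache: dict = {}
        cond = lambda s, eta: lik.conditional_neg2ll(params, s, eta, residual, cache)
    else:
        raise ValueError("kind must be 'concentration' or 'tumor'")

    pooled = omega is None or omega.is_zero() or method == "pooled"
    total = 0.0
    for s in subjects:
        if pooled:
            total += cond(s, {})
        else:
            names = omega.names
            value, _ = _laplace_subject(
                lambda eta: cond(s, dict(zip(names, eta))), omega, names
            )
            total += value
    return total


def _finite_diff_cov(objective, x0: np.ndarray, per_subject, n_free: int,
                     step: float = 1e-4):
    """Sandwich covariance of the log-parameter vector.

    ``objective`` is the total -2LL as a function of the log-parameter
    vector; ``per_subject(x)`` returns the vector of per-subject -2LL
    contributions.  A = Hessian(-LL), B = sum of per-subject score outer
    products; cov = A^-1 B A^-1.
    """
    d = len(x0)
    hess = np.zeros((d, d))
    f0 = objective(x0)
    for i in range(d):
        ei = np.zeros(d); ei[i] = step
        for j in range(i, d):
            ej = np.zeros(d); ej[j] = step
            if i == j:
                hess[i, i] = (objective(x0 + ei) - 2 * f0 + objective(x0 - ei)) / step**2
            else:
                hess[i, j] = hess[j, i] = (
                    objective(x0 + ei + ej) - objective(x0 + ei - ej)
                    - objective(x0 - ei + ej) + objective(x0 - ei - ej)
                ) / (4 * step**2)
    a_mat = hess / 2.0  # Hessian of -LL
    scores = []
    base = per_subject(x0)
    n_subj = len(base)
    grad = np.zeros((n_subj, d))
    for i in range(d):
        ei = np.zeros(d); ei[i] = step
        grad[:, i] = (per_subject(x0 + ei) - per_subject(x0 - ei)) / (2 * step) / 2.0
    b_mat = grad.T @ grad
    try:
        a_inv = np.linalg.inv(a_mat)
        cov = a_inv @ b_mat @ a_inv
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
        return None
    return cov


class _BaseMLEstimator(BaseEstimator):
    """Shared machinery: log-parameter optimization, RSEs, result assembly."""

    #: half-width of the log-parameter search box around the initial values
    _LOG_BOX = 12.0
    #: outer reweighting iterations of the GLS stage
    _IRLS_ITERS = 4

    def _optimize(self, objective, predict_stack, y_all, blq_all, residual,
                  x0: np.ndarray, rng: np.random.Generator):
        """Minimize the objective over log-parameters.

        The workhorse is iteratively reweighted least squares: each outer
        round freezes the observation weights at the current predictions
        (so the weights carry no incentive to inflate the predictions) and
        solves the weighted nonlinear least-squares problem with a
        trust-region Gauss-Newton method.  An optional quasi-Newton polish
        on the exact -2 log-likelihood follows (``polish=True``).
        Multi-start jitter guards against local minima; the search is
        boxed around the initial values in log space, which keeps the
        exploration inside the floating-point range without binding at any
        plausible optimum.
        """
        from types import SimpleNamespace

        lower, upper = x0 - self._LOG_BOX, x0 + self._LOG_BOX
        best = None
        starts = [x0]
        for _ in range(self.n_starts - 1):
            starts.append(x0 + rng.normal(0.0, self.jitter, size=len(x0)))
        for start in starts:
            x_start = np.clip(start, lower, upper)
            ls_ok = False
            if predict_stack is not None:
                try:
                    x_start, ls_ok = self._irls(predict_stack, y_all, blq_all,
                                                residual, x_start, lower, upper)
                except (EstimationError, ValueError, OverflowError):
                    pass
            if self.polish or not ls_ok:
                res = optimize.minimize(
                    objective, x_start, method="L-BFGS-B",
                    bounds=list(zip(lower, upper)),
                    options={"maxiter": self.maxiter, "ftol": 1e-12, "gtol": 1e-8},
                )
            else:
                res = SimpleNamespace(x=x_start, fun=objective(x_start),
                                      success=True, message="irls")
            if best is None or res.fun < best.fun:
                best = res
        status = "converged" if np.isfinite(best.fun) else "failed"
        if not best.success and status == "converged":
            status = "max_iterations" if "ITERATIONS" in str(best.message).upper() else "converged"
        return best, status

    def _irls(self, predict_stack, y_all, blq_all, residual, x0, lower, upper):
        """Iteratively reweighted GLS with weights frozen per outer round."""
        x = x0
        ok = False
        for _ in range(self._IRLS_ITERS):
            pred = predict_stack(x)
            sd = np.sqrt(_obs_variance(pred, blq_all, residual))
            sd = np.maximum(sd, 1e-12)

            def rfun(z, sd=sd):
                return (y_all - predict_stack(z)) / sd

            ls = optimize.least_squares(
                rfun, x, method="trf", bounds=(lower, upper),
                xtol=1e-9, ftol=1e-9, gtol=1e-8, max_nfev=self.maxiter * 4,
            )
            ok = ls.status > 0
            if np.allclose(ls.x, x, rtol=1e-7, atol=1e-9):
                x = ls.x
                break
            x = ls.x
        return x, ok


class PopPKEstimator(_BaseMLEstimator):
    """Population PK model estimator (two-compartment, parallel clearances).

    Parameters
    ----------
    init : PKParameters or None
        Initial structural values at the anchor weight (published typical
        values by default).
    estimate : tuple of str
        Structural parameters to estimate (subset of CL, V1, Q, V2, Vmax,
        Km); the rest stay fixed at their initial values.
    omega : OmegaSpec or None
        Between-subject variability; ``None`` fits a naive-pooled model.
    residual : ResidualSpec or None
        Residual error model (published PK error by default).
    estimate_sigma : bool
        Profile the proportional residual SD after the structural fit.
    method : {"laplace", "pooled"}
        Marginal-likelihood approximation.
    weight_scaling : bool
        Scale the anchor to each subject's body weight allometrically
        (requires a WT column), estimating at the anchor weight.
    rse_method : {"sandwich", "none"}
        Standard errors via the sandwich estimator, or skip.
    n_starts, jitter, seed
        Multi-start control for the optimizer (log-space jitter SD).
    """

    def __init__(self, init: PKParameters | None = None,
                 estimate: tuple[str, ...] = ("CL", "V1", "Q", "V2", "Vmax", "Km"),
                 omega: OmegaSpec | None = None,
                 residual: ResidualSpec | None = None,
                 estimate_sigma: bool = True,
                 method: str = "pooled",
                 weight_scaling: bool = True,
                 anchor_weight: float = 70.0,
                 rse_method: str = "sandwich",
                 n_starts: int = 1, jitter: float = 0.2, seed: int = 0,
                 maxiter: int = 200, polish: bool = False,
                 rtol: float = 1e-6, atol: float = 1e-9):
        self.init = init
        self.estimate = estimate
        self.omega = omega
        self.residual = residual
        self.estimate_sigma = estimate_sigma
        self.method = method
        self.weight_scaling = weight_scaling
        self.anchor_weight = anchor_weight
        self.rse_method = rse_method
        self.n_starts = n_starts
        self.jitter = jitter
        self.seed = seed
        self.maxiter = maxiter
        self.polish = polish
        self.rtol = rtol
        self.atol = atol

    # -- scikit-learn API -------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "PopPKEstimator":
        from .pk_model import human_default_params

        init = self.init or human_default_params()
        residual = self.residual or ResidualSpec(0.108, 0.039)
        free = tuple(self.estimate)
        unknown = set(free) - set(_PK_NAMES)
        if unknown:
            raise ValueError(f"unknown PK parameters: {sorted(unknown)}")
        subjects = _parse_subjects(X, "concentration")
        dose_levels = {round(s.regimen.total_dose / (s.weight or 1.0), 6) for s in subjects}
        if {"Km", "Vmax"} & set(free) and len(dose_levels) < 2:
            warnings.warn("a single dose level gives no saturation contrast; "
                          "Vmax and Km are only jointly identifiable", stacklevel=2)
        rule = AllometricRule(reference_weight=self.anchor_weight) if self.weight_scaling else None
        lik = _PKLikelihood(subjects, residual, rule, self.rtol, self.atol)
        rng = np.random.default_rng(self.seed)

        def unpack(x: np.ndarray) -> PKParameters:
            values = init.as_dict()
            for name, xi in zip(free, x):
                values[name] = math.exp(xi)
            values.pop("body_weight")
            return PKParameters(**values, body_weight=self.anchor_weight)

        use_laplace = (self.method == "laplace" and self.omega is not None
                       and not self.omega.is_zero())

        def per_subject(x: np.ndarray) -> np.ndarray:
            anchor = unpack(x)
            out = np.empty(len(subjects))
            for i, s in enumerate(subjects):
                if use_laplace:
                    names = self.omega.names
                    out[i], _ = _laplace_subject(
                        lambda eta: lik.conditional_neg2ll(
                            anchor, s, dict(zip(names, eta)), residual),
                        self.omega, names)
                else:
                    out[i] = lik.conditional_neg2ll(anchor, s, {}, residual)
            return out

        def objective(x: np.ndarray) -> float:
            try:
                return float(np.sum(per_subject(x)))
            except (EstimationError, ValueError, OverflowError):
                return np.inf

        def predict_stack(x: np.ndarray) -> np.ndarray:
            anchor = unpack(x)
            return np.concatenate([lik.predict(anchor, s, {}) for s in subjects])

        y_all = np.concatenate([s.y for s in subjects])
        blq_all = np.concatenate([s.blq for s in subjects])
        x0 = np.array([math.log(getattr(init, n)) for n in free])
        best, status = self._optimize(objective, None if use_laplace else predict_stack,
                                      y_all, blq_all, residual, x0, rng)
        anchor = unpack(best.x)
        estimates = {n: getattr(anchor, n) for n in free}

        sigma = residual
        if use_laplace:
            objective_value = float(best.fun)
        else:
            if self.estimate_sigma:
                sigma = self._profile_sigma(lik, anchor, subjects, residual)
                estimates["proportional_sd"] = sigma.proportional_sd
            objective_value = float(sum(
                lik.conditional_neg2ll(anchor, s, {}, sigma) for s in subjects
            ))

        rse: dict[str, float] = {}
        if self.rse_method == "sandwich":
            cov = _finite_diff_cov(objective, best.x, per_subject, len(free))
            if cov is not None:
                # log-scale SE approximates the CV of the estimate
                rse = {n: 100.0 * math.sqrt(cov[i, i]) for i, n in enumerate(free)}

        shrinkage: dict[str, float] = {}
        if use_laplace:
            etas = {n: [] for n in self.omega.names}
            for s in subjects:
                names = self.omega.names
                _, eta_hat = _laplace_subject(
                    lambda eta: lik.conditional_neg2ll(
                        anchor, s, dict(zip(names, eta)), residual),
                    self.omega, names)
                for n, v in zip(names, eta_hat):
                    etas[n].append(v)
            for n, vals in etas.items():
                shrinkage[n] = 100.0 * (1.0 - np.std(vals) / self.omega.sd(n))

        self.result_ = FitResult(
            estimates=estimates, params=anchor, objective=objective_value,
            convergence=status, free_names=free, rse_percent=rse,
            eta_shrinkage=shrinkage,
            n_obs=int(sum(len(s.y) for s in subjects)), n_subjects=len(subjects),
            omega=self.omega, residual=sigma,
        )
        self.params_ = anchor
        self.objective_ = objective_value
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _profile_sigma(lik: _PKLikelihood, anchor: PKParameters,
                       subjects: Sequence[_Subject], residual: ResidualSpec) -> ResidualSpec:
        """Profile the proportional SD at fixed structural parameters."""
        preds = [lik.predict(anchor, s, {}) for s in subjects]

        def neg2ll(log_sd: float) -> float:
            trial = ResidualSpec(math.exp(log_sd), residual.additive_sd)
            return sum(
                _gaussian_neg2ll(s.y, p, _obs_variance(p, s.blq, trial))
                for s, p in zip(subjects, preds)
            )

        res = optimize.minimize_scalar(neg2ll, bounds=(math.log(1e-4), math.log(2.0)),
                                       method="bounded")
        return ResidualSpec(math.exp(res.x), residual.additive_sd)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Typical (zero random effect) predictions for observation rows."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "params_")
        residual = self.residual or ResidualSpec(0.108, 0.039)
        rule = AllometricRule(reference_weight=self.anchor_weight) if self.weight_scaling else None
        subjects = _parse_subjects(X, "concentration")
        lik = _PKLikelihood(subjects, residual, rule, self.rtol, self.atol)
        return np.concatenate([lik.predict(self.params_, s, {}) for s in subjects])


class TumorGrowthEstimator(_BaseMLEstimator):
    """Tumor-growth-inhibition model estimator for xenograft studies.

    The mouse PK parameters are fixed (no PK sampling in the efficacy
    study); the tumor parameters listed in ``estimate`` are fitted by
    maximum likelihood with a proportional residual error.  A missing
    vehicle arm triggers a warning, since the growth parameters are then
    weakly identified.
    """

    def __init__(self, mouse_pk: PKParameters | None = None,
                 init: PDParameters | None = None,
                 estimate: tuple[str, ...] = ("Base", "K_G", "K_D", "K_io", "EC50", "lam"),
                 omega: OmegaSpec | None = None,
                 residual: ResidualSpec | None = None,
                 estimate_sigma: bool = True,
                 method: str = "pooled",
                 rse_method: str = "none",
                 n_starts: int = 1, jitter: float = 0.2, seed: int = 0,
                 maxiter: int = 200, polish: bool = False,
                 rtol: float = 1e-6, atol: float = 1e-8):
        self.mouse_pk = mouse_pk
        self.init = init
        self.estimate = estimate
        self.omega = omega
        self.residual = residual
        self.estimate_sigma = estimate_sigma
        self.method = method
        self.rse_method = rse_method
        self.n_starts = n_starts
        self.jitter = jitter
        self.seed = seed
        self.maxiter = maxiter
        self.polish = polish
        self.rtol = rtol
        self.atol = atol

    def fit(self, X: pd.DataFrame, y=None) -> "TumorGrowthEstimator":
        from .pk_model import mouse_default_params
        from .tumor_pd import pd_default_params

        mouse_pk = self.mouse_pk or mouse_default_params()
        init = self.init or pd_default_params()
        residual = self.residual or ResidualSpec(0.256, 0.0)
        free = tuple(self.estimate)
        unknown = set(free) - set(_PD_NAMES)
        if unknown:
            raise ValueError(f"unknown PD parameters: {sorted(unknown)}")
        subjects = _parse_subjects(X, "tumor")
        if not any(s.regimen.total_dose == 0 for s in subjects):
            warnings.warn("no vehicle arm in the dataset; growth parameters are "
                          "weakly identified", stacklevel=2)
        lik = _PDLikelihood(subjects, residual, mouse_pk, self.rtol, self.atol)
        rng = np.random.default_rng(self.seed)

        def unpack(x: np.ndarray) -> PDParameters:
            values = init.as_dict()
            for name, xi in zip(free, x):
                values[name] = math.exp(xi)
            return PDParameters(**values)

        def per_subject(x: np.ndarray) -> np.ndarray:
            params = unpack(x)
            cache: dict = {}
            out = np.empty(len(subjects))
            for i, s in enumerate(subjects):
                out[i] = lik.conditional_neg2ll(params, s, {}, residual, cache)
            return out

        def objective(x: np.ndarray) -> float:
            try:
                return float(np.sum(per_subject(x)))
            except (EstimationError, ValueError, OverflowError):
                return np.inf

        def predict_stack(x: np.ndarray) -> np.ndarray:
            params = unpack(x)
            cache: dict = {}
            return np.concatenate([lik.predict(params, s, {}, cache) for s in subjects])

        y_all = np.concatenate([s.y for s in subjects])
        blq_all = np.concatenate([s.blq for s in subjects])
        x0 = np.array([math.log(getattr(init, n)) for n in free])
        best, status = self._optimize(objective, predict_stack, y_all, blq_all,
                                      residual, x0, rng)
        params = unpack(best.x)
        estimates = {n: getattr(params, n) for n in free}

        sigma = residual
        if self.estimate_sigma:
            cache: dict = {}
            preds = [lik.predict(params, s, {}, cache) for s in subjects]

            def neg2ll(log_sd: float) -> float:
                trial = ResidualSpec(math.exp(log_sd), residual.additive_sd)
                return sum(
                    _gaussian_neg2ll(s.y, p, _obs_variance(p, s.blq, trial))
                    for s, p in zip(subjects, preds)
                )

            res = optimize.minimize_scalar(neg2ll, bounds=(math.log(1e-3), math.log(2.0)),
                                           method="bounded")
            sigma = ResidualSpec(math.exp(res.x), residual.additive_sd)
            estimates["proportional_sd"] = sigma.proportional_sd
            objective_value = float(neg2ll(res.x))
        else:
            objective_value = float(best.fun)

        rse: dict[str, float] = {}
        if self.rse_method == "sandwich":
            cov = _finite_diff_cov(objective, best.x, per_subject, len(free))
            if cov is not None:
                rse = {n: 100.0 * math.sqrt(cov[i, i]) for i, n in enumerate(free)}

        self.result_ = FitResult(
            estimates=estimates, params=params, objective=objective_value,
            convergence=status, free_names=free, rse_percent=rse,
            n_obs=int(sum(len(s.y) for s in subjects)), n_subjects=len(subjects),
            omega=self.omega, residual=sigma,
        )
        self.params_ = params
        self.objective_ = objective_value
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "params_")
        from .pk_model import mouse_default_params

        mouse_pk = self.mouse_pk or mouse_default_params()
        residual = self.residual or ResidualSpec(0.256, 0.0)
        subjects = _parse_subjects(X, "tumor")
        lik = _PDLikelihood(subjects, residual, mouse_pk, self.rtol, self.atol)
        cache: dict = {}
        return np.concatenate([lik.predict(self.params_, s, {}, cache) for s in subjects])


def fit_pk(dataset: pd.DataFrame, init: PKParameters,
           omega_init: OmegaSpec | None = None,
           residual_init: ResidualSpec | None = None, **kwargs) -> FitResult:
    """Fit the population PK model to a long-format dataset.

    Thin wrapper over :class:`PopPKEstimator`; keyword arguments are
    forwarded to the estimator constructor.
    """
    est = PopPKEstimator(init=init, omega=omega_init, residual=residual_init, **kwargs)
    est.fit(dataset)
    return est.result_


def fit_pd(tumor_dataset: pd.DataFrame, fixed_mouse_pk: PKParameters,
           init: PDParameters, **kwargs) -> FitResult:
    """Fit the tumor-growth model with fixed mouse PK parameters.

    Thin wrapper over :class:`TumorGrowthEstimator`.
    """
    est = TumorGrowthEstimator(mouse_pk=fixed_mouse_pk, init=init, **kwargs)
    est.fit(tumor_dataset)
    return est.result_


def compare_models(fit_a: FitResult, fit_b: FitResult, df: int,
                   alpha: float = 0.01) -> dict:
    """Likelihood-ratio comparison of two nested fits.

    The richer model is significant iff the objective drop exceeds the
    chi-square quantile at ``1 - alpha`` with ``df`` degrees of freedom
    (6.63 for df = 1 at alpha = 0.01).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    set_a, set_b = set(fit_a.free_names), set(fit_b.free_names)
    if not (set_a <= set_b or set_b <= set_a):
        raise ValueError("fits are not nested: neither free-parameter set "
                         "contains the other")
    reduced, full = (fit_a, fit_b) if set_a <= set_b else (fit_b, fit_a)
    delta = reduced.objective - full.objective
    threshold = float(stats.chi2.ppf(1.0 - alpha, df))
    return {
        "delta_ofv": float(delta),
        "threshold": threshold,
        "df": df,
        "significant": bool(delta > threshold),
    }
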