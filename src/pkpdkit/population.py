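"""Between-subject variability and residual error layers.

Individual parameters are lognormal perturbations of the typical values,
``P_i = P_pop * exp(eta_i)`` with ``eta_i ~ N(0, omega^2)``.  Reported
between-subject variabilities are coefficients of variation (CV%) of that
lognormal, converted via ``omega^2 = ln(1 + (CV/100)^2)``.

Observations carry combined proportional and additive residual error,
``C_obs = C_pred * (1 + eps_p) + eps_a``; tumor volumes use a
proportional-only error.  Concentrations below the lower limit of
quantification (LLOQ) follow the standard imputation rule: the first
below-LLOQ observation of a subject is fixed to LLOQ/2 (with the fixed
additive error absorbing its uncertainty) and later ones are flagged
missing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

__all__ = [
    "OmegaSpec",
    "ResidualSpec",
    "LLOQRule",
    "ObservedSeries",
    "draw_individual",
    "apply_residual",
    "pk_omega_defaults",
    "pk_residual_defaults",
    "pd_omega_defaults",
    "pd_residual_defaults",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class OmegaSpec:
    """Between-subject variability, parameter name -> CV (%)."""

    cv_percent: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cv_percent", dict(self.cv_percent))
        for name, cv in self.cv_percent.items():
            if cv < 0:
                raise ValueError(f"CV for {name} must be non-negative")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.cv_percent)

    def omega2(self, name: str) -> float:
        """Lognormal variance: omega^2 = ln(1 + (CV/100)^2)."""
        cv = self.cv_percent[name] / 100.0
        return float(np.log1p(cv * cv))

    def sd(self, name: str) -> float:
        return float(np.sqrt(self.omega2(name)))

    def is_zero(self) -> bool:
        return all(cv == 0 for cv in self.cv_percent.values())


@dataclass(frozen=True)
class ResidualSpec:
    """Residual-error magnitudes: proportional (fraction) and additive (mg/L)."""

    proportional_sd: float
    additive_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.proportional_sd < 0 or self.additive_sd < 0:
            raise ValueError("error SDs must be non-negative")

    def sd(self, predicted: np.ndarray) -> np.ndarray:
        """Observation SD at the given predictions (variance addition)."""
        predicted = np.asarray(predicted, dtype=float)
        return np.sqrt((self.proportional_sd * predicted) ** 2 + self.additive_sd**2)


@dataclass(frozen=True)
class LLOQRule:
    """Assay quantification limit and the below-limit handling policy.

    The first below-LLOQ observation per subject is imputed at LLOQ/2;
    later ones are marked missing and excluded from analysis.
    """

    lloq: float = 0.078  # mg/L
    policy: str = "first_blq_imputed"

    def __post_init__(self) -> None:
        if self.lloq <= 0:
            raise ValueError("lloq must be positive")
        if self.policy != "first_blq_imputed":
            raise ValueError("only the 'first_blq_imputed' policy is implemented")

    @property
    def first_blq_value(self) -> float:
        return self.lloq / 2.0


@dataclass(frozen=True)
class ObservedSeries:
    """Residual-perturbed observations with below-LLOQ bookkeeping.

    ``values`` holds the observed (possibly imputed) values; ``blq`` flags
    observations below the quantification limit; ``missing`` flags
    below-limit observations after the first, which are excluded from
    analysis.
    """

    values: np.ndarray
    blq: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "blq", np.asarray(self.blq, dtype=bool))
        object.__setattr__(self, "missing", np.asarray(self.missing, dtype=bool))


def pk_omega_defaults() -> OmegaSpec:
    """Published PK between-subject variability: CL 13.2%, V1 14.6% CV."""
    return OmegaSpec({"CL": 13.2, "V1": 14.6})


def pk_residual_defaults() -> ResidualSpec:
    """Published PK residual error: proportional SD 0.108, additive 0.039 mg/L."""
    return ResidualSpec(proportional_sd=0.108, additive_sd=0.039)


def pd_omega_defaults() -> OmegaSpec:
    """Published tumor-model variability: Base 20.6%, K_G 55.1%, K_D 35.5% CV."""
    return OmegaSpec({"Base": 20.6, "K_G": 55.1, "K_D": 35.5})


def pd_residual_defaults() -> ResidualSpec:
    """Published tumor residual error: proportional CV 25.6%, no additive term."""
    return ResidualSpec(proportional_sd=0.256, additive_sd=0.0)


def draw_individual(pop, omega: OmegaSpec, seed):
    """Draw an individual parameter set, ``P_i = P_pop * exp(eta_i)``.

    ``pop`` may be any dataclass-like parameter object exposing the named
    attributes and a ``replace`` method (``PKParameters``,
    ``PDParameters``).  Only parameters listed in ``omega`` are perturbed.
    """
    rng = _as_rng(seed)
    changes = {}
    for name in omega.names:
        if not hasattr(pop, name):
            raise KeyError(f"parameter {name!r} not present in {type(pop).__name__}")
        eta = rng.normal(0.0, omega.sd(name))
        changes[name] = getattr(pop, name) * float(np.exp(eta))
    return pop.replace(**changes) if changes else pop


def apply_residual(
    predicted: np.ndarray,
    spec: ResidualSpec,
    lloq: LLOQRule | None,
    seed,
) -> ObservedSeries:
    """Perturb a predicted series with residual error and apply the LLOQ rule.

    Each observation receives independent proportional and additive noise.
    With an ``lloq`` rule, observations falling below the limit are
    flagged; the first such observation of the series is imputed at LLOQ/2
    and the later ones are marked missing.  Without a rule all
    observations are retained as drawn (floored at zero).
    """
    rng = _as_rng(seed)
    predicted = np.asarray(predicted, dtype=float)
    if np.any(predicted < 0):
        raise ValueError("predictions must be non-negative")
    eps_p = rng.normal(0.0, 1.0, size=predicted.shape)
    eps_a = rng.normal(0.0, 1.0, size=predicted.shape)
    observed = predicted * (1.0 + spec.proportional_sd * eps_p) + spec.additive_sd * eps_a

    blq = np.zeros(predicted.shape, dtype=bool)
    missing = np.zeros(predicted.shape, dtype=bool)
    if lloq is not None:
        blq = observed < lloq.lloq
        first_seen = False
        for j in range(len(observed)):
            if blq[j]:
                if not first_seen:
                    observed[j] = lloq.first_blq_value
                    first_seen = True
                else:
                    missing[j] = True
    observed = np.clip(observed, 0.0, None)
    return ObservedSeries(values=observed, blq=blq, missing=missing)
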