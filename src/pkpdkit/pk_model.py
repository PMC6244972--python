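"""Structural pharmacokinetic model and allometric scaling.

The structural model is a two-compartment disposition model with parallel
linear and Michaelis-Menten elimination from the central compartment, the
standard approximation of target-mediated drug disposition for a therapeutic
antibody::

    dA1/dt = -(CL/V1)*A1 - Vmax*C1/(Km + C1) - (Q/V1)*A1 + (Q/V2)*A2
    dA2/dt =  (Q/V1)*A1 - (Q/V2)*A2
    C1     =  A1/V1

``A1``/``A2`` are drug amounts (mg) in the central and peripheral
compartments, ``C1`` the central concentration (mg/L).  Units are fixed at
mg / L / h / kg throughout; any conversion happens at the I/O boundary.

Parameters are transported between species by allometric power laws: flows
(CL, Q, Vmax) scale with body weight to the 0.75 power, volumes (V1, V2)
linearly, and Km — a property of the drug-target interaction, not of body
size — is carried over unchanged by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PKParameters",
    "AllometricRule",
    "DoseEvent",
    "Regimen",
    "ConcentrationCourse",
    "simulate",
    "scale_params",
    "human_default_params",
    "mouse_default_params",
]

#: flow-like parameters (allometric exponent 0.75 by default)
FLOW_PARAMS = ("CL", "Q", "Vmax")
#: volume-like parameters (allometric exponent 1.0 by default)
VOLUME_PARAMS = ("V1", "V2")


@dataclass(frozen=True)
class PKParameters:
    """Structural PK parameter set for one species / body-weight context.

    Attributes
    ----------
    CL : float
        Linear clearance (L/h).
    V1 : float
        Central volume of distribution (L).
    Q : float
        Intercompartmental (distributional) clearance (L/h).
    V2 : float
        Peripheral volume of distribution (L).
    Vmax : float
        Maximum nonlinear elimination rate (mg/h).
    Km : float
        Concentration of half-maximal nonlinear elimination (mg/L).
    body_weight : float
        Body weight (kg) this set refers to.
    """

    CL: float
    V1: float
    Q: float
    V2: float
    Vmax: float
    Km: float
    body_weight: float = 70.0

    def __post_init__(self) -> None:
        for name in ("V1", "V2", "Km", "body_weight"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be a finite positive number, got {value!r}")
        for name in ("CL", "Q", "Vmax"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {value!r}")

    def replace(self, **changes: float) -> "PKParameters":
        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {
            "CL": self.CL,
            "V1": self.V1,
            "Q": self.Q,
            "V2": self.V2,
            "Vmax": self.Vmax,
            "Km": self.Km,
            "body_weight": self.body_weight,
        }


@dataclass(frozen=True)
class AllometricRule:
    """Power-law rule for projecting PK parameters across body weights.

    ``scale_km`` defaults to False: the half-saturation concentration is a
    drug-target binding property and is kept fixed across species when the
    epitope is conserved.
    """

    reference_weight: float = 70.0
    exponent_flow: float = 0.75
    exponent_volume: float = 1.0
    scale_km: bool = False

    def __post_init__(self) -> None:
        if self.reference_weight <= 0:
            raise ValueError("reference_weight must be positive")
        for name in ("exponent_flow", "exponent_volume"):
            value = getattr(self, name)
            if not 0 < value <= 1.5:
                raise ValueError(f"{name} must lie in (0, 1.5], got {value!r}")


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: bolus of ``amount`` mg at ``time`` h."""

    time: float
    amount: float
    route: str = "iv_bolus"

    _ROUTES = ("iv_bolus", "ip_bolus")

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be non-negative")
        if self.amount < 0:
            raise ValueError("dose amount must be non-negative")
        if self.route not in self._ROUTES:
            raise ValueError(f"route must be one of {self._ROUTES}, got {self.route!r}")


@dataclass(frozen=True)
class Regimen:
    """Ordered dose events plus the observation cycle length.

    ``cycle_length`` is 504 h for a once-every-three-weeks (q3wk) human
    cycle and 168 h for weekly (q1wk) dosing.
    """

    events: tuple[DoseEvent, ...]
    cycle_length: float = 504.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose events must be sorted by time")

    @property
    def total_dose(self) -> float:
        return float(sum(e.amount for e in self.events))

    @property
    def last_dose_time(self) -> float:
        return max((e.time for e in self.events), default=0.0)

    @classmethod
    def single_dose(cls, amount: float, route: str = "iv_bolus",
                    cycle_length: float = 504.0) -> "Regimen":
        return cls((DoseEvent(0.0, amount, route),), cycle_length)

    @classmethod
    def weekly(cls, amount: float, n_doses: int, route: str = "iv_bolus",
               start: float = 0.0) -> "Regimen":
        events = tuple(DoseEvent(start + 168.0 * i, amount, route) for i in range(n_doses))
        return cls(events, cycle_length=168.0)


@dataclass(frozen=True)
class ConcentrationCourse:
    """Predicted concentration-time series with the underlying amounts."""

    times: np.ndarray
    concentrations: np.ndarray
    amounts: np.ndarray  # shape (n, 2): (A1, A2) mg

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "concentrations", np.asarray(self.concentrations, dtype=float))
        object.__setattr__(self, "amounts", np.asarray(self.amounts, dtype=float))
        if len(self.times) != len(self.concentrations) or len(self.times) != len(self.amounts):
            raise ValueError("times, concentrations and amounts must have equal length")


class SolverError(RuntimeError):
    """Raised when the ODE solver fails or produces an invalid state."""


def _rhs(t: float, y: np.ndarray, p: PKParameters) -> tuple[float, float]:
    a1, a2 = y
    c1 = a1 / p.V1
    mm = p.Vmax * c1 / (p.Km + c1) if a1 > 0 else 0.0
    da1 = -(p.CL / p.V1) * a1 - mm - (p.Q / p.V1) * a1 + (p.Q / p.V2) * a2
    da2 = (p.Q / p.V1) * a1 - (p.Q / p.V2) * a2
    return da1, da2


def _integrate_segments(
    params: PKParameters,
    regimen: Regimen,
    times: np.ndarray,
    rtol: float,
    atol: float,
    ip_bioavailability: float,
    extra_rhs=None,
    n_extra: int = 0,
    events=None,
    t_end: float | None = None,
):
    """Integrate the PK system, restarting at every dose event.

    A requested time that coincides with a dose event reports the
    post-dose (0+) state.  ``extra_rhs`` appends auxiliary cumulative
    states (e.g. an AUC integrator).  Returns ``(times, states)`` where
    states has ``2 + n_extra`` columns, or (when ``events`` given) the
    solver's terminal state.
    """
    times = np.asarray(times, dtype=float)
    horizon = t_end if t_end is not None else (times[-1] if len(times) else 0.0)
    horizon = max(horizon, regimen.last_dose_time)

    def full_rhs(t, y):
        base = _rhs(t, y[:2], params)
        if extra_rhs is None:
            return base
        return (*base, *extra_rhs(t, y, params))

    # breakpoints: dose times plus the final horizon (deduplicated, so a
    # dose falling exactly on the horizon is applied once)
    dose_times = {e.time for e in regimen.events if e.time <= horizon}
    breakpoints = sorted(dose_times | {horizon})

    state = np.zeros(2 + n_extra)
    out = np.full((len(times), 2 + n_extra), np.nan)
    if len(times):
        out[times == 0.0] = state  # pre-dose state at t=0
    t_cur = 0.0
    terminated = False
    for i, t_next in enumerate(breakpoints):
        if t_next > t_cur and not terminated:
            seg_mask = (times >= t_cur) & (times < t_next)
            if i == len(breakpoints) - 1:
                seg_mask = (times >= t_cur) & (times <= t_next)
            t_eval = times[seg_mask]
            # always integrate through to t_next so the carried state is the
            # segment-end state, not the last requested output
            if len(t_eval) == 0 or t_eval[-1] < t_next:
                t_solve = np.concatenate([t_eval, [t_next]])
            else:
                t_solve = t_eval
            sol = solve_ivp(
                full_rhs,
                (t_cur, t_next),
                state,
                method="LSODA",
                t_eval=t_solve,
                rtol=rtol,
                atol=atol,
                events=events,
            )
            if not sol.success:
                raise SolverError(
                    f"ODE integration failed on [{t_cur:g}, {t_next:g}] h: {sol.message}"
                )
            if len(t_eval):
                out[seg_mask] = sol.y[:, : len(t_eval)].T
            if events is not None and sol.t_events and len(sol.t_events[0]):
                state = sol.y_events[0][0].copy()
                terminated = True
            else:
                state = sol.y[:, -1].copy()
        t_cur = t_next
        # apply doses scheduled exactly at this breakpoint
        for e in regimen.events:
            if e.time == t_next and not terminated:
                frac = ip_bioavailability if e.route == "ip_bolus" else 1.0
                state[0] += frac * e.amount
                # times falling exactly on the event report the post-dose state
                at_event = times == t_next
                if at_event.any():
                    out[at_event] = state
    return out, state, terminated


def simulate(
    params: PKParameters,
    regimen: Regimen,
    times: Sequence[float] | np.ndarray,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    ip_bioavailability: float = 1.0,
) -> ConcentrationCourse:
    """Simulate the concentration-time course under an arbitrary regimen.

    Bolus doses (i.v. or i.p.) enter the central compartment
    instantaneously; i.p. doses are multiplied by ``ip_bioavailability``
    (1.0 by default).  Integration restarts exactly at each dose event so
    the discontinuity never crosses a solver step.

    Parameters
    ----------
    params : PKParameters
    regimen : Regimen
    times : array-like of float
        Sorted, non-negative output grid (h).  A time equal to a dose time
        reports the post-dose concentration.

    Returns
    -------
    ConcentrationCourse
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if len(times) and (np.any(np.diff(times) < 0) or times[0] < 0):
        raise ValueError("times must be sorted and non-negative")
    out, _, _ = _integrate_segments(params, regimen, times, rtol, atol, ip_bioavailability)
    amounts = out[:, :2]
    # tolerate tiny negative excursions from the solver, reject real ones
    floor = -100 * atol
    if np.nanmin(amounts) < floor:
        raise SolverError(
            f"negative compartment amount {np.nanmin(amounts):.3e} mg beyond tolerance"
        )
    amounts = np.clip(amounts, 0.0, None)
    conc = amounts[:, 0] / params.V1
    return ConcentrationCourse(times, conc, amounts)


def scale_params(anchor: PKParameters, rule: AllometricRule,
                 target_weight: float) -> PKParameters:
    """Project a PK parameter set to another body weight.

    Flows (CL, Q, Vmax) are multiplied by ``(target/reference)**0.75``,
    volumes (V1, V2) by the plain weight ratio, and Km is copied unchanged
    unless ``rule.scale_km`` is set.
    """
    if target_weight <= 0:
        raise ValueError("target_weight must be positive")
    ratio = target_weight / rule.reference_weight
    flow = ratio ** rule.exponent_flow
    vol = ratio ** rule.exponent_volume
    return PKParameters(
        CL=anchor.CL * flow,
        V1=anchor.V1 * vol,
        Q=anchor.Q * flow,
        V2=anchor.V2 * vol,
        Vmax=anchor.Vmax * flow,
        Km=anchor.Km * flow if rule.scale_km else anchor.Km,
        body_weight=target_weight,
    )


def human_default_params() -> PKParameters:
    """Published typical PK parameter values anchored at a 70 kg human."""
    return PKParameters(CL=0.0125, V1=3.17, Q=0.0313, V2=3.51,
                        Vmax=0.500, Km=0.219, body_weight=70.0)


def mouse_default_params() -> PKParameters:
    """The human anchor allometrically scaled to a 0.02 kg mouse."""
    return scale_params(human_default_params(), AllometricRule(), 0.02)
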