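"""Study-shaped synthetic datasets for the monkey PK and mouse xenograft designs.

The generators emulate the two preclinical study designs the analysis
chain assumes, with the statistical structure of the population model
(lognormal between-subject variability, combined residual error, LLOQ
handling, informative dropout at the humane tumor-size limit), so every
downstream stage is testable without animal data.

Monkey PK studies: intravenous bolus arms at 10 / 30 / 100 mg/kg, a
single-dose arm (n = 6, 14 samples per animal over 0-1007 h) and the first
week of a repeat-dose arm (n = 22, 10 samples per animal over 0-168 h).
Individual parameters are the anchor set allometrically scaled to each
animal's body weight, perturbed by lognormal deviates on CL and V1.

Xenograft studies: three arms of 10 mice (vehicle, 2.5, 25 mg/kg), weekly
intraperitoneal dosing for four weeks, caliper measurement twice weekly,
euthanasia at 800 mm^3 or end of study.  Tumor volume derives from caliper
width and length as ``width^2 * length / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pk_model import AllometricRule, PKParameters, Regimen, scale_params, simulate
from .population import LLOQRule, OmegaSpec, ResidualSpec, apply_residual, draw_individual
from .tumor_pd import PDParameters, simulate_tumor

__all__ = [
    "StudyDesign",
    "XenograftRules",
    "monkey_single_dose_design",
    "monkey_repeat_dose_design",
    "generate_monkey_pk_study",
    "generate_xenograft_study",
    "caliper_volume",
    "twice_weekly_days",
]

@dataclass(frozen=True)
class StudyDesign:
    """A dosing/sampling design for a weight-based PK study.

    ``arms`` maps dose (mg/kg) to the number of animals; ``sampling_times``
    is the per-animal observation grid (h); ``weight_range`` the uniform
    body-weight distribution (kg); ``n_female`` per arm records the sex
    split (recorded in the output, no covariate effect).
    """

    arms: tuple[tuple[float, int], ...]
    sampling_times: tuple[float, ...]
    weight_range: tuple[float, float] = (2.5, 3.5)
    route: str = "iv_bolus"
    label: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "arms", tuple((float(d), int(n)) for d, n in self.arms))
        object.__setattr__(self, "sampling_times", tuple(float(t) for t in self.sampling_times))
        if any(n <= 0 for _, n in self.arms):
            raise ValueError("arm sizes must be positive")
        if list(self.sampling_times) != sorted(self.sampling_times):
            raise ValueError("sampling_times must be sorted")

    @property
    def n_subjects(self) -> int:
        return sum(n for _, n in self.arms)


def monkey_single_dose_design() -> StudyDesign:
    """Single-dose toxicity-study arm: 10/30/100 mg/kg i.v., n = 2 each,
    14 samples per animal from 0.5 to 1007 h."""
    times = (0.5, 2, 4, 8, 24, 48, 96, 168, 240, 336, 504, 672, 840, 1007)
    return StudyDesign(arms=((10, 2), (30, 2), (100, 2)), sampling_times=times,
                       label="single_dose")


def monkey_repeat_dose_design() -> StudyDesign:
    """First week of the repeat-dose arm: 10 mg/kg (n=6), 30 mg/kg (n=6),
    100 mg/kg (n=10); 10 samples per animal from 0.5 to 168 h."""
    times = (0.5, 1, 2, 4, 8, 24, 48, 96, 120, 168)
    return StudyDesign(arms=((10, 6), (30, 6), (100, 10)), sampling_times=times,
                       label="repeat_dose_week1")


def twice_weekly_days(last_day: float) -> np.ndarray:
    """Twice-weekly caliper grid: days 0, 3, 7, 10, 14, ... up to ``last_day``."""
    days = [0.0]
    step = 3.0
    while days[-1] + step <= last_day:
        days.append(days[-1] + step)
        step = 7.0 - step  # alternate +3 / +4
    return np.asarray(days)


@dataclass(frozen=True)
class XenograftRules:
    """Operational rules of the xenograft study.

    Times are days relative to tumor-cell implantation: treatment starts on
    ``treatment_start_day`` with baseline tumors inside ``baseline_range``
    (set to None to disable truncation of the baseline distribution), and
    mice leave the study at ``euthanasia_volume`` or on ``study_end_day``.
    """

    baseline_range: tuple[float, float] | None = (108.0, 172.0)
    euthanasia_volume: float = 800.0
    study_end_day: float = 68.0
    treatment_start_day: float = 8.0
    n_weekly_doses: int = 4
    mouse_weight: float = 0.02

    def __post_init__(self) -> None:
        if self.baseline_range is not None:
            lo, hi = self.baseline_range
            if not 0 < lo < hi:
                raise ValueError("baseline_range must be increasing and positive")
            if self.euthanasia_volume <= hi:
                raise ValueError("euthanasia threshold must exceed the baseline range")

    @property
    def measurement_days(self) -> np.ndarray:
        """Twice-weekly grid in days since treatment start."""
        return twice_weekly_days(self.study_end_day - self.treatment_start_day)


def generate_monkey_pk_study(
    truth: PKParameters,
    omega: OmegaSpec,
    residual: ResidualSpec,
    lloq: LLOQRule | None,
    design: StudyDesign,
    seed,
    *,
    rule: AllometricRule | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Simulate one weight-based PK study in the long-format dialect.

    ``truth`` is the anchor parameter set (typically the 70 kg human
    anchor); each animal's structural parameters are scaled to its drawn
    body weight, perturbed by the between-subject deviates, simulated
    under a single i.v. bolus of dose*weight mg at t = 0, and the residual
    and LLOQ rules applied.  Rows below the limit after the first are kept
    with ``MDV = 1``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rule = rule or AllometricRule(reference_weight=truth.body_weight)
    rows = []
    subject = 0
    for dose_per_kg, n_animals in design.arms:
        for k in range(n_animals):
            subject += 1
            weight = rng.uniform(*design.weight_range)
            typical = scale_params(truth, rule, weight)
            individual = draw_individual(typical, omega, rng)
            amount = dose_per_kg * weight
            regimen = Regimen.single_dose(amount, route=design.route)
            course = simulate(individual, regimen, np.asarray(design.sampling_times),
                              rtol=rtol, atol=atol)
            obs = apply_residual(course.concentrations, residual, lloq, rng)
            sex = "F" if k % 2 == 0 else "M"
            rows.append({
                "ID": subject, "TIME": 0.0, "AMT": amount, "DV": np.nan,
                "EVID": 1, "MDV": 1, "CMT": 1, "WT": weight,
                "DOSEGRP": dose_per_kg, "BLQ": 0, "SEX": sex,
            })
            for t, dv, is_blq, is_missing in zip(design.sampling_times, obs.values,
                                                 obs.blq, obs.missing):
                rows.append({
                    "ID": subject, "TIME": t, "AMT": np.nan, "DV": dv,
                    "EVID": 0, "MDV": int(is_missing), "CMT": 1, "WT": weight,
                    "DOSEGRP": dose_per_kg, "BLQ": int(is_blq), "SEX": sex,
                })
    return pd.DataFrame(rows)


def _draw_baseline(rng: np.random.Generator, base: float, cv_percent: float,
                   bounds: tuple[float, float] | None, max_tries: int = 1000) -> float:
    """Lognormal baseline around ``base``, optionally truncated by rejection."""
    sd = np.sqrt(np.log1p((cv_percent / 100.0) ** 2))
    for _ in range(max_tries):
        value = base * np.exp(rng.normal(0.0, sd)) if sd > 0 else base
        if bounds is None or bounds[0] <= value <= bounds[1]:
            return float(value)
    # heavy truncation relative to the located mass: fall back to clipping
    return float(np.clip(value, *bounds))


def generate_xenograft_study(
    truth_pd: PDParameters,
    mouse_pk: PKParameters,
    omega_pd: OmegaSpec,
    residual_pd: ResidualSpec,
    rules: XenograftRules,
    seed,
    *,
    arms: Sequence[float] = (0.0, 2.5, 25.0),
    n_per_arm: int = 10,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Simulate one three-arm xenograft efficacy study.

    Each mouse receives weekly intraperitoneal doses of
    ``arm_dose * mouse_weight`` mg; its baseline is drawn lognormally
    around ``truth_pd.Base`` (truncated to the design range when one is
    set) and its growth/death rates perturbed by the between-subject
    deviates.  Caliper records stop after the first measurement at or
    above the euthanasia threshold, reproducing the informative dropout of
    the real design.  Tumor DV rows use compartment code 2.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    days = rules.measurement_days
    times_h = days * 24.0
    rows = []
    subject = 0
    growth_omega = OmegaSpec({k: v for k, v in omega_pd.cv_percent.items() if k != "Base"})
    base_cv = omega_pd.cv_percent.get("Base", 0.0)
    for dose_per_kg in arms:
        for _ in range(n_per_arm):
            subject += 1
            baseline = _draw_baseline(rng, truth_pd.Base, base_cv, rules.baseline_range)
            individual = draw_individual(truth_pd, growth_omega, rng).replace(Base=baseline)
            amount = dose_per_kg * rules.mouse_weight
            if amount > 0:
                regimen = Regimen.weekly(amount, rules.n_weekly_doses, route="ip_bolus")
            else:
                regimen = Regimen((), cycle_length=168.0)
            course = simulate_tumor(individual, mouse_pk, regimen, times_h,
                                    rtol=rtol, atol=atol)
            obs = apply_residual(course.volume, residual_pd, None, rng)
            for e in regimen.events:
                rows.append({
                    "ID": subject, "TIME": e.time, "AMT": e.amount, "DV": np.nan,
                    "EVID": 1, "MDV": 1, "CMT": 2, "WT": rules.mouse_weight,
                    "DOSEGRP": dose_per_kg, "BLQ": 0, "SEX": "F",
                })
            for t, dv in zip(times_h, obs.values):
                rows.append({
                    "ID": subject, "TIME": t, "AMT": np.nan, "DV": dv,
                    "EVID": 0, "MDV": 0, "CMT": 2, "WT": rules.mouse_weight,
                    "DOSEGRP": dose_per_kg, "BLQ": 0, "SEX": "F",
                })
                if dv >= rules.euthanasia_volume:
                    break  # euthanized: no further records for this mouse
    df = pd.DataFrame(rows)
    return df.sort_values(["ID", "EVID", "TIME"], kind="stable").sort_values(
        ["ID", "TIME"], kind="stable").reset_index(drop=True)


def caliper_volume(width: float, length: float) -> float:
    """Tumor volume (mm^3) from caliper width and length (mm).

    ``volume = width^2 * length / 2`` with the convention that width is
    the smaller dimension.
    """
    if width <= 0 or length <= 0:
        raise ValueError("caliper dimensions must be positive")
    if width > length:
        raise ValueError("width must not exceed length (by convention)")
    return width * width * length * 0.5
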