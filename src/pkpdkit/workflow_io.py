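"""Dataset dialect, pipeline configuration, and orchestration.

The on-disk dataset dialect is the NONMEM-convention long format: one row
per dose event or observation, columns ID, TIME, AMT, DV, EVID, MDV, CMT,
WT, DOSEGRP, BLQ, missing values written as ``"."``.  Times are hours; DV
is mg/L for concentration rows (CMT 1) and mm^3 for tumor rows (CMT 2).

:func:`run_pipeline` ties the stages together in the order of the
analysis: simulate monkey PK studies, fit the PK model at the human
anchor, scale to mouse, build the human exposure/occupancy dose table,
simulate and fit the xenograft study, and evaluate tumor stasis for the
AUC-matched efficacy regimens.  All randomness is funnelled through one
seeded generator; re-running with the same configuration reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path


import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("pkpdkit")

__all__ = [
    "DATASET_COLUMNS",
    "read_dataset",
    "write_dataset",
    "read_params_file",
    "write_params_file",
    "PipelineConfig",
    "run_pipeline",
]

DATASET_COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "MDV", "CMT", "WT", "DOSEGRP", "BLQ"]
_REQUIRED = ("ID", "TIME", "AMT", "DV", "EVID")
MISSING = "."

#: expected imputed value (LLOQ/2) for below-limit concentration rows
_BLQ_IMPUTED = 0.039


class DatasetError(ValueError):
    """Raised for malformed dataset files; carries the offending row."""


def write_dataset(records: pd.DataFrame, path: str | Path) -> Path:
    """Write a long-format dataset with ``"."`` as the missing marker."""
    path = Path(path)
    out = records.copy()
    cols = [c for c in DATASET_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out = out[cols]
    out.to_csv(path, index=False, na_rep=MISSING, float_format="%.10g")
    return path


def read_dataset(path: str | Path, *, validate: bool = True) -> pd.DataFrame:
    """Read a long-format dataset, validating the dialect.

    Raises :class:`DatasetError` naming the first offending row when a row
    is neither a dose event (AMT > 0, DV missing) nor an observation (AMT
    missing, DV present or below-limit).  A below-limit row whose DV is
    not the LLOQ/2 imputed value triggers a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, na_values=[MISSING], keep_default_na=True)
    missing_cols = set(_REQUIRED) - set(df.columns)
    if missing_cols:
        raise DatasetError(f"{path.name}: missing required columns {sorted(missing_cols)}")
    if not validate:
        return df
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        is_dose = row.EVID == 1
        has_amt = pd.notna(row.AMT) and row.AMT > 0
        has_dv = pd.notna(row.DV)
        if is_dose and not has_amt:
            raise DatasetError(f"{path.name} row {i}: dose event without a positive AMT")
        if is_dose and has_dv:
            raise DatasetError(f"{path.name} row {i}: dose event must not carry a DV")
        if not is_dose and has_amt:
            raise DatasetError(f"{path.name} row {i}: observation row carries an AMT")
        if not is_dose and not has_dv:
            mdv = getattr(row, "MDV", 0)
            if not (pd.notna(mdv) and mdv == 1):
                raise DatasetError(f"{path.name} row {i}: observation without DV or MDV flag")
        blq = getattr(row, "BLQ", 0)
        mdv = getattr(row, "MDV", 0)
        if (not is_dose and pd.notna(blq) and blq == 1 and has_dv
                and (pd.isna(mdv) or mdv == 0) and abs(row.DV - _BLQ_IMPUTED) > 1e-9):
            warnings.warn(
                f"{path.name} row {i}: below-limit observation with DV {row.DV!r}; "
                f"expected the LLOQ/2 imputed value {_BLQ_IMPUTED}",
                stacklevel=2,
            )
    return df


_PARAM_KEYS = {"CL": "CL", "V1": "V1", "Q": "Q", "V2": "V2",
               "VMAX": "Vmax", "KM": "Km", "WT": "body_weight"}


def read_params_file(path: str | Path):
    """Read a flat YAML/JSON PK parameter file (keys CL, V1, Q, V2, VMAX, KM, WT)."""
    from .pk_model import PKParameters

    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise DatasetError(f"{path.name}: parameter file must be a flat mapping")
    upper = {str(k).upper(): v for k, v in data.items()}
    missing = set(_PARAM_KEYS) - set(upper)
    if missing:
        raise DatasetError(f"{path.name}: missing parameter keys {sorted(missing)}")
    return PKParameters(**{attr: float(upper[key]) for key, attr in _PARAM_KEYS.items()})


def write_params_file(params, path: str | Path) -> Path:
    """Write a PK parameter set as flat JSON (keys CL, V1, Q, V2, VMAX, KM, WT)."""
    path = Path(path)
    data = {key: getattr(params, attr) for key, attr in _PARAM_KEYS.items()}
    path.write_text(json.dumps(data, indent=2, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# configuration

_DOSE_LADDER = (10.0, 20.0, 40.0, 80.0, 160.0, 240.0, 360.0, 480.0,
                600.0, 750.0, 900.0, 1000.0, 1200.0)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings (unknown keys are rejected).

    Defaults reproduce the full analysis: both monkey designs, the 13-dose
    human ladder over a 504 h (q3wk) cycle against the 193 g.h/L NOAEL
    reference, a three-arm xenograft study, and stasis evaluation of the
    AUC-matched efficacy regimens.
    """

    seed: int = 1
    monkey_designs: tuple[str, ...] = ("single_dose", "repeat_dose_week1")
    anchor_weight: float = 70.0
    mouse_weight: float = 0.02
    pk_method: str = "pooled"
    pk_estimate: tuple[str, ...] = ("CL", "V1", "Q", "V2", "Vmax", "Km")
    doses: tuple[float, ...] = _DOSE_LADDER
    cycle_hours: float = 504.0
    noael_auc: float = 193.0
    exposure_params: str = "fitted"  # or "published"
    xenograft_arms: tuple[float, ...] = (0.0, 2.5, 25.0)
    n_per_arm: int = 10
    pd_estimate: tuple[str, ...] = ("Base", "K_G", "K_D", "EC50", "lam")
    human_doses: tuple[float, ...] = (360.0, 750.0, 900.0)
    n_weekly_doses: int = 3

    def __post_init__(self) -> None:
        if self.exposure_params not in ("fitted", "published"):
            raise ValueError("exposure_params must be 'fitted' or 'published'")
        unknown = set(self.monkey_designs) - {"single_dose", "repeat_dose_week1"}
        if unknown:
            raise ValueError(f"unknown monkey designs: {sorted(unknown)}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - names
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        coerced = {}
        for key, value in mapping.items():
            if isinstance(value, list):
                value = tuple(value)
            coerced[key] = value
        return cls(**coerced)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("configuration file must contain a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# pipeline

def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run the full analysis chain on synthetic studies; write reports.

    Outputs under ``outdir``: the generated datasets
    (``monkey_pk.csv``, ``xenograft.csv``), parameter reports
    (``pk_parameters.csv``, ``pd_parameters.csv``), the human dose table
    (``exposure_table.csv``), the stasis evaluation
    (``stasis.csv``), and ``manifest.json`` recording configuration, seed
    and version.
    """
    from . import __version__
    from .estimation import fit_pd, fit_pk
    from .exposure import ReferenceExposure, exposure_table
    from .pk_model import AllometricRule, Regimen, human_default_params, scale_params
    from .population import (LLOQRule, pd_omega_defaults, pd_residual_defaults,
                             pk_omega_defaults, pk_residual_defaults)
    from .synthetic_data import (XenograftRules, generate_monkey_pk_study,
                                 generate_xenograft_study, monkey_repeat_dose_design,
                                 monkey_single_dose_design)
    from .tumor_pd import (auc_matched_mouse_dose, pd_default_params, simulate_tumor,
                           stasis_metric)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(4)

    # 1. synthetic monkey PK studies ------------------------------------
    logger.info("stage 1/6: generating monkey PK data (seed %s)", config.seed)
    truth = human_default_params()
    designs = {
        "single_dose": monkey_single_dose_design,
        "repeat_dose_week1": monkey_repeat_dose_design,
    }
    rng_pk = np.random.default_rng(seeds[0])
    frames = []
    id_offset = 0
    for name in config.monkey_designs:
        frame = generate_monkey_pk_study(
            truth, pk_omega_defaults(), pk_residual_defaults(), LLOQRule(),
            designs[name](), rng_pk,
        )
        frame["ID"] += id_offset
        id_offset = int(frame["ID"].max())
        frames.append(frame)
    monkey = pd.concat(frames, ignore_index=True)
    write_dataset(monkey, outdir / "monkey_pk.csv")

    # 2. PK fit at the human anchor --------------------------------------
    logger.info("stage 2/6: fitting the PK model (%s)", config.pk_method)
    pk_fit = fit_pk(
        monkey, truth,
        estimate=tuple(config.pk_estimate), method=config.pk_method,
        anchor_weight=config.anchor_weight, rse_method="sandwich",
    )
    if pk_fit.convergence != "converged":
        raise RuntimeError(f"pipeline stage 'fit-pk' failed: {pk_fit.convergence}")

    # 3. allometric scaling ----------------------------------------------
    rule = AllometricRule(reference_weight=config.anchor_weight)
    mouse_params = scale_params(pk_fit.params, rule, config.mouse_weight)
    pk_report = pd.DataFrame({
        "parameter": list(pk_fit.params.as_dict()),
        "estimate": list(pk_fit.params.as_dict().values()),
        "rse_percent": [pk_fit.rse_percent.get(n, np.nan)
                        for n in pk_fit.params.as_dict()],
        "scaled_mouse": list(mouse_params.as_dict().values()),
    })
    pk_report.to_csv(outdir / "pk_parameters.csv", index=False, float_format="%.6g")

    # 4. human exposure / occupancy dose table ---------------------------
    logger.info("stage 3/6: human exposure table (%d doses)", len(config.doses))
    exp_params = pk_fit.params if config.exposure_params == "fitted" else truth
    ref = ReferenceExposure(noael_auc=config.noael_auc)
    rows = exposure_table(exp_params, list(config.doses), cycle=config.cycle_hours, ref=ref)
    table3 = pd.DataFrame([{
        "dose_mg": r.dose,
        "auc_g_h_per_L": float(f"{r.auc_inf:.3g}"),
        "safety_margin": round(r.safety_margin),
        "ro_cmax_pct": round(r.ro_cmax, 1),
        "ro_cave_pct": round(r.ro_cave, 1),
        "ro_ctrough_pct": round(r.ro_ctrough, 1),
    } for r in rows])
    table3.to_csv(outdir / "exposure_table.csv", index=False)

    # 5. xenograft study and tumor-model fit -----------------------------
    logger.info("stage 4/6: generating xenograft data")
    rules = XenograftRules(mouse_weight=config.mouse_weight)
    xeno = generate_xenograft_study(
        pd_default_params(), mouse_params, pd_omega_defaults(), pd_residual_defaults(),
        rules, np.random.default_rng(seeds[1]),
        arms=config.xenograft_arms, n_per_arm=config.n_per_arm,
    )
    write_dataset(xeno, outdir / "xenograft.csv")
    logger.info("stage 5/6: fitting the tumor-growth model")
    pd_fit = fit_pd(xeno, mouse_params, pd_default_params(),
                    estimate=tuple(config.pd_estimate))
    if pd_fit.convergence != "converged":
        raise RuntimeError(f"pipeline stage 'fit-pd' failed: {pd_fit.convergence}")
    pd_report = pd.DataFrame({
        "parameter": list(pd_fit.estimates),
        "estimate": list(pd_fit.estimates.values()),
    })
    pd_report.to_csv(outdir / "pd_parameters.csv", index=False, float_format="%.6g")

    # 6. AUC-matched efficacy simulation ---------------------------------
    logger.info("stage 6/6: tumor-stasis evaluation")
    stasis_rows = []
    times = np.linspace(0.0, 28 * 24.0, 337)
    for human_dose in config.human_doses:
        mgkg = auc_matched_mouse_dose(
            human_dose, human_params=pk_fit.params, mouse_params=mouse_params,
            n_weekly_doses=config.n_weekly_doses, mouse_weight=config.mouse_weight,
        )
        regimen = Regimen.weekly(mgkg * config.mouse_weight, config.n_weekly_doses,
                                 route="ip_bolus")
        course = simulate_tumor(pd_fit.params, mouse_params, regimen, times)
        result = stasis_metric(course, day=21.0)
        stasis_rows.append({
            "human_dose_mg": human_dose,
            "mouse_dose_mg_per_kg": round(mgkg, 3),
            "t21_over_t0": round(result.ratio, 4),
            "classification": result.classification,
        })
    vehicle = simulate_tumor(pd_fit.params, mouse_params, Regimen((), cycle_length=168.0),
                             times)
    vres = stasis_metric(vehicle, day=21.0)
    stasis_rows.append({
        "human_dose_mg": 0.0, "mouse_dose_mg_per_kg": 0.0,
        "t21_over_t0": round(vres.ratio, 4), "classification": vres.classification,
    })
    pd.DataFrame(stasis_rows).to_csv(outdir / "stasis.csv", index=False)

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "pk_estimates": pk_fit.estimates,
        "pk_objective": pk_fit.objective,
        "pd_estimates": pd_fit.estimates,
        "pd_objective": pd_fit.objective,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
    logger.info("pipeline complete: %s", outdir)
    return outdir
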