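"""Pipeline orchestration: config validation, table I/O, end-to-end driver.

The driver runs the stages in workflow order -- powder scoring, factorial
modeling/optimization, dissolution-kinetics fitting, PK simulation -- on
synthetic inputs generated from the config (or user-supplied files), and
writes one JSON report per stage plus a consolidated run report carrying
full provenance (config, seeds, package version).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from . import doe as _doe
from . import pk as _pk
from . import release_kinetics as _rk
from . import sedem as _sedem
from . import synth_data as _synth

__all__ = ["PipelineConfig", "ConfigError", "SchemaError", "load_table",
           "run_pipeline", "TABLE_SCHEMAS"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class SchemaError(ValueError):
    """Tabular input violates its declared schema."""


TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "measurements": (
        "sample_id", "sample_mass_g", "bulk_volume_ml", "tapped_volume_ml",
        "tablet_hardness_N", "cone_height_cm", "cone_diameter_cm",
        "flow_time_s", "loss_on_drying_pct", "hygroscopicity_pct", "fines_pct",
    ),
    "sieve": ("sample_id", "mean_diameter_um", "mass_pct"),
    "dissolution": ("formulation_id", "time_h", "release_pct"),
    "responses": ("run_id",),
    "plasma": ("time_h", "conc_ng_ml"),
}

_ID_COLUMNS = {"sample_id", "formulation_id", "run_id"}


def load_table(path, schema: str) -> pd.DataFrame:
    """Load a CSV and validate it against a named schema.

    Checks the file is non-empty, that every required column is present,
    and that non-identifier cells are numeric; errors name the offending
    column or row.
    """
    if schema not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(TABLE_SCHEMAS)}")
    if not os.path.exists(path):
        raise SchemaError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"empty input file: {path}") from None
    if df.shape[0] == 0:
        raise SchemaError(f"input table has no rows: {path}")
    for col in TABLE_SCHEMAS[schema]:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col in df.columns:
        if col in _ID_COLUMNS:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) > 0:
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at row {int(bad[0])}"
            )
        df[col] = coerced
    return df


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

_DEFAULT_SEDEM = {
    # a drug-like powder with deficient porosity and cohesion radii
    "target_radii": {
        "Da": 7.0, "Dc": 10.0, "Icd": 4.0, "alpha": 7.0, "t_flow": 7.5,
        "HR": 8.0, "H": 9.0, "Pf": 8.0, "Itheta": 5.0,
    },
    "excipient_radius": 10.0,
}

_DEFAULT_DOE = {
    "k": 4,
    "sigma": 0.5,
    "grid_resolution": 0.1,
    # generating coefficient vectors (intercept, then k main effects)
    "coefficients": {
        "release_2h": [25.258, 6.871, -11.159, -4.846, 1.267],
        "release_12h": [85.061, 1.297, 0.358, -7.188, 0.404],
        "release_16h": [93.201, 2.209, 2.124, -0.948, 0.629],
        "zero_order_r2": [0.814, -0.0795, 0.169, 0.052, -0.007],
    },
    "constraints": {
        "release_2h": {"kind": "range", "low": 0.0, "high": 15.0},
        "release_12h": {"kind": "range", "low": 65.0, "high": 95.0},
        "release_16h": {"kind": "range", "low": 80.0, "high": 110.0},
        "zero_order_r2": {"kind": "maximize", "low": 0.9, "high": 1.0},
    },
}

_DEFAULT_KINETICS = {
    "noise": 0.0,
    "profiles": {
        "CR-A": {"model": "zero_order", "params": {"k0": 5.898}},
        "CR-B": {"model": "zero_order", "params": {"k0": 6.271}},
    },
    "schedule_h": list(range(0, 17)),
}

_DEFAULT_PK = {
    "disposition": {"Vc": 1.4776, "k12": 0.4021, "k21": 0.0569,
                    "CL": 0.00572, "body_weight": 70.0},
    "drug": {},
    "transit": {},
    "ir_reference": {"dose_mg": 50.0, "n_doses": 4, "interval_h": 6.0,
                     "F": 0.7, "target_tmax_h": 1.12},
    "cr_dose_mg": 190.0,
    "cr_release_duration_h": 16.0,
    "sim_horizon_h": 48.0,
    # published exposure inputs for the dose-normalized relative-BA report
    "auc_comparisons": {
        "CR-A_2stage": {"auc_test": 7388.4, "dose_test": 190.0,
                        "auc_ref": 7917.4, "dose_ref": 200.0},
        "CR-B_2stage": {"auc_test": 7663.8, "dose_test": 190.0,
                        "auc_ref": 7917.4, "dose_ref": 200.0},
        "CR-A_pH4.5": {"auc_test": 7559.6, "dose_test": 190.0,
                       "auc_ref": 7917.4, "dose_ref": 200.0},
    },
}


def _merge(defaults: Mapping, override: Mapping, path: str) -> dict:
    out = dict(defaults)
    for key, value in override.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key {path}{key!r}")
        if isinstance(defaults[key], Mapping) and isinstance(value, Mapping) \
                and path in ("", "pk.") and key not in ("profiles", "coefficients",
                                                        "constraints", "auc_comparisons"):
            out[key] = _merge(defaults[key], value, f"{path}{key}.")
        else:
            out[key] = value
    return out


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with strict key checking."""

    seed: int = 0
    output_dir: str = "osmoforge_run"
    stages: dict = field(default_factory=lambda: {
        "sedem": True, "doe": True, "kinetics": True, "pk": True})
    sedem: dict = field(default_factory=lambda: dict(_DEFAULT_SEDEM))
    doe: dict = field(default_factory=lambda: dict(_DEFAULT_DOE))
    kinetics: dict = field(default_factory=lambda: dict(_DEFAULT_KINETICS))
    pk: dict = field(default_factory=lambda: dict(_DEFAULT_PK))

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        known = {"seed", "output_dir", "stages", "sedem", "doe", "kinetics", "pk"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        if "output_dir" in raw:
            cfg.output_dir = str(raw["output_dir"])
        if "stages" in raw:
            bad = set(raw["stages"]) - set(cfg.stages)
            if bad:
                raise ConfigError(f"unknown stage names: {sorted(bad)}")
            cfg.stages.update({k: bool(v) for k, v in raw["stages"].items()})
        for section, defaults in (("sedem", _DEFAULT_SEDEM), ("doe", _DEFAULT_DOE),
                                  ("kinetics", _DEFAULT_KINETICS)):
            if section in raw:
                setattr(cfg, section, _merge(defaults, raw[section], ""))
        if "pk" in raw:
            cfg.pk = _merge(_DEFAULT_PK, raw["pk"], "pk.")
        return cfg

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
        return cls.from_dict(raw)


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _run_sedem_stage(cfg: PipelineConfig) -> dict:
    section = cfg.sedem
    measurements, truth = _synth.generate_powder(section["target_radii"],
                                                 noise=0.0, seed=cfg.seed)
    excip = {name: float(section["excipient_radius"])
             for name in _sedem.PARAMETER_ORDER}
    report = _sedem.profile_report(measurements, correction_excipient_radii=excip)
    report["synthetic_truth"] = json.loads(truth.to_json())
    return report


def _run_doe_stage(cfg: PipelineConfig) -> dict:
    section = cfg.doe
    design = _doe.build_design(int(section["k"]), seed=cfg.seed)
    models: dict[str, _doe.FittedModel] = {}
    out: dict = {"design": {"k": design.k, "n_runs": design.n_runs,
                            "run_order": design.run_order.tolist(),
                            "seed": design.seed},
                 "responses": {}}
    for name, beta in section["coefficients"].items():
        y, truth = _synth.generate_factorial_responses(
            design, beta, sigma=float(section["sigma"]), seed=cfg.seed)
        model = _doe.fit_main_effects(design, y, response=name)
        anova = _doe.anova_main_effects(model, design, y)
        models[name] = model
        out["responses"][name] = {
            "intercept": model.intercept,
            "coefficients": model.coefficients.tolist(),
            "r_squared": model.r_squared,
            "anova": anova,
            "generating_truth": json.loads(truth.to_json()),
        }
    goals = {name: _doe.ResponseGoal(**g) for name, g in section["constraints"].items()}
    spec = _doe.DesirabilitySpec(goals=goals)
    out["optimization"] = _doe.optimize_desirability(
        models, spec, resolution=float(section["grid_resolution"]))
    return out


def _run_kinetics_stage(cfg: PipelineConfig) -> dict:
    section = cfg.kinetics
    schedule = np.asarray(section["schedule_h"], dtype=float)
    out: dict = {"formulations": {}}
    profiles = {}
    for fid, spec in section["profiles"].items():
        profile, truth = _synth.generate_dissolution(
            spec["model"], spec["params"], schedule=schedule,
            noise=float(section["noise"]), seed=cfg.seed)
        profiles[fid] = profile
        fits = _rk.fit_all_models(profile, seed=cfg.seed)
        ranked = _rk.rank_models(fits)
        kp = next((r for r in fits if r.model == "korsmeyer_peppas" and r.converged), None)
        entry = {
            "truth": json.loads(truth.to_json()),
            "fits": {r.model: {"params": dict(r.params),
                               "r_squared": r.r_squared,
                               "aic": r.aic,
                               "converged": r.converged}
                     for r in fits},
            "best_model": ranked[0].model,
        }
        if kp is not None:
            entry["mechanism"] = _rk.classify_mechanism(kp.params["n"]).label
        out["formulations"][fid] = entry
    fids = list(profiles)
    out["f2"] = {}
    for i in range(len(fids)):
        for j in range(i + 1, len(fids)):
            sim = _rk.f2_similarity(profiles[fids[i]], profiles[fids[j]])
            out["f2"][f"{fids[i]}|{fids[j]}"] = {
                "f2": sim.f2, "n_points": sim.n_points,
                "truncated_points": sim.truncated_points,
            }
    return out


def _run_pk_stage(cfg: PipelineConfig) -> dict:
    section = cfg.pk
    d = _pk.DispositionParams(**section["disposition"])
    drug = _pk.DrugProperties(**section["drug"])
    transit = _pk.TransitModelConfig(**section["transit"])
    ir = section["ir_reference"]
    horizon = float(section["sim_horizon_h"])
    times = np.arange(0.0, horizon + 0.1, 0.1)

    ka_ir = _pk.calibrate_ka(d, float(ir["F"]), float(ir["dose_mg"]),
                             target_tmax_h=float(ir["target_tmax_h"]))
    ir_single = _pk.simulate_two_compartment_oral(
        d, ka_ir, float(ir["F"]), float(ir["dose_mg"]), times)
    ir_multi = _pk.superpose(ir_single, float(ir["interval_h"]), int(ir["n_doses"]))
    nca_ir_single = _pk.nca(ir_single)
    nca_ir_multi = _pk.nca(ir_multi)

    dur = float(section["cr_release_duration_h"])
    rel_times = np.linspace(0.0, dur, 33)
    release = _pk.ReleaseInput(times_h=rel_times,
                               fraction_released=rel_times / dur,
                               dose_mg=float(section["cr_dose_mg"]))
    transit_cfg = _pk.TransitModelConfig(
        n_intestinal=transit.n_intestinal,
        transit_time_h=transit.transit_time_h,
        gastric_emptying_rate=transit.gastric_emptying_rate,
        colon_absorption_scale=transit.colon_absorption_scale,
        intestinal_radius_cm=transit.intestinal_radius_cm,
        bioavailable_fraction=float(ir["F"]),
    )
    cr = _pk.transit_absorption_simulate(release, drug, d, transit_cfg, times)
    nca_cr = _pk.nca(cr.profile)

    def _nca_dict(r: _pk.NCAResult) -> dict:
        return {"Cmax": r.Cmax, "Tmax": r.Tmax, "AUCt": r.AUCt,
                "AUCinf": r.AUCinf, "lambda_z": r.lambda_z, "flags": list(r.flags)}

    out: dict = {
        "ka_ir_calibrated": ka_ir,
        "nca": {"ir_single": _nca_dict(nca_ir_single),
                "ir_multi": _nca_dict(nca_ir_multi),
                "cr_transit": _nca_dict(nca_cr)},
        "transit_mass_balance_error": cr.balance_error_max,
        "simulated_relative_bioavailability_pct": None,
        "relative_bioavailability_pct": {},
    }
    if nca_cr.AUCinf and nca_ir_multi.AUCinf:
        out["simulated_relative_bioavailability_pct"] = _pk.relative_bioavailability(
            nca_cr.AUCinf, release.dose_mg,
            nca_ir_multi.AUCinf, float(ir["dose_mg"]) * int(ir["n_doses"]))
    for name, comp in section["auc_comparisons"].items():
        out["relative_bioavailability_pct"][name] = _pk.relative_bioavailability(
            comp["auc_test"], comp["dose_test"], comp["auc_ref"], comp["dose_ref"])
    if d.CL < 0.05:
        out["validation_notes"] = [
            "clearance below the plausible range for a moderately cleared drug; "
            "parameters taken verbatim from input, not corrected"]
    return out


_STAGE_RUNNERS = {
    "sedem": _run_sedem_stage,
    "doe": _run_doe_stage,
    "kinetics": _run_kinetics_stage,
    "pk": _run_pk_stage,
}

_STAGE_ORDER = ("sedem", "doe", "kinetics", "pk")


def run_pipeline(config: PipelineConfig, *, write: bool = True) -> dict:
    """Run the enabled stages in order and assemble the run report.

    A stage failure halts downstream stages; partial results are preserved
    in the report (and on disk when ``write`` is set).
    """
    report: dict = {
        "provenance": {
            "package": "osmoforge",
            "version": __version__,
            "seed": config.seed,
            "config": {
                "seed": config.seed, "output_dir": config.output_dir,
                "stages": dict(config.stages), "sedem": config.sedem,
                "doe": config.doe, "kinetics": config.kinetics, "pk": config.pk,
            },
        },
        "stages": {},
        "halted_at": None,
    }
    outdir = config.output_dir
    if write:
        os.makedirs(outdir, exist_ok=True)
    for stage in _STAGE_ORDER:
        if not config.stages.get(stage, False):
            continue
        try:
            result = _STAGE_RUNNERS[stage](config)
        except Exception as exc:  # halt downstream, keep partials
            report["stages"][stage] = {"error": f"{type(exc).__name__}: {exc}"}
            report["halted_at"] = stage
            break
        report["stages"][stage] = result
        if write:
            with open(os.path.join(outdir, f"{stage}_report.json"), "w") as fh:
                json.dump(result, fh, indent=2, default=_json_default)
    if write:
        with open(os.path.join(outdir, "run_report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
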