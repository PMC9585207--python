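"""Synthetic input generators with persisted ground truth.

Every generator is the measurable inverse of an analysis stage: at zero
noise its output pushed through that stage returns the generating truth.
Each generator draws from its own seed-derived stream, so adding a call
never perturbs the output of another generator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np

from . import pk as _pk
from . import release_kinetics as _rk
from . import sedem as _sedem
from .doe import DesignMatrix

__all__ = [
    "SyntheticTruth",
    "SynthError",
    "UnreachableTargetError",
    "implied_density_radii",
    "generate_powder",
    "generate_dissolution",
    "generate_plasma",
    "generate_factorial_responses",
    "write_with_truth",
]

# stream tags keeping per-generator RNG streams independent at equal seeds
_STREAM = {"powder": 11, "dissolution": 23, "plasma": 37, "factorial": 53}


class SynthError(ValueError):
    """Invalid synthetic-data request."""


class UnreachableTargetError(SynthError):
    """Requested truth cannot be produced by any physical measurement."""


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters persisted next to every synthetic dataset."""

    kind: str
    params: Mapping[str, object]
    noise: float
    seed: int

    def to_json(self) -> str:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, Mapping):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v
        return json.dumps(_clean(asdict(self)), indent=2)


def _rng(kind: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_STREAM[kind], seed])


# --------------------------------------------------------------------------
# powder
# --------------------------------------------------------------------------

#: radii that can be dialed independently through raw measurements
_INDEPENDENT = ("Da", "Dc", "Icd", "alpha", "t_flow", "HR", "H", "Pf", "Itheta")
#: radii fully determined by the two density radii
_DEPENDENT = ("Ie", "IC", "IH")


def implied_density_radii(r_Da: float, r_Dc: float) -> dict[str, float]:
    """Radii of Ie, IC and IH implied by the bulk/tapped density radii."""
    Da = _sedem.inverse_linearize_value("Da", r_Da)
    Dc = _sedem.inverse_linearize_value("Dc", r_Dc)
    if not (Dc >= Da > 0):
        raise UnreachableTargetError(
            f"density radii imply Da={Da}, Dc={Dc}; require Dc >= Da > 0"
        )
    Ie = (Dc - Da) / (Dc * Da)
    IC = (Dc - Da) / Dc * 100.0
    IH = Dc / Da
    return {name: _sedem.linearize_value(name, v)
            for name, v in (("Ie", Ie), ("IC", IC), ("IH", IH))}


def generate_powder(target_radii: Mapping[str, float], *, noise: float = 0.0,
                    seed: int = 0, consistency_tol: float = 1e-6,
                    ) -> tuple[_sedem.PowderMeasurements, SyntheticTruth]:
    """Raw measurements that linearize to the requested radii at zero noise.

    ``target_radii`` must cover the nine independently adjustable radii;
    Ie, IC and IH follow from the density pair and, when also supplied,
    must agree with the implied values to ``consistency_tol``.  ``noise``
    is a relative Gaussian perturbation applied to the raw measurements.
    """
    for name in _INDEPENDENT:
        if name not in target_radii:
            raise SynthError(f"target radii must include {name!r}")
        r = target_radii[name]
        if not 0 <= r <= 10:
            raise SynthError(f"target radius {name}={r} outside [0, 10]")

    implied = implied_density_radii(target_radii["Da"], target_radii["Dc"])
    for name in _DEPENDENT:
        if name in target_radii and abs(target_radii[name] - implied[name]) > consistency_tol:
            raise UnreachableTargetError(
                f"target {name} radius {target_radii[name]} conflicts with the "
                f"value {implied[name]:.6f} implied by the density radii"
            )

    inv = _sedem.inverse_linearize_value
    Da = inv("Da", target_radii["Da"])
    Dc = inv("Dc", target_radii["Dc"])
    if Da <= 0:
        raise UnreachableTargetError("Da radius implies non-positive bulk density")
    mass = 10.0
    hardness = inv("Icd", target_radii["Icd"])
    if hardness <= 0:
        raise UnreachableTargetError("Icd radius implies non-positive hardness")
    alpha_deg = inv("alpha", target_radii["alpha"])
    cone_d = 8.0
    cone_h = cone_d * np.tan(np.radians(alpha_deg)) / 2.0
    if cone_h <= 0:
        raise UnreachableTargetError("alpha radius implies a flat (unmeasurable) cone")
    flow_t = inv("t_flow", target_radii["t_flow"])
    if flow_t <= 0:
        raise UnreachableTargetError("t_flow radius implies non-positive flow time")

    v_theta = inv("Itheta", target_radii["Itheta"])
    if v_theta <= 0:
        raise UnreachableTargetError("Itheta radius 0 needs an infinite diameter gap")
    # majority fraction of 60% at 100 um; the gap to the 40% fraction sets Itheta
    gap = (60.0 / v_theta - 100.0) / 40.0
    fractions = ((100.0, 60.0), (100.0 + gap, 40.0))

    m = _sedem.PowderMeasurements(
        sample_mass_g=mass,
        bulk_volume_ml=mass / Da,
        tapped_volume_ml=mass / Dc,
        tablet_hardness_N=hardness,
        cone_height_cm=cone_h,
        cone_diameter_cm=cone_d,
        flow_time_s=flow_t,
        loss_on_drying_pct=inv("HR", target_radii["HR"]),
        hygroscopicity_pct=inv("H", target_radii["H"]),
        fines_pct=inv("Pf", target_radii["Pf"]),
        sieve_fractions=fractions,
    )
    if noise > 0:
        rng = _rng("powder", seed)
        def jitter(v, lo=1e-9, hi=None):
            out = v * (1.0 + noise * rng.standard_normal())
            out = max(out, lo)
            return min(out, hi) if hi is not None else out
        bulk = jitter(m.bulk_volume_ml)
        m = _sedem.PowderMeasurements(
            sample_mass_g=m.sample_mass_g,
            bulk_volume_ml=bulk,
            tapped_volume_ml=min(jitter(m.tapped_volume_ml), bulk),
            tablet_hardness_N=jitter(m.tablet_hardness_N),
            cone_height_cm=jitter(m.cone_height_cm),
            cone_diameter_cm=jitter(m.cone_diameter_cm),
            flow_time_s=jitter(m.flow_time_s),
            loss_on_drying_pct=jitter(m.loss_on_drying_pct, 0.0, 100.0),
            hygroscopicity_pct=jitter(m.hygroscopicity_pct, 0.0, 100.0),
            fines_pct=jitter(m.fines_pct, 0.0, 100.0),
            sieve_fractions=m.sieve_fractions,
        )
    truth = SyntheticTruth(kind="powder", params={"target_radii": dict(target_radii)},
                           noise=noise, seed=seed)
    return m, truth


# --------------------------------------------------------------------------
# dissolution
# --------------------------------------------------------------------------

def generate_dissolution(model: str, params: Mapping[str, float], *,
                         schedule: Sequence[float] | None = None,
                         noise: float = 0.0, seed: int = 0,
                         stage_boundary_h: float = 2.0,
                         ) -> tuple[_rk.DissolutionProfile, SyntheticTruth]:
    """Dissolution profile from a named kinetic model plus additive noise.

    Default schedule is hourly over 0-24 h.  Two-stage medium annotations
    (pH 1.2 before the boundary, pH 6.8 after) are attached as metadata.
    ``noise`` is the additive standard deviation in % of label claim.
    """
    t = np.asarray(schedule if schedule is not None else np.arange(0.0, 25.0), float)
    if np.any(np.diff(t) <= 0):
        raise SynthError("schedule must be strictly increasing")
    f = _rk.predict_release(model, params, t)
    if noise > 0:
        rng = _rng("dissolution", seed)
        f = f + noise * rng.standard_normal(t.size)
    f = np.clip(f, 0.0, 110.0)
    ph = np.where(t <= stage_boundary_h, 1.2, 6.8)
    profile = _rk.DissolutionProfile(times_h=t, release_pct=f, ph=ph, rpm=75.0,
                                     formulation_id=f"synthetic-{model}")
    truth = SyntheticTruth(kind="dissolution",
                           params={"model": model, "params": dict(params),
                                   "schedule": t, "stage_boundary_h": stage_boundary_h},
                           noise=noise, seed=seed)
    return profile, truth


# --------------------------------------------------------------------------
# plasma
# --------------------------------------------------------------------------

def generate_plasma(d: _pk.DispositionParams, ka: float, F: float, dose_mg: float,
                    times: Sequence[float], *, cv: float = 0.1, seed: int = 0,
                    ) -> tuple[_pk.PlasmaProfile, SyntheticTruth]:
    """Closed-form two-compartment profile with mean-one log-normal error."""
    clean = _pk.simulate_two_compartment_oral(d, ka, F, dose_mg, times)
    conc = clean.conc_ng_ml
    if cv > 0:
        rng = _rng("plasma", seed)
        sigma = np.sqrt(np.log1p(cv * cv))
        conc = conc * np.exp(sigma * rng.standard_normal(conc.size) - sigma * sigma / 2.0)
    profile = _pk.PlasmaProfile(times_h=clean.times_h, conc_ng_ml=conc,
                                regimen=clean.regimen + " (synthetic)")
    truth = SyntheticTruth(kind="plasma",
                           params={"Vc": d.Vc, "k12": d.k12, "k21": d.k21,
                                   "CL": d.CL, "body_weight": d.body_weight,
                                   "ka": ka, "F": F, "dose_mg": dose_mg},
                           noise=cv, seed=seed)
    return profile, truth


# --------------------------------------------------------------------------
# factorial responses
# --------------------------------------------------------------------------

def generate_factorial_responses(design: DesignMatrix, coefficients: Sequence[float],
                                 sigma: float = 0.0, seed: int = 0,
                                 ) -> tuple[np.ndarray, SyntheticTruth]:
    """Responses y = X beta + N(0, sigma^2) on a coded design.

    ``coefficients`` is (intercept, beta_1 .. beta_k).
    """
    beta = np.asarray(coefficients, dtype=float)
    if beta.size != design.k + 1:
        raise SynthError(
            f"need {design.k + 1} coefficients (intercept + {design.k} effects), "
            f"got {beta.size}"
        )
    X = np.column_stack([np.ones(design.n_runs), design.coded])
    y = X @ beta
    if sigma > 0:
        rng = _rng("factorial", seed)
        y = y + sigma * rng.standard_normal(y.size)
    truth = SyntheticTruth(kind="factorial",
                           params={"coefficients": beta, "k": design.k,
                                   "design_seed": design.seed},
                           noise=sigma, seed=seed)
    return y, truth


# --------------------------------------------------------------------------
# sidecar io
# --------------------------------------------------------------------------

def write_with_truth(data_path, truth: SyntheticTruth, writer) -> None:
    """Write a dataset via ``writer(data_path)`` plus its ``*.truth.json`` sidecar."""
    writer(data_path)
    sidecar = str(data_path) + ".truth.json"
    with open(sidecar, "w") as fh:
        fh.write(truth.to_json())
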