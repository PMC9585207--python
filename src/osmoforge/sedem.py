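"""Powder micromeritics scoring on the 12-parameter SeDeM diagram.

Raw bench measurements (densities, compact hardness, repose-cone geometry,
funnel flow time, moisture, sieve analysis) are converted to the 12 standard
SeDeM parameters, linearized onto a common 0-10 "radius" scale, aggregated
into diagram indices (IP, IPP, IGC) and, where a parameter is deficient,
translated into a corrective-excipient fraction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PARAMETER_ORDER",
    "INCIDENCE_GROUPS",
    "PowderMeasurements",
    "DerivedParameters",
    "SeDeMProfile",
    "SeDeMIndices",
    "CorrectionPlan",
    "SedemError",
    "InfeasibleCorrectionError",
    "ExcipientInsufficientError",
    "compute_micromeritic_parameters",
    "homogeneity_index",
    "linearize_profile",
    "linearize_value",
    "inverse_linearize_value",
    "compute_indices",
    "reliability_factor",
    "corrective_excipient_fraction",
    "radar_chart_data",
    "profile_report",
]

#: Canonical diagram order (clockwise on the radar chart).
PARAMETER_ORDER: tuple[str, ...] = (
    "Da", "Dc",                 # dimension
    "Ie", "IC", "Icd",          # compressibility
    "IH", "alpha", "t_flow",    # flowability / powder flow
    "HR", "H",                  # lubricity / stability
    "Pf", "Itheta",             # lubricity / dosage
)

INCIDENCE_GROUPS: dict[str, tuple[str, ...]] = {
    "dimension": ("Da", "Dc"),
    "compressibility": ("Ie", "IC", "Icd"),
    "flowability": ("IH", "alpha", "t_flow"),
    "lubricity_stability": ("HR", "H"),
    "lubricity_dosage": ("Pf", "Itheta"),
}

#: Published reliability factor for the standard 12-parameter diagram.
RELIABILITY_FACTOR_12 = 0.952

#: Radius threshold below which a parameter is considered deficient.
ACCEPTANCE_RADIUS = 5.0


class SedemError(ValueError):
    """Invalid input to a SeDeM computation."""


class InfeasibleCorrectionError(SedemError):
    """Corrective excipient is not better than the powder (RE <= RP)."""


class ExcipientInsufficientError(SedemError):
    """Corrective excipient cannot reach the required radius (RE < R)."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PowderMeasurements:
    """Raw bench measurements for one powder or blend.

    ``sieve_fractions`` is a sequence of ``(mean_diameter_um, mass_pct)``
    pairs; the 355/212/100/50 um sieve series is the usual schema but any
    series is accepted.
    """

    sample_mass_g: float
    bulk_volume_ml: float
    tapped_volume_ml: float
    tablet_hardness_N: float
    cone_height_cm: float
    cone_diameter_cm: float
    flow_time_s: float
    loss_on_drying_pct: float
    hygroscopicity_pct: float
    fines_pct: float
    sieve_fractions: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        positive = {
            "sample_mass_g": self.sample_mass_g,
            "bulk_volume_ml": self.bulk_volume_ml,
            "tapped_volume_ml": self.tapped_volume_ml,
            "tablet_hardness_N": self.tablet_hardness_N,
            "cone_height_cm": self.cone_height_cm,
            "cone_diameter_cm": self.cone_diameter_cm,
            "flow_time_s": self.flow_time_s,
        }
        for name, value in positive.items():
            if not value > 0:
                raise SedemError(f"{name} must be strictly positive, got {value!r}")
        if self.tapped_volume_ml > self.bulk_volume_ml:
            raise SedemError(
                "tapped_volume_ml must not exceed bulk_volume_ml "
                f"({self.tapped_volume_ml} > {self.bulk_volume_ml})"
            )
        for name, value in (
            ("loss_on_drying_pct", self.loss_on_drying_pct),
            ("hygroscopicity_pct", self.hygroscopicity_pct),
            ("fines_pct", self.fines_pct),
        ):
            if not 0 <= value <= 100:
                raise SedemError(f"{name} must lie in [0, 100], got {value!r}")
        if self.sieve_fractions:
            total = sum(p for _, p in self.sieve_fractions)
            if abs(total - 100.0) > 0.5:
                raise SedemError(
                    f"sieve fraction percentages must sum to 100 +/- 0.5, got {total}"
                )
        object.__setattr__(self, "sieve_fractions", tuple(
            (float(d), float(p)) for d, p in self.sieve_fractions
        ))


@dataclass(frozen=True)
class DerivedParameters:
    """The 12 SeDeM parameters in their measurement units."""

    Da: float          # bulk density, g/ml
    Dc: float          # tapped density, g/ml
    Ie: float          # inter-particle porosity, dimensionless
    IC: float          # Carr's compressibility index, %
    Icd: float         # cohesion index (compact hardness), N
    IH: float          # Hausner ratio, dimensionless
    alpha: float       # angle of repose, degrees
    t_flow: float      # funnel flow time for 100 g, s
    HR: float          # loss on drying, %
    H: float           # hygroscopicity, %
    Pf: float          # fines (<50 um), %
    Itheta: float      # particle-size homogeneity index, dimensionless

    def __post_init__(self) -> None:
        if not (self.Dc >= self.Da > 0):
            raise SedemError(f"require Dc >= Da > 0, got Da={self.Da}, Dc={self.Dc}")
        if self.IH < 1:
            raise SedemError(f"Hausner ratio must be >= 1, got {self.IH}")
        if not 0 <= self.IC < 100:
            raise SedemError(f"Carr index must lie in [0, 100), got {self.IC}")
        if not 0 <= self.alpha < 90:
            raise SedemError(f"angle of repose must lie in [0, 90), got {self.alpha}")
        if self.Itheta < 0:
            raise SedemError(f"homogeneity index must be >= 0, got {self.Itheta}")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_ORDER}


@dataclass(frozen=True)
class SeDeMProfile:
    """Linearized diagram: 12 named radii on the 0-10 scale."""

    radii: Mapping[str, float]
    incidence_groups: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(INCIDENCE_GROUPS)
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "radii", dict(self.radii))
        missing = [n for n in PARAMETER_ORDER if n not in self.radii]
        extra = [n for n in self.radii if n not in PARAMETER_ORDER]
        if missing or extra:
            raise SedemError(
                f"profile must carry exactly the 12 diagram parameters; "
                f"missing={missing}, unexpected={extra}"
            )
        for name, r in self.radii.items():
            if not 0 <= r <= 10:
                raise SedemError(f"radius {name}={r} outside [0, 10]")

    def ordered_radii(self) -> np.ndarray:
        return np.array([self.radii[n] for n in PARAMETER_ORDER], dtype=float)


@dataclass(frozen=True)
class SeDeMIndices:
    IP: float
    IPP: float
    f: float
    IGC: float
    deficient_parameters: tuple[str, ...]
    incidence_means: Mapping[str, float]


@dataclass(frozen=True)
class CorrectionPlan:
    CP_pct: float
    RE: float
    RP: float
    R: float


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def compute_micromeritic_parameters(m: PowderMeasurements) -> DerivedParameters:
    """Derive the 12 SeDeM parameters from raw measurements.

    Densities come from mass over bulk/tapped volume; the porosity, Carr
    and Hausner indices follow from the two densities; the repose angle
    from the cone geometry (``tan(alpha) = 2h/d``); hardness, flow time,
    moisture and fines pass through unchanged; the homogeneity index is
    computed from the sieve analysis.
    """
    Da = m.sample_mass_g / m.bulk_volume_ml
    Dc = m.sample_mass_g / m.tapped_volume_ml
    Ie = (Dc - Da) / (Dc * Da)
    IC = (Dc - Da) / Dc * 100.0
    IH = Dc / Da
    alpha = math.degrees(math.atan(2.0 * m.cone_height_cm / m.cone_diameter_cm))
    Itheta = homogeneity_index(m.sieve_fractions) if m.sieve_fractions else 0.0
    return DerivedParameters(
        Da=Da, Dc=Dc, Ie=Ie, IC=IC, Icd=m.tablet_hardness_N, IH=IH,
        alpha=alpha, t_flow=m.flow_time_s, HR=m.loss_on_drying_pct,
        H=m.hygroscopicity_pct, Pf=m.fines_pct, Itheta=Itheta,
    )


def homogeneity_index(fractions: Sequence[tuple[float, float]]) -> float:
    """Particle-size homogeneity index from a sieve analysis.

    ``fractions`` is a sequence of ``(mean_diameter_um, mass_pct)``.  With
    ``Fm`` the mass percentage of the majority fraction and ``dm`` its mean
    diameter, the index is::

        Itheta = Fm / (100 + sum_i |d_i - dm| * F_i)   over i != m

    i.e. the majority share damped by diameter-gap-weighted off-mode mass.
    All mass in a single fraction gives exactly ``Fm/100``.
    """
    if not fractions:
        raise SedemError("sieve analysis requires at least one fraction")
    for d, p in fractions:
        if p < 0:
            raise SedemError(f"negative mass percentage {p} at diameter {d}")
        if d <= 0:
            raise SedemError(f"non-positive sieve diameter {d}")
    m_idx = max(range(len(fractions)), key=lambda i: fractions[i][1])
    dm, Fm = fractions[m_idx]
    denom = 100.0
    for i, (d, p) in enumerate(fractions):
        if i == m_idx:
            continue
        denom += abs(d - dm) * p
    return Fm / denom


# Table of (slope, offset) for the affine map radius = slope * v + offset.
_LINEARIZATION: dict[str, tuple[float, float]] = {
    "Da": (10.0, 0.0),
    "Dc": (10.0, 0.0),
    "Ie": (10.0 / 1.2, 0.0),
    "IC": (1.0 / 5.0, 0.0),
    "Icd": (1.0 / 20.0, 0.0),
    "IH": (-5.0, 15.0),        # 5 * (3 - v)
    "alpha": (-1.0 / 5.0, 10.0),
    "t_flow": (-1.0 / 2.0, 10.0),
    "HR": (-1.0, 10.0),
    "H": (-1.0 / 2.0, 10.0),
    "Pf": (-1.0 / 5.0, 10.0),
    "Itheta": (500.0, 0.0),
}


def linearize_value(name: str, v: float) -> float:
    """Map one measured parameter value to its radius, clamped to [0, 10]."""
    try:
        slope, offset = _LINEARIZATION[name]
    except KeyError:
        raise SedemError(f"unknown SeDeM parameter {name!r}") from None
    return float(min(10.0, max(0.0, slope * v + offset)))


def inverse_linearize_value(name: str, radius: float) -> float:
    """Measured value whose radius equals ``radius`` (exact for interior radii)."""
    slope, offset = _LINEARIZATION[name]
    return (radius - offset) / slope


def linearize_profile(p: DerivedParameters) -> SeDeMProfile:
    """Linearize all 12 derived parameters onto the 0-10 radius scale."""
    radii = {name: linearize_value(name, v) for name, v in p.as_dict().items()}
    return SeDeMProfile(radii=radii)


def reliability_factor(n: int = 12) -> float:
    """Reliability factor f for an n-parameter diagram.

    For the standard 12-parameter diagram the published constant 0.952 is
    returned so that downstream IGC values match the literature; for any
    other n the regular-polygon/circle area ratio ``n*sin(2*pi/n)/(2*pi)``
    (which gives 0.9549 at n=12) is used.
    """
    if n < 3:
        raise SedemError(f"reliability factor undefined for n={n} (< 3)")
    if n == 12:
        return RELIABILITY_FACTOR_12
    return n * math.sin(2.0 * math.pi / n) / (2.0 * math.pi)


def compute_indices(profile: SeDeMProfile, *, allow_generalized: bool = False) -> SeDeMIndices:
    """Aggregate a linearized profile into the diagram indices.

    IP is the fraction of radii at or above the acceptance value 5; IPP is
    the arithmetic mean radius; IGC = IPP * f with f the reliability factor.
    Profiles with other than 12 radii are rejected unless
    ``allow_generalized`` is set (SeDeMProfile enforces 12, so the flag only
    matters for duck-typed inputs).
    """
    radii = dict(profile.radii)
    n = len(radii)
    if n != 12 and not allow_generalized:
        raise SedemError(
            f"expected a 12-parameter profile, got {n}; "
            "pass allow_generalized=True to score anyway"
        )
    values = np.array(list(radii.values()), dtype=float)
    IP = float(np.count_nonzero(values >= ACCEPTANCE_RADIUS)) / n
    IPP = float(values.mean())
    f = reliability_factor(n)
    IGC = IPP * f
    deficient = tuple(
        name for name in PARAMETER_ORDER
        if name in radii and radii[name] < ACCEPTANCE_RADIUS
    )
    groups = profile.incidence_groups if hasattr(profile, "incidence_groups") else INCIDENCE_GROUPS
    incidence_means = {
        group: float(np.mean([radii[p] for p in params if p in radii]))
        for group, params in groups.items()
        if any(p in radii for p in params)
    }
    return SeDeMIndices(
        IP=IP, IPP=IPP, f=f, IGC=IGC,
        deficient_parameters=deficient,
        incidence_means=incidence_means,
    )


def corrective_excipient_fraction(RE: float, RP: float, R: float = ACCEPTANCE_RADIUS) -> CorrectionPlan:
    """Minimum corrective-excipient percentage to raise a deficient radius.

    ``CP = 100 - (RE - R) / (RE - RP) * 100`` where RE is the excipient's
    radius, RP the powder's deficient radius and R the required minimum.
    """
    if RE <= RP:
        raise InfeasibleCorrectionError(
            f"excipient radius RE={RE} must exceed powder radius RP={RP}"
        )
    if RE < R:
        raise ExcipientInsufficientError(
            f"excipient radius RE={RE} below required radius R={R}"
        )
    CP = 100.0 - (RE - R) / (RE - RP) * 100.0
    CP = float(min(100.0, max(0.0, CP)))
    return CorrectionPlan(CP_pct=CP, RE=float(RE), RP=float(RP), R=float(R))


def radar_chart_data(profile: SeDeMProfile) -> tuple[np.ndarray, float]:
    """Polygon vertices and shoelace area of the diagram.

    Axes are equally spaced, the first at 12 o'clock, proceeding clockwise
    in canonical parameter order.  Returns ``(vertices, area)`` with
    ``vertices`` an (n, 2) array.
    """
    r = profile.ordered_radii()
    n = r.size
    theta = np.pi / 2.0 - 2.0 * np.pi * np.arange(n) / n   # clockwise from top
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    return np.column_stack([x, y]), area


# --------------------------------------------------------------------------
# reporting / io
# --------------------------------------------------------------------------

def profile_report(m: PowderMeasurements, *, correction_excipient_radii: Mapping[str, float] | None = None) -> dict:
    """Full JSON-serializable scoring report for one sample.

    ``correction_excipient_radii`` optionally maps deficient parameter names
    to the radius of the corrective excipient; a correction plan is emitted
    for every deficient parameter it covers.
    """
    derived = compute_micromeritic_parameters(m)
    profile = linearize_profile(derived)
    indices = compute_indices(profile)
    _, area = radar_chart_data(profile)
    report = {
        "derived_parameters": {k: round(v, 6) for k, v in derived.as_dict().items()},
        "radii": {k: round(profile.radii[k], 2) for k in PARAMETER_ORDER},
        "indices": {
            "IP": round(indices.IP, 2),
            "IPP": round(indices.IPP, 2),
            "f": indices.f,
            "IGC": round(indices.IGC, 2),
        },
        "incidence_means": {k: round(v, 2) for k, v in indices.incidence_means.items()},
        "deficient_parameters": list(indices.deficient_parameters),
        "polygon_area": round(area, 4),
        "correction_plans": {},
    }
    if correction_excipient_radii:
        for name in indices.deficient_parameters:
            if name in correction_excipient_radii:
                plan = corrective_excipient_fraction(
                    correction_excipient_radii[name], profile.radii[name]
                )
                report["correction_plans"][name] = {
                    "CP_pct": round(plan.CP_pct, 2),
                    "RE": plan.RE, "RP": round(plan.RP, 2), "R": plan.R,
                }
    return report


def read_measurements_csv(path, sieve_path=None) -> dict[str, PowderMeasurements]:
    """Load per-sample measurements (and optional long-format sieve table)."""
    import pandas as pd

    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise SedemError("measurements CSV must carry a sample_id column")
    required = [
        "sample_mass_g", "bulk_volume_ml", "tapped_volume_ml",
        "tablet_hardness_N", "cone_height_cm", "cone_diameter_cm",
        "flow_time_s", "loss_on_drying_pct", "hygroscopicity_pct", "fines_pct",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SedemError(f"measurements CSV missing columns: {missing}")
    sieves: dict[str, list[tuple[float, float]]] = {}
    if sieve_path is not None:
        sf = pd.read_csv(sieve_path)
        for col in ("sample_id", "mean_diameter_um", "mass_pct"):
            if col not in sf.columns:
                raise SedemError(f"sieve CSV missing column: {col}")
        for sid, grp in sf.groupby("sample_id"):
            sieves[str(sid)] = list(zip(grp["mean_diameter_um"], grp["mass_pct"]))
    out = {}
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        out[sid] = PowderMeasurements(
            **{c: float(row[c]) for c in required},
            sieve_fractions=tuple(sieves.get(sid, ())),
        )
    return out


def write_radar_svg(profile: SeDeMProfile, path) -> None:
    """Render the diagram as a radar (spider) SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = profile.ordered_radii()
    n = r.size
    theta = np.pi / 2.0 - 2.0 * np.pi * np.arange(n + 1) / n
    rr = np.append(r, r[0])
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    ax.plot(theta, rr, lw=1.5)
    ax.fill(theta, rr, alpha=0.25)
    ax.set_ylim(0, 10)
    ax.set_xticks(np.pi / 2.0 - 2.0 * np.pi * np.arange(n) / n)
    ax.set_xticklabels(PARAMETER_ORDER, fontsize=8)
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)


def write_report_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
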