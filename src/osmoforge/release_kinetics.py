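"""Dissolution-kinetics model fitting, mechanism classification and f2.

Seven classical release models (zero-order, first-order, Higuchi,
Korsmeyer-Peppas, Hixson-Crowell, Baker-Lonsdale, Weibull) are fitted by
untransformed nonlinear least squares with multi-start initial guesses,
ranked by goodness of fit, and release mechanism is classified from the
Korsmeyer-Peppas exponent.  Profile pairs are compared with the f2
similarity factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "MODELS",
    "MODEL_PARAM_NAMES",
    "DissolutionProfile",
    "KineticFitResult",
    "MechanismClass",
    "SimilarityResult",
    "KineticsError",
    "predict_release",
    "fit_model",
    "fit_all_models",
    "classify_mechanism",
    "f2_similarity",
    "rank_models",
]


class KineticsError(ValueError):
    """Invalid input to a dissolution-kinetics operation."""


MODEL_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "zero_order": ("k0",),
    "first_order": ("k1",),
    "higuchi": ("kH",),
    "korsmeyer_peppas": ("kKP", "n"),
    "hixson_crowell": ("kHC",),
    "baker_lonsdale": ("kBL",),
    "weibull": ("alpha", "beta"),
}

MODELS: tuple[str, ...] = tuple(MODEL_PARAM_NAMES)


@dataclass(frozen=True)
class DissolutionProfile:
    """Cumulative-release time course with medium annotations."""

    times_h: np.ndarray
    release_pct: np.ndarray
    ph: np.ndarray | None = None
    rpm: float | None = None
    formulation_id: str = ""
    #: indices where cumulative release decreases by more than the tolerance
    monotonicity_violations: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        f = np.asarray(self.release_pct, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise KineticsError("times and release must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise KineticsError("time points must be strictly increasing")
        if np.any(f < 0) or np.any(f > 110):
            raise KineticsError("release values must lie in [0, 110] % of label claim")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "release_pct", f)
        viol = tuple(int(i) for i in np.nonzero(np.diff(f) < -0.5)[0] + 1)
        object.__setattr__(self, "monotonicity_violations", viol)


@dataclass(frozen=True)
class KineticFitResult:
    model: str
    params: Mapping[str, float]
    r_squared: float
    adj_r_squared: float
    aic: float
    residuals: np.ndarray
    converged: bool
    notes: tuple[str, ...] = ()

    @property
    def n_params(self) -> int:
        return len(MODEL_PARAM_NAMES[self.model])


@dataclass(frozen=True)
class MechanismClass:
    label: str   # fickian | anomalous | case_ii | super_case_ii
    n: float


@dataclass(frozen=True)
class SimilarityResult:
    f2: float
    n_points: int
    truncated_points: int


# --------------------------------------------------------------------------
# forward models
# --------------------------------------------------------------------------

def _baker_lonsdale_lhs(frac: float) -> float:
    return 1.5 * (1.0 - (1.0 - frac) ** (2.0 / 3.0)) - frac


def predict_release(model: str, params: Mapping[str, float], times: Sequence[float]) -> np.ndarray:
    """Evaluate a named release model at the given times (hours).

    Returns cumulative release in percent of label claim.  The
    Hixson-Crowell cube-root law is capped at 100% beyond its domain
    (kHC*t > 1); Baker-Lonsdale is inverted numerically by bracketed
    root finding.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise KineticsError("times must be non-negative")
    p = dict(params)
    for name in MODEL_PARAM_NAMES.get(model, ()):
        if name not in p:
            raise KineticsError(f"model {model!r} requires parameter {name!r}")

    if model == "zero_order":
        return p["k0"] * t
    if model == "first_order":
        return 100.0 * (1.0 - np.exp(-p["k1"] * t))
    if model == "higuchi":
        return p["kH"] * np.sqrt(t)
    if model == "korsmeyer_peppas":
        return p["kKP"] * np.power(t, p["n"])
    if model == "hixson_crowell":
        core = 1.0 - p["kHC"] * t
        F = np.where(core > 0.0, 100.0 * (1.0 - np.clip(core, 0.0, None) ** 3), 100.0)
        return F
    if model == "baker_lonsdale":
        rhs = p["kBL"] * t
        out = np.empty_like(rhs)
        for i, r in np.ndenumerate(rhs):
            if r <= 0.0:
                out[i] = 0.0
            elif r >= 0.5:          # LHS maximum at complete release
                out[i] = 100.0
            else:
                frac = optimize.brentq(lambda x: _baker_lonsdale_lhs(x) - r, 0.0, 1.0,
                                       xtol=1e-13, rtol=1e-14)
                out[i] = 100.0 * frac
        return out
    if model == "weibull":
        return 100.0 * (1.0 - np.exp(-np.power(t, p["beta"]) / p["alpha"]))
    raise KineticsError(f"unknown model {model!r}; expected one of {MODELS}")


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def _initial_guess(model: str, t: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Closed-form transform guesses (log/loglog linearizations)."""
    pos = (t > 0) & (f > 0)
    tp, fp = t[pos], np.clip(f[pos], 1e-6, None)
    if tp.size == 0:
        tp, fp = np.array([1.0]), np.array([1.0])
    frac = np.clip(fp / 100.0, 1e-6, 1.0 - 1e-6)
    if model == "zero_order":
        return np.array([np.mean(fp / tp)])
    if model == "first_order":
        slope = np.polyfit(tp, -np.log(1.0 - frac), 1)[0]
        return np.array([max(slope, 1e-4)])
    if model == "higuchi":
        return np.array([np.mean(fp / np.sqrt(tp))])
    if model == "korsmeyer_peppas":
        n, logk = np.polyfit(np.log(tp), np.log(fp), 1)
        return np.array([math.exp(logk), min(max(n, 0.05), 1.9)])
    if model == "hixson_crowell":
        return np.array([np.mean((1.0 - (1.0 - frac) ** (1.0 / 3.0)) / tp)])
    if model == "baker_lonsdale":
        return np.array([np.mean([_baker_lonsdale_lhs(x) for x in frac] / tp)])
    if model == "weibull":
        y = np.log(-np.log(1.0 - frac))
        beta, c = np.polyfit(np.log(tp), y, 1)
        beta = min(max(beta, 0.05), 5.0)
        return np.array([math.exp(-c), beta])
    raise KineticsError(f"unknown model {model!r}")


_BOUNDS: dict[str, tuple[np.ndarray, np.ndarray]] = {
    "zero_order": (np.array([1e-8]), np.array([1e3])),
    "first_order": (np.array([1e-8]), np.array([1e2])),
    "higuchi": (np.array([1e-8]), np.array([1e3])),
    "korsmeyer_peppas": (np.array([1e-8, 1e-3]), np.array([1e3, 2.0])),
    "hixson_crowell": (np.array([1e-8]), np.array([1e2])),
    "baker_lonsdale": (np.array([1e-8]), np.array([1e2])),
    "weibull": (np.array([1e-6, 1e-3]), np.array([1e6, 10.0])),
}


def fit_model(profile: DissolutionProfile, model: str, *, n_restarts: int = 5,
              seed: int = 0) -> KineticFitResult:
    """Fit one release model by untransformed nonlinear least squares.

    The initial guess comes from the model's closed-form linearization and
    is followed by ``n_restarts`` log-normally jittered restarts; the best
    converged solution wins.  Fails loudly (``converged=False``, NaN
    statistics) if no start converges.
    """
    if model not in MODEL_PARAM_NAMES:
        raise KineticsError(f"unknown model {model!r}; expected one of {MODELS}")
    t, f = profile.times_h, profile.release_pct
    n_par = len(MODEL_PARAM_NAMES[model])
    if t.size < n_par + 2:
        raise KineticsError(
            f"need at least {n_par + 2} points to fit {model}, got {t.size}"
        )
    lo, hi = _BOUNDS[model]
    base = np.clip(_initial_guess(model, t, f), lo, hi)
    rng = np.random.default_rng(seed)
    starts = [base] + [np.clip(base * np.exp(rng.normal(0, 0.5, base.size)), lo, hi)
                       for _ in range(n_restarts)]

    def residual(theta: np.ndarray) -> np.ndarray:
        p = dict(zip(MODEL_PARAM_NAMES[model], theta))
        return predict_release(model, p, t) - f

    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(residual, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if not sol.success:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    notes = []
    if np.any(f > 100):
        notes.append("release exceeds 100% at some points")
    if profile.monotonicity_violations:
        notes.append(f"non-monotone release at indices {profile.monotonicity_violations}")
    if best is None:
        return KineticFitResult(
            model=model, params={}, r_squared=float("nan"),
            adj_r_squared=float("nan"), aic=float("nan"),
            residuals=np.full_like(f, np.nan), converged=False,
            notes=tuple(notes) + ("no start converged",),
        )
    params = dict(zip(MODEL_PARAM_NAMES[model], (float(v) for v in best.x)))
    resid = residual(best.x)
    ss_res = float(resid @ resid)
    ss_tot = float(((f - f.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    n = t.size
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_par - 1) if n > n_par + 1 else float("nan")
    aic = n * math.log(max(ss_res, 1e-300) / n) + 2 * n_par
    return KineticFitResult(
        model=model, params=params, r_squared=r2, adj_r_squared=adj,
        aic=aic, residuals=resid, converged=True, notes=tuple(notes),
    )


def fit_all_models(profile: DissolutionProfile, models: Sequence[str] = MODELS,
                   **kwargs) -> list[KineticFitResult]:
    return [fit_model(profile, m, **kwargs) for m in models]


def classify_mechanism(n: float) -> MechanismClass:
    """Release-mechanism class from the Korsmeyer-Peppas exponent.

    n <= 0.5 Fickian diffusion; 0.5 < n <= 0.85 anomalous transport;
    0.85 < n <= 1 case-II (zero-order) transport; n > 1 super case-II.
    """
    if not n > 0:
        raise KineticsError(f"release exponent must be positive, got {n}")
    if n <= 0.5:
        label = "fickian"
    elif n <= 0.85:
        label = "anomalous"
    elif n <= 1.0:
        label = "case_ii"
    else:
        label = "super_case_ii"
    return MechanismClass(label=label, n=float(n))


def f2_similarity(reference: DissolutionProfile, test: DissolutionProfile, *,
                  truncate_at_85: bool = True) -> SimilarityResult:
    """f2 similarity factor between two profiles on an identical time grid.

    ``f2 = 50 log10(100 / sqrt(1 + mean((R - T)^2)))``.  Under the
    regulatory convention (default) at most one reference point beyond 85%
    release enters the comparison.
    """
    if reference.times_h.shape != test.times_h.shape or \
            not np.allclose(reference.times_h, test.times_h):
        raise KineticsError("profiles must share an identical time grid")
    R, T = reference.release_pct, test.release_pct
    n_total = R.size
    truncated = 0
    if truncate_at_85:
        beyond = np.nonzero(R > 85.0)[0]
        if beyond.size > 1:
            keep = beyond[0] + 1          # keep exactly one point beyond 85%
            truncated = n_total - keep
            R, T = R[:keep], T[:keep]
    if R.size < 3:
        raise KineticsError(f"need at least 3 comparable points, got {R.size}")
    msd = float(np.mean((R - T) ** 2))
    f2 = 50.0 * math.log10(100.0 / math.sqrt(1.0 + msd))
    return SimilarityResult(f2=f2, n_points=int(R.size), truncated_points=int(truncated))


def rank_models(results: Sequence[KineticFitResult]) -> list[KineticFitResult]:
    """Rank fits by r^2 (descending); ties by fewer parameters, then AIC."""
    ok = [r for r in results if r.converged]
    if not ok:
        raise KineticsError("no successful fits to rank")
    return sorted(ok, key=lambda r: (-r.r_squared, r.n_params, r.aic))


# --------------------------------------------------------------------------
# io
# --------------------------------------------------------------------------

def read_profiles_csv(path) -> dict[str, DissolutionProfile]:
    """Load long-format profiles (formulation_id, time_h, release_pct[, pH, rpm])."""
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("formulation_id", "time_h", "release_pct"):
        if col not in df.columns:
            raise KineticsError(f"profiles CSV missing column: {col}")
    out = {}
    for fid, grp in df.groupby("formulation_id"):
        grp = grp.sort_values("time_h")
        out[str(fid)] = DissolutionProfile(
            times_h=grp["time_h"].to_numpy(float),
            release_pct=grp["release_pct"].to_numpy(float),
            ph=grp["pH"].to_numpy(float) if "pH" in grp.columns else None,
            rpm=float(grp["rpm"].iloc[0]) if "rpm" in grp.columns else None,
            formulation_id=str(fid),
        )
    return out


def fits_table(per_formulation: Mapping[str, Sequence[KineticFitResult]]):
    """Wide comparison table: one row per formulation, r^2/params per model."""
    import pandas as pd

    rows = []
    for fid, results in per_formulation.items():
        row: dict = {"formulation_id": fid}
        for res in results:
            row[f"{res.model}_r2"] = round(res.r_squared, 4) if res.converged else None
            for pname, val in res.params.items():
                row[f"{res.model}_{pname}"] = round(val, 4)
        rows.append(row)
    return pd.DataFrame(rows)
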