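"""Two-level full factorial designs, coded-unit regression and desirability.

Implements 2^k designs in standard (Yates) order with a seeded randomized
run order, ordinary least-squares main-effects fits in coded units, the
associated ANOVA partition, and Derringer-Suich desirability optimization
over the coded cube by exhaustive grid search.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FactorSpec",
    "DesignMatrix",
    "FittedModel",
    "ResponseGoal",
    "DesirabilitySpec",
    "DoeError",
    "build_design",
    "code_value",
    "decode_value",
    "fit_main_effects",
    "anova_main_effects",
    "predict",
    "desirability",
    "optimize_desirability",
]


class DoeError(ValueError):
    """Invalid input to a design/analysis operation."""


@dataclass(frozen=True)
class FactorSpec:
    """A continuous factor with its low/high levels in actual units."""

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise DoeError(f"factor {self.name!r}: require low < high, got {self.low}, {self.high}")


@dataclass(frozen=True)
class DesignMatrix:
    """Full 2^k design: coded +/-1 levels plus a seeded run order."""

    coded: np.ndarray              # (2^k, k), entries +/-1, standard order
    run_order: np.ndarray          # permutation of range(2^k)
    seed: int

    @property
    def k(self) -> int:
        return self.coded.shape[1]

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    def randomized(self) -> np.ndarray:
        return self.coded[self.run_order]


@dataclass(frozen=True)
class FittedModel:
    response: str
    intercept: float
    coefficients: np.ndarray       # main effects in coded units, length k
    residual_variance: float
    r_squared: float
    residual_df: int

    @property
    def k(self) -> int:
        return self.coefficients.size


@dataclass(frozen=True)
class ResponseGoal:
    """Desirability goal for one response.

    ``kind`` is ``"range"`` (two-sided; desirability 1 at the midpoint of
    [low, high], falling linearly to 0 at either bound) or ``"maximize"``
    (0 at ``low``, 1 at ``high`` and beyond).
    """

    kind: str
    low: float
    high: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("range", "maximize"):
            raise DoeError(f"unknown goal kind {self.kind!r}")
        if not self.low < self.high:
            raise DoeError(f"goal bounds must satisfy low < high, got {self.low}, {self.high}")
        if self.weight <= 0:
            raise DoeError("goal weight must be positive")

    def desirability(self, y: float) -> float:
        if self.kind == "maximize":
            d = (y - self.low) / (self.high - self.low)
        else:
            mid = 0.5 * (self.low + self.high)
            if y <= mid:
                d = (y - self.low) / (mid - self.low)
            else:
                d = (self.high - y) / (self.high - mid)
        d = min(1.0, max(0.0, d))
        return d ** self.weight


@dataclass(frozen=True)
class DesirabilitySpec:
    goals: Mapping[str, ResponseGoal] = field(default_factory=dict)


# --------------------------------------------------------------------------

def build_design(k: int, seed: int) -> DesignMatrix:
    """Full 2^k design in standard order with a seeded randomized run order.

    Standard (Yates) order: the first factor alternates sign fastest.
    """
    if not 2 <= k <= 8:
        raise DoeError(f"k must lie in [2, 8], got {k}")
    rows = []
    for levels in itertools.product((-1.0, 1.0), repeat=k):
        rows.append(levels[::-1])  # first factor varies fastest
    coded = np.array(rows)
    rng = np.random.default_rng(seed)
    order = rng.permutation(coded.shape[0])
    return DesignMatrix(coded=coded, run_order=order, seed=int(seed))


def code_value(f: FactorSpec, actual: float) -> float:
    """Actual units -> coded units: (actual - midpoint) / half-range."""
    mid = 0.5 * (f.low + f.high)
    half = 0.5 * (f.high - f.low)
    return (actual - mid) / half


def decode_value(f: FactorSpec, coded: float) -> float:
    """Coded units -> actual units (exact inverse of :func:`code_value`)."""
    mid = 0.5 * (f.low + f.high)
    half = 0.5 * (f.high - f.low)
    return mid + coded * half


def fit_main_effects(design: DesignMatrix, y: Sequence[float], *, response: str = "y") -> FittedModel:
    """OLS fit of intercept + main effects in coded units.

    On an orthogonal two-level design each coefficient equals half the
    difference between the response mean at the +1 level and at the -1
    level of its factor.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (design.n_runs,):
        raise DoeError(f"y must have length {design.n_runs}, got {y.shape}")
    X = np.column_stack([np.ones(design.n_runs), design.coded])
    for j in range(design.k):
        if np.allclose(design.coded[:, j], design.coded[0, j]):
            raise DoeError(f"design column {j} is constant")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    df_resid = design.n_runs - (design.k + 1)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    sigma2 = ss_res / df_resid if df_resid > 0 else float("nan")
    return FittedModel(
        response=response,
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        residual_variance=sigma2,
        r_squared=r2,
        residual_df=df_resid,
    )


def anova_main_effects(model: FittedModel, design: DesignMatrix, y: Sequence[float]) -> dict:
    """Term-wise ANOVA for a main-effects fit on an orthogonal design.

    Each term's sum of squares is ``n * coefficient**2`` (orthogonality);
    F and p are reported per term and for the whole model.  With zero
    residual degrees of freedom p-values are reported as None rather
    than 0.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (design.n_runs,):
        raise DoeError(f"y must have length {design.n_runs}, got {y.shape}")
    n, k = design.n_runs, design.k
    ss_terms = n * model.coefficients ** 2
    ss_model = float(ss_terms.sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = max(ss_tot - ss_model, 0.0)
    df_res = n - k - 1
    table: dict = {"terms": {}, "model": {}, "residual": {"ss": ss_res, "df": df_res}}
    if df_res > 0 and ss_res > 0:
        ms_res = ss_res / df_res
        for j in range(k):
            F = float(ss_terms[j] / ms_res)
            p = float(stats.f.sf(F, 1, df_res))
            table["terms"][f"x{j + 1}"] = {"ss": float(ss_terms[j]), "df": 1, "F": F, "p": p}
        F_model = (ss_model / k) / ms_res
        p_model = float(stats.f.sf(F_model, k, df_res))
        table["model"] = {
            "ss": ss_model, "df": k, "F": float(F_model), "p": p_model,
            "significant_at_0.05": bool(p_model <= 0.05),
        }
    else:
        for j in range(k):
            table["terms"][f"x{j + 1}"] = {"ss": float(ss_terms[j]), "df": 1, "F": None, "p": None}
        table["model"] = {"ss": ss_model, "df": k, "F": None, "p": None,
                          "significant_at_0.05": None}
    return table


def predict(model: FittedModel, point: Sequence[float]) -> float:
    """Predicted response at a coded point: intercept + beta . point."""
    point = np.asarray(point, dtype=float)
    if point.shape != (model.k,):
        raise DoeError(f"point must have length {model.k}, got {point.shape}")
    return float(model.intercept + model.coefficients @ point)


def desirability(models: Mapping[str, FittedModel], spec: DesirabilitySpec,
                 point: Sequence[float]) -> float:
    """Overall desirability D at a coded point: geometric mean over goals."""
    ds = []
    for name, goal in spec.goals.items():
        if name not in models:
            raise DoeError(f"no fitted model for response {name!r}")
        ds.append(goal.desirability(predict(models[name], point)))
    if not ds:
        raise DoeError("desirability spec carries no goals")
    ds = np.array(ds)
    if np.any(ds == 0.0):
        return 0.0
    return float(np.exp(np.mean(np.log(ds))))


def optimize_desirability(models: Mapping[str, FittedModel], spec: DesirabilitySpec,
                          resolution: float = 0.1) -> dict:
    """Exhaustive grid search of D over the coded cube [-1, 1]^k.

    Ties are broken by the lexicographically smallest coded point; all
    tied optima are reported.  A ``warning`` flag is set when the best
    D is 0 (no feasible point at this resolution).
    """
    ks = {m.k for m in models.values()}
    if len(ks) != 1:
        raise DoeError("all models must share the same factor count")
    k = ks.pop()
    if not 0 < resolution <= 2:
        raise DoeError(f"resolution must lie in (0, 2], got {resolution}")
    n_steps = int(round(2.0 / resolution))
    axis = np.linspace(-1.0, 1.0, n_steps + 1)
    best_d = -1.0
    best_points: list[tuple[float, ...]] = []
    for point in itertools.product(axis, repeat=k):
        d = desirability(models, spec, point)
        if d > best_d + 1e-12:
            best_d = d
            best_points = [point]
        elif abs(d - best_d) <= 1e-12:
            best_points.append(point)
    best_points.sort()
    return {
        "optimum": list(best_points[0]),
        "D": best_d,
        "tied_optima": [list(p) for p in best_points],
        "warning": "no feasible point (D = 0 everywhere on grid)" if best_d == 0.0 else None,
    }
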