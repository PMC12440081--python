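"""Payoff inference from mono-/co-culture growth-rate assays.

A game assay measures the per-capita growth rate of each type across a
range of seeding mutant fractions x.  Under the linear (matrix-game) model
each type's growth rate is a straight line in x — the growth-frequency
plot — and the payoff entries are the line values at the boundaries:

    wild-type line:  g_w(x) = a + (b - a) x   ->  a at x = 0, b at x = 1
    mutant line:     g_m(x) = c + (d - c) x   ->  c at x = 0, d at x = 1

Monoculture values sit at the type's own boundary (x = 0 for wild-type,
x = 1 for mutant); the opposite boundary is the extrapolated co-culture
payoff.  Fitting ordinary least-squares lines per type and reading off the
intersections therefore recovers the full payoff matrix, after which
normalization and decomposition proceed through :mod:`ecogames.payoff`.

A synthetic-assay generator produces measurement tables with known
ground-truth coefficients for testing the inference pipeline end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from . import payoff as pc
from .payoff import GameDecomposition, PayoffMatrix

__all__ = [
    "WILD_TYPE",
    "MUTANT",
    "AssayMeasurement",
    "LineFit",
    "AssayFit",
    "InsufficientDataError",
    "fit_growth_frequency",
    "payoff_from_fits",
    "generate_synthetic_assay",
    "import_payoff_table",
]

WILD_TYPE = "wild-type"
MUTANT = "mutant"

ASSAY_COLUMNS = ["experiment", "type", "mutant_fraction", "growth_rate", "replicate"]


class InsufficientDataError(ValueError):
    """Raised when a type has too few distinct seeding fractions for a line fit."""


@dataclass(frozen=True)
class AssayMeasurement:
    type_label: str
    mutant_fraction: float
    growth_rate: float

    def __post_init__(self) -> None:
        if self.type_label not in (WILD_TYPE, MUTANT):
            raise ValueError(f"type_label must be {WILD_TYPE!r} or {MUTANT!r}")
        if not 0.0 <= self.mutant_fraction <= 1.0:
            raise ValueError("seeding mutant fraction must lie in [0, 1]")


@dataclass(frozen=True)
class LineFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    residual_sd: float
    n: int
    quadratic_p: float  # p-value of an added quadratic term (linearity diagnostic)

    def at(self, x: float) -> float:
        return self.intercept + self.slope * x


@dataclass(frozen=True)
class AssayFit:
    lines: Dict[str, LineFit]

    @property
    def wild_type(self) -> LineFit:
        return self.lines[WILD_TYPE]

    @property
    def mutant(self) -> LineFit:
        return self.lines[MUTANT]


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    rows = [
        {"type": m.type_label, "mutant_fraction": m.mutant_fraction, "growth_rate": m.growth_rate}
        for m in data
    ]
    return pd.DataFrame(rows)


def _quadratic_p(x: np.ndarray, y: np.ndarray) -> float:
    """p-value for the quadratic coefficient of a degree-2 fit (t-test)."""
    if len(np.unique(x)) < 3 or len(x) < 4:
        return float("nan")
    X = np.column_stack([np.ones_like(x), x, x * x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(x) - 3
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)
    se = math.sqrt(max(cov[2, 2], 0.0))
    if se == 0.0:
        return 1.0 if coef[2] == 0 else 0.0
    t = coef[2] / se
    return float(2 * stats.t.sf(abs(t), dof))


def fit_growth_frequency(data, weighted: bool = False) -> AssayFit:
    """Per-type ordinary least-squares line of growth rate against mutant fraction.

    ``weighted=True`` averages replicates per fraction first and weights by
    replicate counts (documented option; unweighted OLS on the raw points
    is the default).  Emits a warning-level diagnostic via the returned
    ``quadratic_p`` when curvature would be significant at the 5% level.
    """
    df = _as_frame(data)
    lines: Dict[str, LineFit] = {}
    for label in (WILD_TYPE, MUTANT):
        sub = df[df["type"] == label]
        x = sub["mutant_fraction"].to_numpy(dtype=float)
        y = sub["growth_rate"].to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            raise InsufficientDataError(
                f"type {label!r} needs measurements at >= 2 distinct fractions, "
                f"got {len(np.unique(x))}"
            )
        if weighted:
            grouped = sub.groupby("mutant_fraction")["growth_rate"]
            xm = grouped.mean().index.to_numpy(dtype=float)
            ym = grouped.mean().to_numpy(dtype=float)
            w = grouped.count().to_numpy(dtype=float)
            W = np.diag(w)
            X = np.column_stack([np.ones_like(xm), xm])
            beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ ym)
            intercept, slope = beta
            resid = y - (intercept + slope * x)
            dof = max(len(x) - 2, 1)
            resid_sd = float(np.sqrt(resid @ resid / dof))
            cov = resid_sd**2 * np.linalg.inv(X.T @ W @ X)
            ise, sse = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
        else:
            res = stats.linregress(x, y)
            slope, intercept = float(res.slope), float(res.intercept)
            sse = float(res.stderr)
            ise = float(res.intercept_stderr)
            resid = y - (intercept + slope * x)
            dof = max(len(x) - 2, 1)
            resid_sd = float(np.sqrt(resid @ resid / dof))
        lines[label] = LineFit(
            slope=slope, intercept=intercept, slope_se=sse, intercept_se=ise,
            residual_sd=resid_sd, n=len(x), quadratic_p=_quadratic_p(x, y),
        )
    return AssayFit(lines=lines)


def payoff_from_fits(fit: AssayFit) -> PayoffMatrix:
    """Read the payoff entries off the fitted growth-frequency lines.

    a and b are the wild-type line at x = 0 and x = 1; c and d the mutant
    line at x = 0 and x = 1.
    """
    wt, mut = fit.wild_type, fit.mutant
    return PayoffMatrix(a=wt.at(0.0), b=wt.at(1.0), c=mut.at(0.0), d=mut.at(1.0))


def decomposition_from_assay(data, weighted: bool = False) -> GameDecomposition:
    """Full pipeline: fit lines, read payoffs, normalize, decompose."""
    P = payoff_from_fits(fit_growth_frequency(data, weighted=weighted))
    return pc.decompose(pc.normalize_payoff(P))


def generate_synthetic_assay(
    dec: GameDecomposition,
    fractions: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    noise_sd: float = 0.02,
    replicates: int = 3,
    seed: int = 0,
    g_w: float = 1.0,
    experiment: str = "synthetic",
) -> pd.DataFrame:
    """Growth-rate table from the payoff-implied lines plus Gaussian noise.

    Rates are the decomposition's lines scaled by the wild-type reference
    growth ``g_w``; both types are measured at every seeding fraction, with
    independent noise per measurement.  Reproducible for a fixed seed.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for label in (WILD_TYPE, MUTANT):
        for x in fractions:
            if label == WILD_TYPE:
                rate = g_w * (1.0 + dec.alpha_wm * x)
            else:
                rate = g_w * (1.0 + dec.s_m + dec.alpha_mw * (1.0 - x))
            noise = rng.normal(0.0, noise_sd, size=replicates) if noise_sd > 0 else np.zeros(replicates)
            for r in range(replicates):
                rows.append(
                    {
                        "experiment": experiment,
                        "type": label,
                        "mutant_fraction": float(x),
                        "growth_rate": rate + noise[r],
                        "replicate": r,
                    }
                )
    return pd.DataFrame(rows, columns=ASSAY_COLUMNS)


def import_payoff_table(path) -> pd.DataFrame:
    """Read and validate a payoff table, decomposing each normalizable row.

    Malformed or non-normalizable rows are kept and flagged (``error``
    column, with the row index), never silently dropped.  Rows follow the
    CSV schema [label, condition, a, b, c, d]; entries keep their native
    units and are normalized per row by dividing by a.
    """
    df = pc.read_payoff_table(path)
    out = pc.decompose_table(df)
    out["normalizable"] = out["error"] == ""
    out["decomposable"] = out["error"] == ""
    return out
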