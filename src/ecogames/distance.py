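"""Perpendicular distance from measured games to the regime surfaces.

Each of the maintenance, masking, and mirroring conditions defines a
surface in the dimensionless coordinate space (s_m, alpha_mw, alpha_wm)
once the mutation rate is frozen (default mu = 0.001, the value used for
experimentally derived distances; mimicry is excluded because it would
require an arbitrary target sigma).  The distance of a measured point to a
surface is the minimum unitless Euclidean distance to any point on it,
found by parameterizing the surface by its free coordinates and
multi-start local minimization.

The masking surface alpha_wm = alpha_mw + 2 s_m is a plane with normal
(-2, -1, 1)/sqrt(6) in (s_m, alpha_mw, alpha_wm), so its distance has the
closed form |alpha_wm - alpha_mw - 2 s_m| / sqrt(6), which serves as an
oracle for the numerical machinery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .replicator import RegimeSpec
from .stochastic import mode_no_interaction, stochastic_surface_first_order

__all__ = [
    "DISTANCE_REGIMES",
    "ManifoldDistanceResult",
    "surface_residual",
    "surface_constrained_coordinate",
    "project_to_surface",
    "masking_plane_distance",
    "rank_experiments",
]

DISTANCE_REGIMES = ("maintenance", "masking", "mirroring")

# coordinate order is (s_m, alpha_mw, alpha_wm) throughout
_FREE = {
    "maintenance": ("s_m", "alpha_mw"),  # constrained: alpha_wm
    "masking": ("s_m", "alpha_mw"),
    "mirroring": ("s_m", "alpha_wm"),    # constrained: alpha_mw
}

_SINGULAR_MARGIN = 1e-4


@dataclass(frozen=True)
class ManifoldDistanceResult:
    regime: str
    d_min: float
    projected_point: Tuple[float, float, float]  # (s_m, alpha_mw, alpha_wm)
    n_starts: int
    converged: bool
    residual: float


def _check_regime(regime: str) -> None:
    if regime not in DISTANCE_REGIMES:
        raise ValueError(
            f"regime must be one of {DISTANCE_REGIMES} (mimicry is excluded "
            "from the distance analysis)"
        )


def surface_constrained_coordinate(
    regime: str, s_m: float, free_alpha: float, mu: float, method: str = "first_order"
) -> float:
    """Constrained coordinate of the regime surface at the given free coordinates.

    For maintenance and masking the free interaction coefficient is
    alpha_mw and the constrained one alpha_wm; for mirroring the roles are
    swapped.  Singular parameter values (s_m = 0, s_m = -1 for
    maintenance) raise.
    """
    _check_regime(regime)
    if regime == "masking":
        return free_alpha + 2.0 * s_m
    spec = RegimeSpec(regime, "stochastic_mode")
    if method == "first_order":
        return stochastic_surface_first_order(spec, s_m, mu, free_alpha)
    if method == "exact":
        from .stochastic import exact_surface_solve

        return exact_surface_solve(spec, s_m, mu, free_alpha)
    raise ValueError(f"unknown surface method {method!r}")


def surface_residual(regime: str, point, mu: float, method: str = "first_order") -> float:
    """Signed residual of the regime constraint at (s_m, alpha_mw, alpha_wm).

    Zero exactly on the surface.  For the first-order surfaces the residual
    is the defect of the constrained coordinate; for the exact surfaces it
    is sigma_m at the target reference mode minus the target.
    """
    _check_regime(regime)
    s_m, alpha_mw, alpha_wm = (float(v) for v in point)
    if method == "exact":
        spec = RegimeSpec(regime, "stochastic_mode")
        target = spec.resolve_target(s_m)
        x_eval = mode_no_interaction(target, mu)
        num = s_m + alpha_mw - (alpha_wm + alpha_mw) * x_eval
        return num / (1.0 + alpha_wm * x_eval) - target
    if regime == "masking":
        return alpha_wm - alpha_mw - 2.0 * s_m
    if regime == "maintenance":
        return alpha_wm - surface_constrained_coordinate(regime, s_m, alpha_mw, mu, method)
    return alpha_mw - surface_constrained_coordinate(regime, s_m, alpha_wm, mu, method)


def masking_plane_distance(point) -> float:
    """Closed-form point-to-plane distance for the linear masking surface."""
    s_m, alpha_mw, alpha_wm = (float(v) for v in point)
    return abs(alpha_wm - alpha_mw - 2.0 * s_m) / math.sqrt(6.0)


def _surface_point(regime: str, free: np.ndarray, mu: float, method: str):
    s_m, alpha = float(free[0]), float(free[1])
    if abs(s_m) < _SINGULAR_MARGIN or abs(1.0 + s_m) < _SINGULAR_MARGIN:
        if regime != "masking":
            return None
    try:
        c = surface_constrained_coordinate(regime, s_m, alpha, mu, method)
    except (ValueError, RuntimeError):
        return None
    if not math.isfinite(c):
        return None
    if regime == "mirroring":
        return np.array([s_m, c, alpha])
    return np.array([s_m, alpha, c])


def project_to_surface(
    regime: str,
    point,
    mu: float = 0.001,
    method: str = "first_order",
    n_starts: int = 16,
    seed: int = 0,
    bounds: Tuple[float, float] = (-1.5, 1.5),
) -> ManifoldDistanceResult:
    """Minimum Euclidean distance from ``point`` to a regime surface.

    The surface is parameterized by its two free coordinates; the squared
    distance is minimized by derivative-free local optimization from
    ``n_starts`` Latin-hypercube starting points (plus the measured point's
    own free coordinates as an extra start).  The best converged result is
    returned; if no start converges a diagnostic failure result (d_min NaN)
    is returned rather than a silent zero.
    """
    _check_regime(regime)
    p0 = np.asarray([float(v) for v in point], dtype=float)
    if p0.shape != (3,):
        raise ValueError("point must be (s_m, alpha_mw, alpha_wm)")

    def objective(free: np.ndarray) -> float:
        sp = _surface_point(regime, free, mu, method)
        if sp is None:
            return 1e6 + float(np.sum(free**2))  # steer away from singular strips
        return float(np.sum((sp - p0) ** 2))

    sampler = qmc.LatinHypercube(d=2, seed=seed)
    lo, hi = bounds
    starts = [qmc.scale(sampler.random(1), lo, hi)[0] for _ in range(n_starts)]
    if regime == "mirroring":
        starts.append(np.array([p0[0], p0[2]]))
    else:
        starts.append(np.array([p0[0], p0[1]]))
    # coarse vectorized scan seeds extra starts so no basin (including the
    # thin near-singular sheet of the maintenance/mirroring surfaces) is missed
    g = np.linspace(lo, hi, 120)
    S, A = np.meshgrid(g, g, indexing="ij")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        if regime == "masking":
            C = A + 2.0 * S
            pts = np.stack([S, A, C], axis=-1)
        elif regime == "maintenance":
            C = mu * A / (S * (1.0 + S))
            pts = np.stack([S, A, C], axis=-1)
        else:
            C = -2.0 * S + mu * (A * (1.0 - S) - 2.0 * S) / S
            pts = np.stack([S, C, A], axis=-1)
        d2 = np.sum((pts - p0) ** 2, axis=-1)
    bad = ~np.isfinite(d2)
    if regime != "masking":
        bad |= (np.abs(S) < _SINGULAR_MARGIN) | (np.abs(1.0 + S) < _SINGULAR_MARGIN)
    d2[bad] = np.inf
    order = np.argsort(d2, axis=None)
    for flat in order[:6]:
        i, j = np.unravel_index(flat, d2.shape)
        starts.append(np.array([S[i, j], A[i, j]]))
    # the maintenance/mirroring surfaces carry a thin sheet near s = 0 where
    # the mu/s term can match any target coordinate; seed its analytic root
    if regime == "maintenance" and p0[2] != 0.0:
        q = mu * p0[1] / p0[2]
        if 1.0 + 4.0 * q > 0:
            s_sheet = (-1.0 + math.sqrt(1.0 + 4.0 * q)) / 2.0
            if abs(s_sheet) >= _SINGULAR_MARGIN:
                starts.append(np.array([s_sheet, p0[1]]))
    elif regime == "mirroring" and p0[1] != 0.0:
        s_sheet = mu * p0[2] / p0[1]
        if abs(s_sheet) >= _SINGULAR_MARGIN:
            starts.append(np.array([s_sheet, p0[2]]))

    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="Powell",
            options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 10000},
        )
        if not res.success:
            continue
        any_converged = True
        if best is None or res.fun < best.fun:
            best = res
    if best is None or objective(best.x) >= 1e6:
        return ManifoldDistanceResult(
            regime=regime, d_min=float("nan"),
            projected_point=(math.nan, math.nan, math.nan),
            n_starts=len(starts), converged=False, residual=float("nan"),
        )
    proj = _surface_point(regime, best.x, mu, method)
    resid = surface_residual(regime, proj, mu, method)
    return ManifoldDistanceResult(
        regime=regime,
        d_min=float(math.sqrt(best.fun)),
        projected_point=tuple(float(v) for v in proj),
        n_starts=len(starts),
        converged=any_converged,
        residual=float(resid),
    )


def rank_experiments(
    records: pd.DataFrame,
    regimes: Sequence[str] = DISTANCE_REGIMES,
    mu: float = 0.001,
    method: str = "first_order",
    n_starts: int = 16,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-experiment distances to each regime surface with closest flags.

    ``records`` needs columns [experiment, s_m, alpha_mw, alpha_wm].
    Records with s_m = 0 are excluded from the maintenance and mirroring
    surfaces (their formulas are singular there) with a diagnostic note.
    Output columns: experiment, regime, d_min, proj_s_m, proj_alpha_mw,
    proj_alpha_wm, converged, closest, note.
    """
    rows = []
    for _, rec in records.iterrows():
        point = (rec["s_m"], rec["alpha_mw"], rec["alpha_wm"])
        for regime in regimes:
            _check_regime(regime)
            if regime != "masking" and rec["s_m"] == 0.0:
                warnings.warn(
                    f"experiment {rec['experiment']!r}: s_m = 0 is singular for "
                    f"the {regime} surface; excluded"
                )
                rows.append(
                    {
                        "experiment": rec["experiment"], "regime": regime,
                        "d_min": np.nan, "proj_s_m": np.nan, "proj_alpha_mw": np.nan,
                        "proj_alpha_wm": np.nan, "converged": False,
                        "note": "excluded: s_m = 0 singular",
                    }
                )
                continue
            res = project_to_surface(
                regime, point, mu=mu, method=method, n_starts=n_starts, seed=seed
            )
            rows.append(
                {
                    "experiment": rec["experiment"], "regime": regime,
                    "d_min": res.d_min,
                    "proj_s_m": res.projected_point[0],
                    "proj_alpha_mw": res.projected_point[1],
                    "proj_alpha_wm": res.projected_point[2],
                    "converged": res.converged,
                    "note": "",
                }
            )
    out = pd.DataFrame(rows)
    out["closest"] = False
    for regime in regimes:
        sub = out[(out["regime"] == regime) & out["d_min"].notna()]
        if len(sub):
            out.loc[sub["d_min"].idxmin(), "closest"] = True
    return out
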