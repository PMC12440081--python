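"""Deterministic replicator dynamics and frequency-dependent selection.

For a normalized decomposed game the two types have frequency-dependent
fitnesses

    f_w(x) = 1 + alpha_wm * x
    f_m(x) = 1 + s_m + alpha_mw * (1 - x)

with ``x`` the mutant fraction.  The frequency-dependent selection
coefficient is the relative fitness advantage of the mutant,

    sigma_m(x) = (f_m - f_w) / f_w
               = (s_m + alpha_mw - (alpha_wm + alpha_mw) x) / (1 + alpha_wm x),

and the replicator equation reads dx/dt = x (1 - x) (f_m - f_w).

Four interaction regimes are defined by requiring sigma_m(x) to equal a
constant target identically in x: *maintenance* (target s_m, only the
trivial non-interacting solution), *masking* (target 0, neutralizing an
intrinsic fitness difference), *mirroring* (target -s_m, inverting it) and
*mimicry* (nonzero target with s_m = 0, fabricating selection from pure
ecology).  Imposing the identity and matching polynomial coefficients in x
yields a linear system whose solution is

    alpha_mw = target - s_m,      alpha_wm = (s_m - target) / (1 + target).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .payoff import GameDecomposition

__all__ = [
    "FixedPoint",
    "FixedPointSet",
    "Trajectory",
    "RegimeSpec",
    "REGIME_KINDS",
    "SingularParameterError",
    "fitnesses",
    "sigma",
    "replicator_rhs",
    "fixed_points",
    "integrate",
    "solve_sigma_identity",
    "deterministic_regime_coefficients",
    "classify_regime_dynamics",
    "steady_state_equivalence",
]

REGIME_KINDS = ("maintenance", "masking", "mirroring", "mimicry")
FRAMEWORKS = ("deterministic_dynamics", "deterministic_steady_state", "stochastic_mode")


class SingularParameterError(ValueError):
    """Raised when a regime formula is evaluated at a singular parameter value."""


@dataclass(frozen=True)
class RegimeSpec:
    """One of the four interaction regimes together with its selection target.

    ``target`` is the constant value sigma_m must take: ``s_m`` for
    maintenance, ``0`` for masking, ``-s_m`` for mirroring and an arbitrary
    nonzero s' (or sigma) for mimicry, which additionally requires the
    intrinsic coefficient to vanish.
    """

    kind: str
    framework: str = "deterministic_dynamics"
    target: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in REGIME_KINDS:
            raise ValueError(f"unknown regime kind {self.kind!r}; expected one of {REGIME_KINDS}")
        if self.framework not in FRAMEWORKS:
            raise ValueError(f"unknown framework {self.framework!r}")
        if self.kind == "mimicry" and self.target in (None, 0.0):
            raise ValueError("mimicry requires a nonzero selection target")

    def resolve_target(self, s_m: float) -> float:
        if self.kind == "maintenance":
            return s_m
        if self.kind == "masking":
            if s_m == 0.0:
                raise ValueError("masking requires a nonzero intrinsic selection coefficient")
            return 0.0
        if self.kind == "mirroring":
            if s_m == 0.0:
                raise ValueError("mirroring requires a nonzero intrinsic selection coefficient")
            return -s_m
        # mimicry
        if s_m != 0.0:
            raise ValueError("mimicry requires s_m = 0")
        return float(self.target)


@dataclass(frozen=True)
class FixedPoint:
    x: float
    stability: str  # "stable" | "unstable" | "degenerate"


@dataclass(frozen=True)
class FixedPointSet:
    points: tuple
    degenerate: bool = False  # whole interval stationary (fully neutral game)

    def stable(self) -> tuple:
        return tuple(p for p in self.points if p.stability == "stable")

    def as_dict(self) -> dict:
        return {
            "degenerate": self.degenerate,
            "points": [{"x": p.x, "stability": p.stability} for p in self.points],
        }


@dataclass
class Trajectory:
    """Time course of the mutant fraction, dimensionless time (g_w = 1)."""

    times: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)

    @property
    def final(self) -> float:
        return float(self.x[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.times, "x": self.x})


def _check_x(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any((x < 0.0) | (x > 1.0)):
        raise ValueError("mutant fraction x must lie in [0, 1]")
    return x


def fitnesses(dec: GameDecomposition, x):
    """Frequency-dependent fitnesses (f_w, f_m) at mutant fraction x.

    Identical to the expected payoffs a(1-x)+bx and c(1-x)+dx of the
    underlying matrix game.
    """
    x = _check_x(x)
    f_w = 1.0 + dec.alpha_wm * x
    f_m = 1.0 + dec.s_m + dec.alpha_mw * (1.0 - x)
    return f_w, f_m


def sigma(dec: GameDecomposition, x):
    """Frequency-dependent selection coefficient sigma_m(x) = (f_m - f_w)/f_w."""
    x = _check_x(x)
    num = dec.s_m + dec.alpha_mw - (dec.alpha_wm + dec.alpha_mw) * x
    return num / (1.0 + dec.alpha_wm * x)


def replicator_rhs(dec: GameDecomposition, x):
    """Replicator velocity dx/dt = x(1-x)(f_m - f_w)."""
    x = _check_x(x)
    fd = (dec.s_m + dec.alpha_mw) - (dec.alpha_wm + dec.alpha_mw) * x
    return x * (1.0 - x) * fd


def fixed_points(dec: GameDecomposition, eps: float = 1e-6) -> FixedPointSet:
    """Stationary points of the replicator equation with stability labels.

    The boundaries 0 and 1 are always stationary; an interior point
    x* = (s_m + alpha_mw)/(alpha_wm + alpha_mw) is included when it falls in
    (0, 1).  Stability is read off the sign of the velocity on either side
    of each point.  A fully neutral game (velocity identically zero) is
    reported as degenerate.
    """
    u = dec.s_m + dec.alpha_mw          # c - a
    uv = dec.alpha_wm + dec.alpha_mw    # (c - a) + (b - d)
    if u == 0.0 and uv == 0.0:
        return FixedPointSet(
            points=(FixedPoint(0.0, "degenerate"), FixedPoint(1.0, "degenerate")),
            degenerate=True,
        )
    xs = [0.0, 1.0]
    if uv != 0.0:
        x_int = u / uv
        if 0.0 < x_int < 1.0:
            xs = [0.0, x_int, 1.0]

    def vel(x):
        return float(replicator_rhs(dec, x))

    pts = []
    for x0 in xs:
        lo, hi = max(x0 - eps, 0.0), min(x0 + eps, 1.0)
        left = vel((max(x0 - eps, xs[0]) + x0) / 2) if x0 > 0 else None
        right = vel((x0 + min(x0 + eps, 1.0)) / 2) if x0 < 1 else None
        # attracting from every admissible side -> stable
        attracting = []
        if left is not None:
            attracting.append(left > 0)
        if right is not None:
            attracting.append(right < 0)
        if all(attracting):
            stab = "stable"
        elif not any(attracting):
            stab = "unstable"
        else:
            stab = "degenerate"
        # a side with exactly zero velocity is degenerate
        if (left is not None and left == 0.0) or (right is not None and right == 0.0):
            stab = "degenerate"
        pts.append(FixedPoint(float(x0), stab))
    return FixedPointSet(points=tuple(pts))


def integrate(
    dec: GameDecomposition,
    x0: float,
    horizon: float = 1000.0,
    tolerance: float = 1e-10,
    n_points: int = 201,
) -> Trajectory:
    """Numerically integrate the replicator equation from x0.

    Adaptive explicit Runge-Kutta with absolute tolerance ``tolerance``;
    the state is clipped to [0, 1] when evaluating the right-hand side so
    round-off never pushes the trajectory outside the simplex.
    """
    if not 0.0 <= x0 <= 1.0:
        raise ValueError("x0 must lie in [0, 1]")

    def rhs(_t, y):
        return [float(replicator_rhs(dec, min(max(y[0], 0.0), 1.0)))]

    t_eval = np.linspace(0.0, horizon, n_points)
    sol = solve_ivp(
        rhs, (0.0, horizon), [x0], t_eval=t_eval,
        rtol=1e-10, atol=tolerance, method="RK45", dense_output=False,
    )
    x = np.clip(sol.y[0], 0.0, 1.0)
    return Trajectory(times=sol.t, x=x)


def solve_sigma_identity(s_m: float, target: float):
    """Interaction coefficients making sigma_m(x) equal ``target`` identically.

    Clearing the denominator of sigma_m and matching polynomial
    coefficients in x gives a 2x2 linear system for (alpha_mw, alpha_wm)::

        constant term:  s_m + alpha_mw           = target
        linear term:   -(alpha_wm + alpha_mw)    = target * alpha_wm

    solved numerically here; the closed form is alpha_mw = target - s_m,
    alpha_wm = (s_m - target)/(1 + target), singular at target = -1.
    """
    if target == -1.0:
        raise SingularParameterError("sigma target -1 makes the identity singular")
    A = np.array([[1.0, 0.0], [1.0, 1.0 + target]])
    rhs = np.array([target - s_m, 0.0])
    alpha_mw, alpha_wm = np.linalg.solve(A, rhs)
    return float(alpha_mw), float(alpha_wm)


def deterministic_regime_coefficients(spec: RegimeSpec, s_m: float):
    """(alpha_mw, alpha_wm) realizing a deterministic regime at intrinsic selection s_m.

    maintenance -> (0, 0); masking -> (-s_m, s_m);
    mirroring -> (-2 s_m, 2 s_m/(1 - s_m)); mimicry with target s' ->
    (s', -s'/(1 + s')).  Singular at mirroring with s_m = 1 and mimicry with
    s' = -1.
    """
    if spec.framework == "stochastic_mode":
        raise ValueError("use the stochastic module for stochastic-mode surfaces")
    target = spec.resolve_target(s_m)
    if spec.kind == "mirroring" and s_m == 1.0:
        raise SingularParameterError("mirroring is singular at s_m = 1")
    try:
        return solve_sigma_identity(s_m, target)
    except SingularParameterError as exc:
        raise SingularParameterError(f"{spec.kind}: {exc}") from exc


def classify_regime_dynamics(
    dec: GameDecomposition, reference_s: float, tol: float = 1e-9
) -> Optional[str]:
    """Label the regime realized by ``dec`` relative to ``reference_s``, or None.

    sigma_m(x) is constant in x iff, after clearing the denominator, the
    linear coefficient matches:  alpha_wm + alpha_mw + C*alpha_wm = 0 with
    C = s_m + alpha_mw the constant value.  The constant is then compared to
    {reference_s, -reference_s, 0, nonzero-with-s_m=0}.
    """
    C = dec.s_m + dec.alpha_mw  # sigma at x = 0
    if abs(dec.alpha_wm + dec.alpha_mw + C * dec.alpha_wm) > tol:
        return None  # sigma varies with x
    if dec.s_m == 0.0 and abs(C) > tol:
        return "mimicry"
    if abs(C - reference_s) <= tol and reference_s != 0.0:
        return "maintenance"
    if abs(C + reference_s) <= tol and reference_s != 0.0:
        return "mirroring"
    if abs(C) <= tol and dec.s_m != 0.0:
        return "masking"
    if abs(C - reference_s) <= tol:
        return "maintenance"
    return None


def reached_steady_state(dec: GameDecomposition, x0: float, tol: float = 1e-12) -> Optional[float]:
    """Stable steady state reached from x0 under the replicator flow.

    Determined from the fixed-point structure and the sign of the velocity
    at x0 (the flow is monotone between adjacent fixed points); returns None
    for a degenerate (fully neutral) game.
    """
    fps = fixed_points(dec)
    if fps.degenerate:
        return None
    v0 = float(replicator_rhs(dec, x0))
    if abs(v0) <= tol:
        return float(x0)
    xs = sorted(p.x for p in fps.points)
    if v0 > 0:
        return float(min(x for x in xs if x > x0))
    return float(max(x for x in xs if x < x0))


def steady_state_equivalence(
    dec: GameDecomposition, reference_s: float, x0: float, tol: float = 1e-9
) -> str:
    """Classify the steady state reached from x0 against the non-interacting outcome.

    The non-interacting reference with selection ``reference_s`` fixes the
    favored type (x_inf = 1 for reference_s > 0, 0 for < 0).  The interacting
    outcome is labelled maintenance (same), mirroring (inverted),
    alternate-masking (x_inf = 1/2), mimicry (s_m = 0 yet a type fixes), or
    none.
    """
    if not 0.0 < x0 < 1.0:
        raise ValueError("x0 must lie in the open interval (0, 1)")
    x_inf = reached_steady_state(dec, x0)
    if x_inf is None:
        warnings.warn("fully neutral game: every x is stationary; no regime label assigned")
        return "none"
    if abs(x_inf - 0.5) <= tol:
        return "alternate-masking"
    if dec.s_m == 0.0 and (x_inf <= tol or x_inf >= 1.0 - tol):
        return "mimicry"
    if reference_s == 0.0:
        return "none"
    x_ref = 1.0 if reference_s > 0 else 0.0
    if abs(x_inf - x_ref) <= tol:
        return "maintenance"
    if abs(x_inf - (1.0 - x_ref)) <= tol:
        return "mirroring"
    return "none"
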