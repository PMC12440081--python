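"""Mutation-aware regime analysis and the Wright-Fisher stationary law.

With symmetric per-generation mutation at rate ``mu`` the mutant fraction no
longer fixes; its stationary distribution peaks at the mutation-selection
equilibrium.  For a non-interacting system with constant selection sigma the
mode solves

    sigma * x * (1 - x) + mu * (1 - 2 x) = 0,

whose root in [0, 1] is x_mode = (sigma - 2 mu + R) / (2 sigma) with
R = sqrt(sigma^2 + 4 mu^2) (and 1/2 in the sigma -> 0 limit).

Evaluating the frequency-dependent selection coefficient of an interacting
game at the non-interacting mode gives a closed form,

    sigma_m(x_mode) = [2 s^2 + s (a_mw - a_wm) + (2 mu - R)(a_mw + a_wm)]
                      / [2 s + a_wm (s + R - 2 mu)],   R = sqrt(4 mu^2 + s^2),

valid for either sign of s (it reduces to s when both interactions vanish).
Requiring this quantity to equal the regime target defines one surface per
regime in (s_m, alpha_mw, alpha_wm, mu) space; the module exposes both the
exact implicit solve and the first-order-in-mu closed forms:

    maintenance:  alpha_wm = mu * alpha_mw / (s_m (1 + s_m))
    masking:      alpha_wm = alpha_mw + 2 s_m          (exact, mu-free)
    mirroring:    alpha_mw = -2 s_m + mu (alpha_wm (1 - s_m) - 2 s_m) / s_m
    mimicry:      alpha_wm = -sigma/(1+sigma) + mu (alpha_mw - sigma)/(sigma (1+sigma))

Each condition is evaluated at the mode of its own target reference system
(maintenance at x_mode(s_m), masking at 1/2, mirroring at x_mode(-s_m),
mimicry at x_mode(sigma)).  In the mu -> 0 limit every surface reduces to
the deterministic regime pair.

The exact stationary law is obtained numerically as the stationary vector
of the (N+1)-state frequency-dependent Wright-Fisher chain, the same
process the simulator samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .payoff import GameDecomposition
from .replicator import RegimeSpec, SingularParameterError, sigma

__all__ = [
    "ModeQuery",
    "StationaryDistribution",
    "mode_no_interaction",
    "sigma_at_mode",
    "stochastic_surface_first_order",
    "exact_surface_solve",
    "transition_probabilities",
    "wf_stationary_distribution",
]


@dataclass(frozen=True)
class ModeQuery:
    """Reference selection value and mutation rate for a mode computation."""

    sigma_ref: float
    mu: float

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mutation rate must be non-negative")

    @property
    def R(self) -> float:
        return math.sqrt(self.sigma_ref**2 + 4.0 * self.mu**2)


def mode_no_interaction(sigma_ref: float, mu: float) -> float:
    """Modal mutant fraction of the non-interacting mutation-selection balance.

    Root in [0, 1] of sigma*x*(1-x) + mu*(1-2x) = 0.  Continuous through
    sigma = 0 (limit 1/2 from either side) and monotone increasing in
    sigma.  At mu = 0 the mode degenerates to fixation of the favored type.
    """
    if mu < 0:
        raise ValueError("mutation rate must be non-negative")
    if sigma_ref == 0.0:
        return 0.5
    if mu == 0.0:
        return 1.0 if sigma_ref > 0 else 0.0
    R = math.sqrt(sigma_ref**2 + 4.0 * mu**2)
    if sigma_ref > 0:
        return (sigma_ref - 2.0 * mu + R) / (2.0 * sigma_ref)
    # algebraically identical, but avoids catastrophic cancellation for sigma < 0
    return 2.0 * mu / (R + 2.0 * mu - sigma_ref)


def sigma_at_mode(dec: GameDecomposition, mu: float) -> float:
    """Closed-form sigma_m evaluated at the non-interacting mode x_mode(s_m, mu).

    Identical to ``sigma(dec, mode_no_interaction(dec.s_m, mu))``; the s_m = 0
    case is handled by the two-sided limit (direct evaluation at x = 1/2).
    """
    s = dec.s_m
    if mu < 0:
        raise ValueError("mutation rate must be non-negative")
    if s == 0.0:
        return float(sigma(dec, 0.5))
    R = math.sqrt(4.0 * mu**2 + s * s)
    num = 2.0 * s * s + s * (dec.alpha_mw - dec.alpha_wm) + (2.0 * mu - R) * (dec.alpha_mw + dec.alpha_wm)
    den = 2.0 * s + dec.alpha_wm * (s + R - 2.0 * mu)
    if den == 0.0:
        raise SingularParameterError("sigma_at_mode denominator vanishes for these parameters")
    return num / den


def _resolve(spec: RegimeSpec, s_m: float) -> float:
    if spec.framework != "stochastic_mode":
        raise ValueError("regime spec must use the stochastic_mode framework")
    return spec.resolve_target(s_m)


def stochastic_surface_first_order(
    spec: RegimeSpec, s_m: float, mu: float, free_coefficient: float
) -> float:
    """Constrained interaction coefficient on the first-order-in-mu regime surface.

    The free coefficient is alpha_mw for maintenance, masking and mimicry
    (returning alpha_wm) and alpha_wm for mirroring (returning alpha_mw;
    solving the other way introduces a 1/mu term).
    """
    target = _resolve(spec, s_m)
    if spec.kind == "maintenance":
        if s_m == 0.0 or s_m == -1.0:
            raise SingularParameterError("maintenance surface singular at s_m in {0, -1}")
        return mu * free_coefficient / (s_m * (1.0 + s_m))
    if spec.kind == "masking":
        return free_coefficient + 2.0 * s_m
    if spec.kind == "mirroring":
        return -2.0 * s_m + mu * (free_coefficient * (1.0 - s_m) - 2.0 * s_m) / s_m
    # mimicry
    sig = target
    if sig == -1.0:
        raise SingularParameterError("mimicry surface singular at sigma = -1")
    return -sig / (1.0 + sig) + mu * (free_coefficient - sig) / (sig * (1.0 + sig))


def _dec_for(spec: RegimeSpec, s_m: float, free: float, constrained: float) -> GameDecomposition:
    if spec.kind == "mirroring":
        return GameDecomposition(s_m=s_m, alpha_wm=free, alpha_mw=constrained)
    return GameDecomposition(s_m=s_m, alpha_wm=constrained, alpha_mw=free)


def surface_dec(spec: RegimeSpec, s_m: float, mu: float, free_coefficient: float,
                method: str = "first_order") -> GameDecomposition:
    """Full decomposition on a stochastic regime surface."""
    if method == "first_order":
        constrained = stochastic_surface_first_order(spec, s_m, mu, free_coefficient)
    elif method == "exact":
        constrained = exact_surface_solve(spec, s_m, mu, free_coefficient)
    else:
        raise ValueError(f"unknown surface method {method!r}")
    return _dec_for(spec, s_m, free_coefficient, constrained)


def exact_surface_solve(
    spec: RegimeSpec, s_m: float, mu: float, free_coefficient: float
) -> float:
    """Solve the exact regime condition sigma_m(x_mode(target, mu)) = target.

    The condition is evaluated at the mode of the regime's target reference
    system and solved for the constrained coefficient by bracketed 1-D
    root-finding; it agrees with the first-order surface to O(mu^2).
    """
    target = _resolve(spec, s_m)
    x_eval = mode_no_interaction(target, mu)

    def residual(c: float) -> float:
        # evaluate sigma directly; positivity of the decomposition is not
        # needed for the algebra, so bypass the dataclass checks
        if spec.kind == "mirroring":
            awm, amw = free_coefficient, c
        else:
            awm, amw = c, free_coefficient
        num = s_m + amw - (awm + amw) * x_eval
        den = 1.0 + awm * x_eval
        return num / den - target

    guess = stochastic_surface_first_order(spec, s_m, mu, free_coefficient)
    lo, hi = guess - 1e-3, guess + 1e-3
    for _ in range(60):
        if residual(lo) * residual(hi) <= 0:
            break
        lo, hi = guess - 2 * (guess - lo), guess + 2 * (hi - guess)
    else:
        raise RuntimeError(
            f"no sign change found for {spec.kind} surface in bracket [{lo:g}, {hi:g}]"
        )
    return float(optimize.brentq(residual, lo, hi, xtol=1e-14, rtol=8.9e-16))


@dataclass(frozen=True)
class StationaryDistribution:
    """Stationary law of the mutant count over states 0..N."""

    probabilities: np.ndarray
    N: int

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.N + 1)

    @property
    def mode(self) -> float:
        return float(np.argmax(self.probabilities)) / self.N

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.probabilities)) / self.N

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"count": self.support, "probability": self.probabilities})


def transition_probabilities(dec: GameDecomposition, N: int, mu: float) -> np.ndarray:
    """Post-selection, post-mutation binomial success probability per state.

    Order of events: fitness weighting of the current frequencies, then
    symmetric mutation of the expected frequency, then binomial sampling.
    The simulator uses the identical kernel, so chain and simulator describe
    the same process.
    """
    x = np.arange(N + 1) / N
    f_w = 1.0 + dec.alpha_wm * x
    f_m = 1.0 + dec.s_m + dec.alpha_mw * (1.0 - x)
    if np.any(f_w < 0) or np.any(f_m < 0):
        raise ValueError("negative fitness encountered; invalid parameters")
    w = x * f_m + (1.0 - x) * f_w
    if np.any(w <= 0):
        raise ValueError("vanishing mean fitness; invalid parameters")
    p_sel = x * f_m / w
    return p_sel * (1.0 - mu) + (1.0 - p_sel) * mu


def wf_stationary_distribution(
    dec: GameDecomposition, N: int, mu: float
) -> StationaryDistribution:
    """Stationary vector of the (N+1)-state frequency-dependent Wright-Fisher chain.

    Requires mu > 0 for irreducibility; with mu = 0 the boundary states are
    absorbing and the long-run behavior is a fixation probability, not a
    stationary density.
    """
    if N < 2:
        raise ValueError("population size must be at least 2")
    if mu <= 0:
        raise ValueError(
            "mu = 0 makes the chain absorbing; analyze fixation probabilities instead"
        )
    p = transition_probabilities(dec, N, mu)
    k = np.arange(N + 1)
    # T[i, j] = P(next count = j | current count = i)
    T = stats.binom.pmf(k[None, :], N, p[:, None])
    # stationary pi solves pi (T - I) = 0 with sum(pi) = 1
    A = (T - np.eye(N + 1)).T
    A[-1, :] = 1.0
    b = np.zeros(N + 1)
    b[-1] = 1.0
    pi = linalg.solve(A, b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return StationaryDistribution(probabilities=pi, N=N)
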