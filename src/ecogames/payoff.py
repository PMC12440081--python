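"""Payoff-matrix algebra for two-type evolutionary games.

A 2x2 payoff matrix ``[[a, b], [c, d]]`` encodes per-capita growth payoffs:
``a`` for wild-type growing against wild-type, ``b`` for wild-type against
mutant, ``c`` for mutant against wild-type and ``d`` for mutant against
mutant.  After normalizing the wild-type reference growth to 1 (dividing all
entries by ``a``), the matrix separates additively into a cell-intrinsic
mutant selection coefficient ``s_m`` and two ecological interaction
coefficients::

    [[1,           1 + alpha_wm],
     [1 + s_m + alpha_mw, 1 + s_m]]

``alpha_wm`` is the effect of the mutant on wild-type growth, ``alpha_mw``
the effect of the wild-type on mutant growth.  A row of the payoff matrix is
constant exactly when the corresponding interaction coefficient vanishes, so
the decomposition isolates frequency dependence from intrinsic fitness.

The module also maps games into the two classification planes used
throughout the package: the classical game space ``(c - a, b - d)`` whose
quadrants determine the qualitative replicator outcome, and the
interaction-selection plane ``(alpha_mw/s_m, alpha_wm/s_m)`` whose unit
circle separates intrinsic-selection-dominated from ecology-dominated
systems.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "PayoffMatrix",
    "GameDecomposition",
    "GamePoint",
    "InteractionSelectionPoint",
    "NormalizationError",
    "DecompositionError",
    "normalize_payoff",
    "decompose",
    "compose",
    "game_coordinates",
    "interaction_selection_point",
    "read_payoff_table",
    "decompose_table",
]


class NormalizationError(ValueError):
    """Raised when a payoff matrix cannot be normalized to g_w = 1."""


class DecompositionError(ValueError):
    """Raised when a payoff matrix violates the positivity requirements."""


@dataclass(frozen=True)
class PayoffMatrix:
    """2x2 growth payoff table of the wild-type (row 1) and mutant (row 2)."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"payoff entry {name!r} must be finite, got {v!r}")

    @property
    def is_normalized(self) -> bool:
        return self.a == 1.0

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "PayoffMatrix":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (2, 2):
            raise ValueError(f"expected a 2x2 array, got shape {arr.shape}")
        return cls(float(arr[0, 0]), float(arr[0, 1]), float(arr[1, 0]), float(arr[1, 1]))


@dataclass(frozen=True)
class GameDecomposition:
    """Intrinsic selection and interaction coefficients of a normalized game.

    The wild-type reference growth is fixed at 1.  ``alpha_wm = -1`` is a
    valid boundary value (the convention used when the wild-type-vs-mutant
    payoff ``b`` is reported as zero); coefficients implying a *negative*
    payoff entry are rejected.
    """

    s_m: float
    alpha_wm: float
    alpha_mw: float

    g_w: float = 1.0  # wild-type reference growth, fixed by normalization

    def __post_init__(self) -> None:
        if self.g_w != 1.0:
            raise DecompositionError("wild-type reference growth must be 1 after normalization")
        for name in ("s_m", "alpha_wm", "alpha_mw"):
            if not math.isfinite(getattr(self, name)):
                raise DecompositionError(f"coefficient {name!r} must be finite")
        b = 1.0 + self.alpha_wm
        c = 1.0 + self.s_m + self.alpha_mw
        d = 1.0 + self.s_m
        for name, v in (("b", b), ("c", c), ("d", d)):
            if v < 0.0:
                raise DecompositionError(
                    f"coefficients imply negative payoff entry {name} = {v:g}; "
                    "growth payoffs must be non-negative"
                )


@dataclass(frozen=True)
class GamePoint:
    """Position of a game in the classical (c - a, b - d) game space."""

    u: float  # c - a = s_m + alpha_mw
    v: float  # b - d = alpha_wm - s_m
    quadrant: str
    game_name: str


@dataclass(frozen=True)
class InteractionSelectionPoint:
    """Position in the interaction-selection plane (alpha_mw/s_m, alpha_wm/s_m)."""

    rho_mw: float
    rho_wm: float
    dominance: str


# dynamics-based quadrant labels; stability analysis of the replicator
# equation fixes the mapping (see replicator.fixed_points)
_QUADRANTS = {
    (1, 1): ("coexistence", "Snow Drift"),
    (-1, -1): ("bistable", "Stag Hunt"),
    (1, -1): ("mutant dominates", "Harmony"),
    (-1, 1): ("wild-type dominates", "Prisoner's Dilemma"),
}


def normalize_payoff(P: PayoffMatrix) -> PayoffMatrix:
    """Divide all entries by ``a`` so the wild-type reference growth is 1.

    Division (rather than subtraction) preserves fitness ratios, which is
    what the frequency-dependent selection coefficient depends on.
    """
    if P.a <= 0:
        raise NormalizationError(
            f"cannot normalize: wild-type self payoff a = {P.a:g} must be positive"
        )
    if P.a == 1.0:
        return P
    return PayoffMatrix(1.0, P.b / P.a, P.c / P.a, P.d / P.a)


def decompose(P: PayoffMatrix) -> GameDecomposition:
    """Split a normalized payoff matrix into intrinsic and ecological parts.

    Row constancy is the defining intuition: with no ecological effects each
    row of the payoff matrix is constant, so ``alpha_wm = b - a`` and
    ``alpha_mw = c - d`` measure the departure of each row from constancy
    while ``s_m = d - a`` is the intrinsic mutant advantage.
    """
    if not P.is_normalized:
        raise DecompositionError(
            f"payoff matrix must be normalized (a = 1) before decomposition; got a = {P.a:g}"
        )
    if min(P.b, P.c, P.d) < 0:
        raise DecompositionError("normalized payoff entries must be non-negative")
    return GameDecomposition(s_m=P.d - 1.0, alpha_wm=P.b - 1.0, alpha_mw=P.c - P.d)


def compose(dec: GameDecomposition) -> PayoffMatrix:
    """Rebuild the normalized payoff matrix from a decomposition (inverse of decompose)."""
    return PayoffMatrix(
        1.0,
        1.0 + dec.alpha_wm,
        1.0 + dec.s_m + dec.alpha_mw,
        1.0 + dec.s_m,
    )


def game_coordinates(P: Union[PayoffMatrix, GameDecomposition]) -> GamePoint:
    """Map a game to the (u, v) = (c - a, b - d) plane and classify its quadrant.

    In decomposition terms u = s_m + alpha_mw and v = alpha_wm - s_m, so the
    coexistence quadrant is alpha_mw > -s_m and alpha_wm > s_m.  Exact zeros
    of either coordinate are reported as "boundary" rather than absorbed
    into a quadrant.
    """
    if isinstance(P, GameDecomposition):
        u = P.s_m + P.alpha_mw
        v = P.alpha_wm - P.s_m
    else:
        u = P.c - P.a
        v = P.b - P.d
    if u == 0.0 or v == 0.0:
        return GamePoint(u, v, "boundary", "boundary")
    quadrant, name = _QUADRANTS[(int(math.copysign(1, u)), int(math.copysign(1, v)))]
    return GamePoint(u, v, quadrant, name)


def interaction_selection_point(dec: GameDecomposition) -> InteractionSelectionPoint:
    """Coordinates (alpha_mw/s_m, alpha_wm/s_m) with unit-circle dominance.

    Inside the unit circle intrinsic selection outweighs ecological
    interactions; outside, ecology dominates.  ``s_m = 0`` leaves the ratios
    undefined (both coordinates are NaN and dominance is "undefined").
    """
    if dec.s_m == 0.0:
        return InteractionSelectionPoint(math.nan, math.nan, "undefined")
    rho_mw = dec.alpha_mw / dec.s_m
    rho_wm = dec.alpha_wm / dec.s_m
    r2 = rho_mw * rho_mw + rho_wm * rho_wm
    if r2 < 1.0:
        dominance = "intrinsic-dominated"
    elif r2 > 1.0:
        dominance = "ecology-dominated"
    else:
        dominance = "boundary"
    return InteractionSelectionPoint(rho_mw, rho_wm, dominance)


# ---------------------------------------------------------------------------
# tabular I/O

_PAYOFF_COLUMNS = ["label", "condition", "a", "b", "c", "d"]


def read_payoff_table(path) -> pd.DataFrame:
    """Read a payoff table (CSV or JSON records) with columns label, condition, a, b, c, d."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        df = pd.read_csv(path)
    missing = [c for c in _PAYOFF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"payoff table {path} is missing columns {missing}")
    return df[_PAYOFF_COLUMNS + [c for c in df.columns if c not in _PAYOFF_COLUMNS]]


def decompose_table(df: pd.DataFrame) -> pd.DataFrame:
    """Annotate a payoff table with decomposition, quadrant and dominance columns.

    Rows that cannot be normalized or decomposed are kept with an ``error``
    message instead of being dropped.
    """
    records = []
    for idx, row in df.iterrows():
        rec = dict(row)
        rec.update(
            s_m=np.nan, alpha_wm=np.nan, alpha_mw=np.nan,
            quadrant="", dominance="", error="",
        )
        try:
            P = normalize_payoff(PayoffMatrix(row["a"], row["b"], row["c"], row["d"]))
            dec = decompose(P)
        except (ValueError, TypeError) as exc:
            rec["error"] = f"row {idx}: {exc}"
        else:
            rec["s_m"] = dec.s_m
            rec["alpha_wm"] = dec.alpha_wm
            rec["alpha_mw"] = dec.alpha_mw
            rec["quadrant"] = game_coordinates(dec).quadrant
            rec["dominance"] = interaction_selection_point(dec).dominance
        records.append(rec)
    return pd.DataFrame(records)
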