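"""Prior-knowledge objective for scoring a 32-slot tooth combination.

The objective is f(P) = omega_p * f_p(P) + omega_c * f_c(P), where f_c is the
mean detector confidence over the 32 slots (missing teeth contribute 0) and
f_p scores the pairwise horizontal spacing of neighboring teeth with a
piecewise trapezoid-with-cliffs model delta(x, y):

    -4                        too close / reversed   (g <  a)
     0                        suspiciously close     (a <= g < b)
     (g - b) / (c - b)        ramp up                (b <= g < c)
     1                        plausible spacing      (c <= g < d)
     1 - (g - d) / (e - d)    ramp down              (d <= g < e)
     0                        suspiciously far       (e <= g < f)
    -4                        far too far            (g >= f)
     kappa                    either slot missing

with g the center-x separation of the two chosen boxes measured along the
jaw's numbering direction (UTN numbers increase rightward across the maxilla
and leftward across the mandible in the mirrored panoramic view), so a
reversed pair yields a negative g and lands in the first branch.  The
distance thresholds derive from the assumption that the 16 teeth of one row
span ~55% of the image width:

    b = width * 0.55 / 16 * 0.4        e = width * 0.55 / 16 * 2
    Range = e - b                      a = b / 2
    c = b + Range/4                    f = e + Range/4
    d = c + 3*Range/4   ("as_printed") or  d = b + 3*Range/4   ("quartile")

The as_printed rule makes d = e exactly (the ramp-down segment is empty); the
quartile variant ends the plateau at the third quartile of Range.  Three
adjustments: (i) when both teeth lie in the crowded mandibular center
(21 <= x, y <= 28), b is halved and the dependent values recomputed; (ii) when
either tooth is a mandibular molar (17-19 or 30-32), e is multiplied by 1.5
and the dependent values recomputed; (iii) for next-nearest neighbors
(|x - y| = 2) the too-close cutoff a widens to the unshifted c and b..f all
shift outward by that same c.

f_p(P) averages, over the 32 slots, the mean of delta over each tooth's
same-jaw neighbor set Omega = {x-2, x-1, x+1, x+2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .candidate_model import Combination, jaw_numbers

__all__ = [
    "PriorParams",
    "ObjectiveWeights",
    "PriorConfig",
    "derive_params",
    "signed_gap",
    "delta_of_gap",
    "delta",
    "neighbor_set",
    "fp_tooth",
    "objective",
    "PriorContext",
]

TOO_CLOSE_PENALTY = -4.0
MANDIBLE_CENTER = range(21, 29)
MANDIBLE_MOLARS = frozenset(range(17, 20)) | frozenset(range(30, 33))


@dataclass(frozen=True)
class PriorParams:
    """Distance thresholds (pixels) for one (x, y) comparison context."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    range: float
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.a <= self.b <= self.c <= self.d <= self.e <= self.f):
            raise ValueError(f"thresholds must be ordered 0 < a <= ... <= f: {self}")


@dataclass(frozen=True)
class ObjectiveWeights:
    omega_p: float = 0.8
    omega_c: float = 0.2

    def __post_init__(self) -> None:
        if self.omega_p < 0 or self.omega_c < 0:
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class PriorConfig:
    kappa: float = 0.0
    d_variant: str = "as_printed"  # or "quartile"
    mandible_center_halving: bool = True
    molar_e_factor: float = 1.5


def derive_params(
    width: float,
    x: int,
    y: int,
    variant: str = "as_printed",
    *,
    kappa: float = 0.0,
    config: PriorConfig | None = None,
) -> PriorParams:
    """Derive the delta thresholds for comparing teeth x and y.

    x and y must belong to the same jaw with |x - y| in {1, 2}.
    """
    if config is None:
        config = PriorConfig(kappa=kappa, d_variant=variant)
    gap = abs(x - y)
    if gap not in (1, 2):
        raise ValueError(f"teeth must be nearest or next-nearest neighbors: {x}, {y}")
    if jaw_numbers(x) != jaw_numbers(y):
        raise ValueError(f"teeth must share a jaw: {x}, {y}")
    if config.d_variant not in ("as_printed", "quartile"):
        raise ValueError(f"unknown d variant: {config.d_variant!r}")

    unit = width * 0.55 / 16
    b = unit * 0.4
    e = unit * 2
    if config.mandible_center_halving and x in MANDIBLE_CENTER and y in MANDIBLE_CENTER:
        b = b / 2
    if x in MANDIBLE_MOLARS or y in MANDIBLE_MOLARS:
        e = e * config.molar_e_factor

    rng = e - b
    a = b / 2
    c = b + rng / 4
    d = c + rng / 4 * 3 if config.d_variant == "as_printed" else b + rng / 4 * 3
    f = e + rng / 4

    if gap == 2:
        shift = c
        a = c
        b, c, d, e, f = b + shift, c + shift, d + shift, e + shift, f + shift
    return PriorParams(a, b, c, d, e, f, rng, kappa=config.kappa)


def signed_gap(x: int, y: int, cx_x: float, cx_y: float) -> float:
    """Center-x separation of teeth x and y along the jaw's numbering
    direction: positive when the higher-numbered tooth lies on its expected
    side (right in the maxilla, left in the mandible), negative when the
    pair is reversed."""
    lo, hi = (x, y) if x < y else (y, x)
    cx_lo, cx_hi = (cx_x, cx_y) if x < y else (cx_y, cx_x)
    return cx_hi - cx_lo if hi <= 16 else cx_lo - cx_hi


def delta_of_gap(g: float, params: PriorParams) -> float:
    """Piecewise positional score for a signed center-x gap (negative =
    reversed pair, first branch)."""
    a, b, c, d, e, f = params.a, params.b, params.c, params.d, params.e, params.f
    if g < a:
        return TOO_CLOSE_PENALTY
    if g < b:
        return 0.0
    if g < c:
        return (g - b) / (c - b)
    if g < d:
        return 1.0
    if g < e:  # empty when d == e
        return 1.0 - (g - d) / (e - d)
    if g < f:
        return 0.0
    return TOO_CLOSE_PENALTY


def delta(x: int, y: int, P: Combination, params: PriorParams) -> float:
    """Positional score of the chosen candidates for teeth x and y; kappa if
    either slot is missing."""
    cand_x, cand_y = P[x], P[y]
    if cand_x is None or cand_y is None:
        return params.kappa
    return delta_of_gap(signed_gap(x, y, cand_x.box.cx, cand_y.box.cx), params)


def neighbor_set(x: int) -> list[int]:
    """Same-jaw neighbor set Omega = {x-2, x-1, x+1, x+2} of a tooth."""
    jaw = jaw_numbers(x)
    return [y for y in (x - 2, x - 1, x + 1, x + 2) if y in jaw]


def fp_tooth(
    x: int,
    P: Combination,
    width: float,
    config: PriorConfig = PriorConfig(),
) -> float:
    """Mean delta of tooth x against its same-jaw neighbors (0 if none)."""
    omega = neighbor_set(x)
    if not omega:
        return 0.0
    total = sum(
        delta(x, y, P, derive_params(width, x, y, config=config)) for y in omega
    )
    return total / len(omega)


def objective(
    P: Combination,
    width: float,
    weights: ObjectiveWeights = ObjectiveWeights(),
    config: PriorConfig = PriorConfig(),
) -> float:
    """Reference (plain-Python) evaluation of f(P).

    f_p is the mean of fp_tooth over the 32 slots; f_c the mean confidence
    with missing slots contributing 0.
    """
    fp = sum(fp_tooth(x, P, width, config) for x in range(1, 33)) / 32
    fc = sum(c.mu for c in P.choice if c is not None) / 32
    return weights.omega_p * fp + weights.omega_c * fc


class PriorContext:
    """Vectorized objective evaluator for a fixed image width and config.

    Precomputes the ordered neighbor-pair list and per-pair thresholds so
    that batches of combinations (rows) can be scored with numpy.  Missing
    slots are encoded as NaN center x and confidence 0.
    """

    def __init__(
        self,
        width: float,
        weights: ObjectiveWeights = ObjectiveWeights(),
        config: PriorConfig = PriorConfig(),
    ):
        self.width = width
        self.weights = weights
        self.config = config
        lo_idx, hi_idx, signs, wts, params = [], [], [], [], []
        for x in range(1, 33):
            omega = neighbor_set(x)
            for y in omega:
                lo, hi = min(x, y), max(x, y)
                lo_idx.append(lo - 1)
                hi_idx.append(hi - 1)
                signs.append(1.0 if hi <= 16 else -1.0)
                wts.append(1.0 / (32 * len(omega)))
                params.append(derive_params(width, x, y, config=config))
        self.pair_lo = np.array(lo_idx)
        self.pair_hi = np.array(hi_idx)
        self.pair_sign = np.array(signs)
        self.pair_weight = np.array(wts)
        self.pa = np.array([p.a for p in params])
        self.pb = np.array([p.b for p in params])
        self.pc = np.array([p.c for p in params])
        self.pd = np.array([p.d for p in params])
        self.pe = np.array([p.e for p in params])
        self.pf = np.array([p.f for p in params])

    def objective_batch(self, cx: np.ndarray, mu: np.ndarray) -> np.ndarray:
        """Score combinations given as (n, 32) arrays of center x (NaN for
        missing) and confidence (0 for missing)."""
        cx = np.atleast_2d(np.asarray(cx, dtype=float))
        mu = np.atleast_2d(np.asarray(mu, dtype=float))
        g = self.pair_sign * (cx[:, self.pair_hi] - cx[:, self.pair_lo])
        with np.errstate(invalid="ignore"):
            # trapezoid: ramp up on [b, c), plateau [c, d), ramp down [d, e)
            # (a unit step at d when d == e), zero shoulders, -4 cliffs
            d = np.clip((g - self.pb) / (self.pc - self.pb), 0.0, 1.0)
            de = self.pe - self.pd
            d -= np.where(
                de > 0,
                np.clip((g - self.pd) / np.where(de > 0, de, 1.0), 0.0, 1.0),
                (g >= self.pd) * 1.0,
            )
            d = np.where((g < self.pa) | (g >= self.pf), TOO_CLOSE_PENALTY, d)
            d = np.where(np.isnan(g), self.config.kappa, d)
        fp = d @ self.pair_weight
        fc = mu.mean(axis=1)
        return self.weights.omega_p * fp + self.weights.omega_c * fc

    @staticmethod
    def arrays_of(P: Combination) -> tuple[np.ndarray, np.ndarray]:
        cx = np.full(32, np.nan)
        mu = np.zeros(32)
        for i, cand in enumerate(P.choice):
            if cand is not None:
                cx[i] = cand.box.cx
                mu[i] = cand.mu
        return cx, mu

    def objective_of(self, P: Combination) -> float:
        cx, mu = self.arrays_of(P)
        return float(self.objective_batch(cx[None, :], mu[None, :])[0])
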