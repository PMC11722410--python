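"""Closed-form and numerical companion to the group-structured simulator.

A single group of size ``n`` performs a pure-birth random walk on ``[0, K]``
with per-step survival probability ``delta`` (elimination resets it to the
absorbing state 0) and upward step probability ``b * t_up(n, K)`` where
``t_up(n, K) = (n/K)(1 - n/K)``.  The probability ``psi(n)`` of reaching the
splitting threshold ``K`` before elimination has the product form

    psi_n = prod_{l=n}^{K-1}  delta b T_l / (1 - delta + delta b T_l),

with the proliferation criterion for a population of such groups being that
the average over initial sizes exceeds one half, ``<psi> > 1/2``: on average
more than one of the two daughters of a split must itself reach the threshold.
In the high-survival limit ``delta -> 1`` the average linearises to
``<psi> ~ 1 - (1-delta) H_{K-1} K^2 / (b (K-1))`` (``H`` a harmonic number),
which yields closed-form thresholds in ``mu``, ``Ng``, the social trait
strength ``a`` and the asocial advantage ``b`` for both the relative and the
absolute fitness-advantage modes.  In the rare-death limit the group-level
competition collapses to a one-step birth--death (Moran) chain whose fixation
probability depends only on the bias ratio ``1 - a``.

Thresholds that fall outside their admissible ranges (``a`` in [0,1], ``b`` in
[1,4], probabilities in [0,1]) are returned together with an out-of-regime
flag rather than silently clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SurvivalContext",
    "harmonic",
    "t_up",
    "psi",
    "psi_avg",
    "psi_avg_high_delta",
    "delta_star",
    "neutral_threshold",
    "solve_threshold_numeric",
    "survival_probs",
    "competition_thresholds",
    "psi_half_a",
    "psi_half_b",
    "psi_half_ng",
    "psi_half_curves",
    "moran_limit_transitions",
    "fixation_probability",
]

Mode = Literal["relative", "absolute"]


@dataclass(frozen=True)
class SurvivalContext:
    """Per-step group survival probability, splitting threshold and asocial
    reproduction scale factor for a single group's absorption problem."""

    delta: float
    K: int
    b: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must lie in [0, 1], got {self.delta}")
        if self.K < 2:
            raise ValueError(f"K must be >= 2, got {self.K}")


def harmonic(n: int) -> float:
    """Harmonic number H_n = sum_{i=1}^{n} 1/i by direct summation."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def t_up(l: int | np.ndarray, K: int) -> float | np.ndarray:
    """Upward transition probability (l/K)(1 - l/K) of the size walk."""
    l = np.asarray(l, float)
    out = (l / K) * (K - l) / K
    return float(out) if out.ndim == 0 else out


def psi(n: int, ctx: SurvivalContext) -> float:
    """Probability of reaching the threshold K before elimination, from size n."""
    if not 1 <= n <= ctx.K:
        raise ValueError(f"n must lie in [1, K], got {n}")
    ls = np.arange(n, ctx.K)
    bt = ctx.b * t_up(ls, ctx.K)
    num = ctx.delta * bt
    return float(np.prod(num / (1.0 - ctx.delta + num)))


def psi_avg(ctx: SurvivalContext) -> float:
    """Mean of psi over the initial sizes {1..K-1}."""
    return float(np.mean([psi(n, ctx) for n in range(1, ctx.K)]))


def psi_avg_high_delta(ctx: SurvivalContext) -> float:
    """First-order high-survival expansion of the averaged absorption
    probability: 1 - (1-delta) H_{K-1} K^2 / (b (K-1))."""
    K = ctx.K
    return 1.0 - (1.0 - ctx.delta) * harmonic(K - 1) * K**2 / (ctx.b * (K - 1))


def delta_star(K: int, b: float = 1.0) -> float:
    """Survival probability at which <psi> = 1/2 in the high-delta limit.

    delta* = 1 - b (K-1) / (2 H_{K-1} K^2).  Raises if the value leaves
    [0, 1], i.e. the expansion regime does not apply.
    """
    val = 1.0 - b * (K - 1) / (2.0 * harmonic(K - 1) * K**2)
    if not 0.0 <= val <= 1.0:
        raise ValueError(f"delta* = {val} outside [0, 1]: high-delta regime invalid")
    return val


def neutral_threshold(
    K: int, b: float = 1.0, Ng: float | None = None, mu: float | None = None
) -> float:
    """Proliferation threshold mu/Ng = b (K-1) / (2 H_{K-1} K^2).

    Give ``Ng`` to obtain the critical death probability mu*, or ``mu`` to
    obtain the critical initial group number Ng*.  A mu* above 1 is flagged
    (the threshold lies beyond the admissible probability range).
    """
    if (Ng is None) == (mu is None):
        raise ValueError("provide exactly one of Ng or mu")
    ratio = b * (K - 1) / (2.0 * harmonic(K - 1) * K**2)
    if Ng is not None:
        mu_star = Ng * ratio
        if mu_star > 1.0:
            raise ValueError(
                f"mu* = {mu_star} > 1: no admissible death-probability threshold"
            )
        return mu_star
    return mu / ratio


def solve_threshold_numeric(K: int, Ng: float, b: float = 1.0) -> float:
    """Critical mu solving <psi(1 - mu/Ng, K)> = 1/2 without the high-delta
    assumption, by bracketed root-finding to 1e-8."""
    def g(mu: float) -> float:
        return psi_avg(SurvivalContext(1.0 - mu / Ng, K, b)) - 0.5

    lo, hi = 1e-12, float(Ng)
    if g(lo) <= 0 or g(hi) >= 0:
        raise ValueError("no proliferation threshold bracketed in (0, Ng]")
    return float(brentq(g, lo, hi, xtol=1e-8))


def survival_probs(
    mode: Mode, Ng: float, NgA: float, mu: float, a: float
) -> tuple[float, float]:
    """Per-step survival probabilities (deltaA, deltaB) of all-A and all-B
    groups in a homogeneous-group population with NgA all-A groups of Ng.

    relative:  deltaA = 1 - mu(1-a)/(Ng - a NgA), deltaB = 1 - mu/(Ng - a NgA)
    absolute:  deltaA = 1 - mu(1-a)/Ng,           deltaB = 1 - mu/Ng
    """
    if not 0 <= NgA <= Ng:
        raise ValueError("need 0 <= NgA <= Ng")
    if mode == "relative":
        denom = Ng - a * NgA
        if denom <= 0:
            raise ValueError("relative mode requires Ng - a*NgA > 0")
        dA, dB = 1.0 - mu * (1.0 - a) / denom, 1.0 - mu / denom
    elif mode == "absolute":
        dA, dB = 1.0 - mu * (1.0 - a) / Ng, 1.0 - mu / Ng
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for d in (dA, dB):
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"survival probability {d} outside [0, 1]")
    return dA, dB


@dataclass(frozen=True)
class Thresholds:
    """Critical social trait strength and asocial advantage, with regime flags
    marking values outside a in [0,1] / b in [1,4]."""

    a_star: float
    b_star: float
    a_in_regime: bool
    b_in_regime: bool


def competition_thresholds(
    mode: Mode, mu: float, K: int, Ng: float, NgA: float | None = None
) -> Thresholds:
    """High-survival-limit thresholds a*, b* solving psiA = psiB = 1/2.

    relative:  a* = ((K-1)Ng - 2 mu H K^2) / ((K-1)NgA - 2 mu H K^2),
               b* = b*(a*) = 2 mu H K^2 / ((K-1)(Ng - a* NgA))
    absolute:  a* = 1 - (K-1)Ng / (2 mu H K^2),
               b* = 2 mu H K^2 / ((K-1) Ng)
    """
    C = 2.0 * mu * harmonic(K - 1) * K**2
    if mode == "relative":
        if NgA is None:
            raise ValueError("relative mode needs NgA")
        a_star = ((K - 1) * Ng - C) / ((K - 1) * NgA - C)
        b_star = C / ((K - 1) * (Ng - a_star * NgA))
    elif mode == "absolute":
        a_star = 1.0 - (K - 1) * Ng / C
        b_star = C / ((K - 1) * Ng)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Thresholds(
        a_star, b_star, 0.0 <= a_star <= 1.0, 1.0 <= b_star <= 4.0
    )


def b_star_of_a(mode: Mode, mu: float, K: int, Ng: float, NgA: float, a: float) -> float:
    """High-survival cheater threshold b*(a) at a given social trait strength."""
    C = 2.0 * mu * harmonic(K - 1) * K**2
    denom = Ng - a * NgA if mode == "relative" else Ng
    return C / ((K - 1) * denom)


def psi_half_a(mode: Mode, mu: float, K: int, Ng: float, NgA: float) -> float:
    """Social trait strength at which the all-A proliferation probability
    crosses 1/2 (numeric, no high-delta assumption; independent of b)."""
    def g(a: float) -> float:
        dA, _ = survival_probs(mode, Ng, NgA, mu, a)
        return psi_avg(SurvivalContext(dA, K, 1.0)) - 0.5

    if g(0.0) >= 0:
        raise ValueError("all-A groups proliferate already at a = 0")
    if g(1.0) <= 0:
        raise ValueError("all-A groups cannot proliferate even at a = 1")
    return float(brentq(g, 0.0, 1.0, xtol=1e-10))


def psi_half_b(mode: Mode, mu: float, K: int, Ng: float, NgA: float, a: float) -> float:
    """Asocial advantage at which the all-B proliferation probability crosses
    1/2, for a given social trait strength (numeric)."""
    def g(b: float) -> float:
        _, dB = survival_probs(mode, Ng, NgA, mu, a)
        return psi_avg(SurvivalContext(dB, K, b)) - 0.5

    if g(1.0) >= 0:
        raise ValueError("all-B groups proliferate already at b = 1")
    if g(4.0) <= 0:
        raise ValueError("all-B groups cannot proliferate even at b = 4")
    return float(brentq(g, 1.0, 4.0, xtol=1e-10))


def psi_half_ng(
    mode: Mode,
    mu: float,
    K: int,
    b: float,
    which: Literal["A", "B"],
    a: float,
    frac_A: float = 0.5,
    ng_max: float = 1e4,
) -> float:
    """Smallest initial group number Ng at which the proliferation probability
    of the given homogeneous type crosses 1/2, with NgA = frac_A * Ng."""
    def g(Ng: float) -> float:
        dA, dB = survival_probs(mode, Ng, frac_A * Ng, mu, a)
        if which == "A":
            return psi_avg(SurvivalContext(dA, K, 1.0)) - 0.5
        return psi_avg(SurvivalContext(dB, K, b)) - 0.5

    lo = mu / (1.0 - a * frac_A) + 1e-9 if mode == "relative" else mu + 1e-9
    if g(lo) >= 0 or g(ng_max) <= 0:
        raise ValueError("no Ng threshold bracketed")
    return float(brentq(g, lo, ng_max, xtol=1e-8))


def psi_half_curves(
    mode: Mode,
    mu: float,
    K: int,
    Ng: float,
    NgA: float,
    b_grid: np.ndarray,
) -> "np.recarray":
    """Numeric psiA = 1/2 and psiB = 1/2 curves over an asocial-advantage grid.

    Returns a record array with fields (b, a_A, a_B, ok_A, ok_B): ``a_A`` is
    the cooperator threshold (independent of b by construction), ``a_B`` the
    social trait strength at which all-B proliferation crosses 1/2 for the
    given b (relative mode; constant in the absolute mode).  Cells without a
    root inside the admissible range are marked not-ok.
    """
    b_grid = np.asarray(b_grid, float)
    out = np.recarray(
        b_grid.shape,
        dtype=[("b", float), ("a_A", float), ("a_B", float),
               ("ok_A", bool), ("ok_B", bool)],
    )
    try:
        a_A = psi_half_a(mode, mu, K, Ng, NgA)
        ok_A = True
    except ValueError:
        a_A, ok_A = np.nan, False

    for i, b in enumerate(b_grid):
        def g(a: float, b: float = b) -> float:
            _, dB = survival_probs(mode, Ng, NgA, mu, a)
            return psi_avg(SurvivalContext(dB, K, b)) - 0.5

        try:
            if g(0.0) * g(1.0) < 0:
                a_B, ok_B = float(brentq(g, 0.0, 1.0, xtol=1e-10)), True
            else:
                a_B, ok_B = np.nan, False
        except ValueError:
            a_B, ok_B = np.nan, False
        out[i] = (b, a_A, a_B, ok_A, ok_B)
    return out


def moran_limit_transitions(
    mode: Mode, NgA: int, Kg: int, mu: float, a: float
) -> tuple[float, float]:
    """(T_down, T_up) of the rare-death birth--death chain over the number of
    all-A groups in a population at carrying capacity.

    In both fitness modes the ratio T_down / T_up equals 1 - a; mu only sets
    the clock.
    """
    if not 0 < NgA < Kg:
        raise ValueError("need 0 < NgA < Kg")
    wA = NgA * (1.0 - a)
    wB = Kg - NgA
    if mode == "relative":
        t_down = mu * (wB / Kg) * (wA / (wA + wB))
        t_up_ = mu * (NgA / Kg) * (wB / (wA + wB))
    elif mode == "absolute":
        t_down = mu * (1.0 - a) * (NgA / Kg) * (wB / Kg)
        t_up_ = mu * (NgA / Kg) * (wB / Kg)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return t_down, t_up_


def fixation_probability(NgA0: int, Kg: int, a: float) -> float:
    """Fixation probability of the social type in the rare-death limit.

    Constant-bias birth--death chain: phi = (1 - (1-a)^NgA0) / (1 - (1-a)^Kg)
    for a > 0, reducing to the neutral NgA0/Kg at a = 0.
    """
    if not 0 <= NgA0 <= Kg:
        raise ValueError("need 0 <= NgA0 <= Kg")
    if NgA0 == 0:
        return 0.0
    if NgA0 == Kg:
        return 1.0
    if a == 0.0:
        return NgA0 / Kg
    r = 1.0 - a
    return float((1.0 - r**NgA0) / (1.0 - r**Kg))
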