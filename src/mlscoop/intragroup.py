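"""Within-group reproduction dynamics.

A group occupies ``K`` sites shared between social individuals (A), asocial
individuals (B) and untouched resources ``R = K - nA - nB``.  Per time step at
most one individual reproduces: an A with probability ``(nA/K)(1 - n/K)``, a B
with probability ``b (nB/K)(1 - n/K)`` where ``n = nA + nB`` and ``b >= 1`` is
the frequency-independent reproductive advantage of the asocial type.  The two
probabilities sum to at most 1 for every occupancy exactly when ``b <= 4`` (the
sum is maximised at ``nA = 0, nB = K/2``), which is why ``b`` lives in
``[1, 4]``.  There is no individual death; groups only grow until they hit the
splitting threshold ``K``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "GroupState",
    "IntragroupParams",
    "reproduction_probs",
    "reproduction_probs_arrays",
    "step_group",
]


@dataclass(frozen=True)
class GroupState:
    """Composition of one group: counts of social (A) and asocial (B) members."""

    nA: int
    nB: int

    def __post_init__(self) -> None:
        if self.nA < 0 or self.nB < 0:
            raise ValueError(f"negative counts: nA={self.nA}, nB={self.nB}")

    @property
    def size(self) -> int:
        return self.nA + self.nB


@dataclass(frozen=True)
class IntragroupParams:
    """Splitting threshold ``K`` (group site count) and asocial scale factor ``b``."""

    K: int
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError(f"K must be >= 2, got {self.K}")
        if not 1.0 <= self.b <= 4.0:
            raise ValueError(f"b must lie in [1, 4], got {self.b}")


def _validate(g: GroupState, p: IntragroupParams) -> None:
    if g.size > p.K:
        raise ValueError(f"group size {g.size} exceeds threshold K={p.K}")


def reproduction_probs(
    g: GroupState, p: IntragroupParams
) -> tuple[float, float, float]:
    """Per-step probabilities (A birth, B birth, no event) for one group.

    The vacancy factor ``1 - n/K`` is computed as ``(K - n)/K`` so that a group
    at the threshold gets exactly zero reproduction probability, and the three
    returned values sum to 1 exactly.
    """
    _validate(g, p)
    K = p.K
    free = Fraction(K - g.size, K)
    pA = float(Fraction(g.nA, K) * free)
    pB = float(p.b) * float(Fraction(g.nB, K) * free)
    p0 = 1.0 - pA - pB
    return pA, pB, p0


def reproduction_probs_arrays(
    nA: np.ndarray, nB: np.ndarray, K: int, b: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (pA, pB) over arrays of group compositions."""
    n = nA + nB
    if np.any(n > K):
        raise ValueError("group size exceeds threshold K")
    free = (K - n) / K
    return (nA / K) * free, b * (nB / K) * free


def step_group(
    g: GroupState, p: IntragroupParams, rng: np.random.Generator
) -> GroupState:
    """Advance one group by one time step.

    A single uniform variate is partitioned into ``[0, pA)``, ``[pA, pA+pB)``
    and the remainder, so trajectories are reproducible from a seed.
    """
    pA, pB, _ = reproduction_probs(g, p)
    u = rng.random()
    if u < pA:
        return GroupState(g.nA + 1, g.nB)
    if u < pA + pB:
        return GroupState(g.nA, g.nB + 1)
    return g
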