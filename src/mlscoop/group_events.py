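"""Group-level death and splitting.

Group death: with total probability ``mu`` per time step (at most one death per
step), the victim is chosen according to one of three weighting schemes over
the cooperator fractions ``f_j = nA_j / (nA_j + nB_j)``:

``neutral``
    every group is equally likely, ``mu / Ng`` each;
``relative``
    weights ``1 - a f_j`` normalised over the population, so a group is
    protected only relative to the others and the total death probability is
    exactly ``mu`` regardless of composition;
``absolute``
    ``(mu/Ng)(1 - a f_j)`` per group, so cooperators lower the total death
    probability itself (the sum is at most ``mu``).

Splitting: whenever at least one group has reached the threshold ``K`` and the
population is below the group carrying capacity ``Kg``, exactly one group at
the threshold (chosen uniformly) splits.  Each daughter receives a uniform
random number of the parent's A's and, independently, of its B's; an empty
daughter is eliminated on the spot, which makes the split abortive (the parent
effectively survives unchanged and may split again next step).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Literal, Optional

import numpy as np

from .intragroup import GroupState

if TYPE_CHECKING:  # pragma: no cover
    from .simulator import PopulationState

__all__ = [
    "GroupLevelParams",
    "SplitOutcome",
    "death_probabilities",
    "sample_death",
    "select_splitter",
    "split_group",
]

Mode = Literal["neutral", "relative", "absolute"]

#: tolerance used when validating probability sums
PROB_TOL = 1e-12


@dataclass(frozen=True)
class GroupLevelParams:
    """Death probability ``mu``, social trait strength ``a``, carrying capacity
    ``Kg`` and the fitness mode of the social trait."""

    mu: float
    a: float = 0.0
    Kg: int = 1
    mode: Mode = "neutral"

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"a must lie in [0, 1], got {self.a}")
        if self.Kg < 1:
            raise ValueError(f"Kg must be >= 1, got {self.Kg}")
        if self.mode not in ("neutral", "relative", "absolute"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class SplitOutcome:
    """Result of a splitting event: two daughters, or an abortive split in
    which the surviving daughter equals the parent."""

    kind: Literal["two_daughters", "abortive"]
    daughters: tuple[GroupState, ...]


def death_probabilities(pop: "PopulationState", p: GroupLevelParams) -> np.ndarray:
    """Per-group death probabilities for the current population.

    Raises if the population is empty or contains an empty group.  In the
    relative mode, if every weight ``1 - a f_j`` vanishes (all-cooperator
    population at ``a = 1``), the weights degenerate to 0/0 and the uniform
    ``mu / Ng`` split is used, preserving the total-death-probability
    conservation of that mode.
    """
    nA, nB = np.asarray(pop.nA, float), np.asarray(pop.nB, float)
    ng = len(nA)
    if ng == 0:
        raise ValueError("empty population")
    size = nA + nB
    if np.any(size == 0):
        raise ValueError("population contains an empty group")
    if p.mode == "neutral":
        return np.full(ng, p.mu / ng)
    f = nA / size
    w = 1.0 - p.a * f
    if p.mode == "relative":
        W = w.sum()
        if W <= 0.0:
            return np.full(ng, p.mu / ng)
        return p.mu * w / W
    return (p.mu / ng) * w  # absolute


def sample_death(probs: np.ndarray, rng: np.random.Generator) -> Optional[int]:
    """Draw at most one death: returns the victim's index, or None.

    A single uniform variate is compared against the cumulative partition of
    ``probs``; the leftover mass ``1 - sum(probs)`` maps to "no death".
    """
    probs = np.asarray(probs, float)
    total = probs.sum()
    if total > 1.0 + PROB_TOL:
        raise ValueError(f"death probabilities sum to {total} > 1")
    u = rng.random()
    cum = np.cumsum(probs)
    idx = int(np.searchsorted(cum, u, side="right"))
    return idx if idx < len(probs) else None


def select_splitter(
    pop: "PopulationState", p: GroupLevelParams, K: int, rng: np.random.Generator
) -> Optional[int]:
    """Uniformly pick one group at the splitting threshold, or None.

    Returns None when no group has reached ``K`` or the population is at the
    group carrying capacity (splitting blocked).
    """
    nA, nB = np.asarray(pop.nA), np.asarray(pop.nB)
    if len(nA) >= p.Kg:
        return None
    at_threshold = np.flatnonzero(nA + nB == K)
    if at_threshold.size == 0:
        return None
    return int(at_threshold[rng.integers(0, at_threshold.size)])


def split_group(g: GroupState, K: int, rng: np.random.Generator) -> SplitOutcome:
    """Split a threshold-sized group by independent uniform allocation.

    ``mA ~ U{0..nA}`` and ``mB ~ U{0..nB}`` are drawn independently (this is
    deliberately *not* a hypergeometric partition of the K individuals).  If
    either daughter ends up empty the outcome is abortive and the single
    returned daughter equals the parent.
    """
    if g.size != K:
        raise ValueError(f"split requires size == K ({K}), got {g.size}")
    mA = int(rng.integers(0, g.nA + 1))
    mB = int(rng.integers(0, g.nB + 1))
    d1 = GroupState(mA, mB)
    d2 = GroupState(g.nA - mA, g.nB - mB)
    if d1.size == 0 or d2.size == 0:
        survivor = d1 if d1.size > 0 else d2
        return SplitOutcome("abortive", (survivor,))
    return SplitOutcome("two_daughters", (d1, d2))
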