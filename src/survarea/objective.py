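"""The area-under-the-survival-curve training objective.

A candidate risk group is scored by the area A of its Kaplan-Meier curve
on a fixed horizon [0, t_N]:

    A = sum_i S_i (t_{i+1} - t_i),      0 <= A <= t_N,

the exact integral of the KM step function with S = 1 before the first
event and the last segment extended flat to t_N.  A low-risk classifier
maximizes A; a high-risk classifier maximizes the complement
A' = t_N - A.  A hard minimum group size m keeps the optimizer from
collapsing onto one or two extreme survivors: any group with fewer than m
members scores exactly 0 (higher is always better).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SurvivalDataset
from .kaplan_meier import KaplanMeierCurve

__all__ = [
    "GroupMembership",
    "FitnessSpec",
    "area_under_curve",
    "complement_area",
    "group_fitness",
    "AreaFitness",
]


@dataclass(frozen=True)
class GroupMembership:
    """Binary membership mask over a dataset's subjects."""

    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask)
        if not np.isin(m, (0, 1)).all():
            raise ValueError("membership mask must be binary")
        object.__setattr__(self, "mask", m.astype(bool))

    @property
    def M(self) -> int:
        """Number of subjects in the group."""
        return int(self.mask.sum())


@dataclass(frozen=True)
class FitnessSpec:
    """What a classifier is rewarded for.

    mode : "maximize" for low-risk groups (reward A), "minimize" for
        high-risk groups (reward A' = t_N - A).
    m : hard minimum group size; groups smaller than m score 0.
    t_N : common horizon, fixed per training run (the maximum follow-up
        of the training data), so scores are comparable across candidates.
    """

    mode: str
    m: int
    t_N: float

    def __post_init__(self):
        if self.mode not in ("maximize", "minimize"):
            raise ValueError("mode must be 'maximize' or 'minimize'")
        if self.m < 1:
            raise ValueError("minimum group size m must be >= 1")
        if self.t_N <= 0:
            raise ValueError("horizon t_N must be positive")


def area_under_curve(curve: KaplanMeierCurve, t_N: float) -> float:
    """Exact integral of the KM step function over [0, t_N]."""
    if t_N < curve.last_time:
        raise ValueError(
            f"t_N={t_N} is smaller than the curve's last time point "
            f"{curve.last_time}"
        )
    edges = np.concatenate(([0.0], curve.time_points, [t_N]))
    heights = np.concatenate(([1.0], curve.survival))
    return float(np.dot(heights, np.diff(edges)))


def complement_area(A: float, t_N: float) -> float:
    """A' = t_N - A, the score maximized when hunting high-risk groups."""
    if A > t_N:
        raise ValueError(f"area A={A} exceeds its maximum t_N={t_N}")
    if A < 0:
        raise ValueError("area must be non-negative")
    return t_N - A


def group_fitness(
    data: SurvivalDataset, membership: GroupMembership, spec: FitnessSpec
) -> float:
    """Score of one candidate group: A or A' if |group| >= m, else 0."""
    if len(membership.mask) != len(data):
        raise ValueError("membership mask must align with the dataset")
    evaluator = AreaFitness(data.times, data.events, spec)
    return evaluator(membership.mask)


class AreaFitness:
    """Vectorized fitness evaluator bound to one (sub)sample.

    Pre-sorts the sample once so that scoring a membership mask is a
    single pass: select the members in sorted-time order, form the
    product-limit factors at their event times, and integrate the step
    function to t_N.  This is the hot path of genetic training.
    """

    def __init__(self, times, events, spec: FitnessSpec):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events)
        if times.max() > spec.t_N:
            raise ValueError("t_N must cover every follow-up time in the sample")
        self.spec = spec
        self._order = np.argsort(times, kind="stable")
        self._t_sorted = times[self._order]
        self._e_sorted = events[self._order].astype(bool)
        self.n = len(times)

    def area(self, mask: np.ndarray) -> float:
        """KM area of the masked subgroup on [0, t_N]; mask must be non-empty."""
        ms = np.asarray(mask, dtype=bool)[self._order]
        t = self._t_sorted[ms]
        e = self._e_sorted[ms]
        t_N = self.spec.t_N
        if not e.any():
            return t_N  # flat curve: no events observed
        uniq, start = np.unique(t, return_index=True)
        d = np.add.reduceat(e.astype(np.int64), start)
        n_risk = len(t) - start
        ev = d > 0
        surv = np.cumprod(1.0 - d[ev] / n_risk[ev])
        edges = np.concatenate(([0.0], uniq[ev], [t_N]))
        heights = np.concatenate(([1.0], surv))
        return float(np.dot(heights, np.diff(edges)))

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if len(mask) != self.n:
            raise ValueError("membership mask must align with the sample")
        if int(mask.sum()) < self.spec.m:
            return 0.0
        A = self.area(mask)
        return A if self.spec.mode == "maximize" else self.spec.t_N - A
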