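"""Kaplan-Meier (product-limit) estimation as a light-weight step function.

The estimator here is deliberately a thin numpy routine rather than a
wrapper around a survival library: it sits in the inner loop of the
genetic training procedure, where it is evaluated on the order of 1e5
times per run, on candidate subgroups of the training sample.  Its output
agrees with standard implementations (ties handled by the usual
convention that subjects censored at t are still at risk for events at t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SurvivalDataset

__all__ = [
    "KaplanMeierCurve",
    "km_estimate",
    "km_from_arrays",
    "median_survival_time",
    "end_survival_rate",
]


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Step-function estimate of a survival curve.

    ``survival[i]`` is the survival probability just after
    ``time_points[i]``; the curve equals 1 on ``[0, time_points[0])``.
    Only times with at least one observed event contribute a step.
    """

    time_points: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_points, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "time_points", t)
        object.__setattr__(self, "survival", s)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("time_points and survival must be 1-D and aligned")
        if len(t) and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("time_points must be strictly increasing and >= 0")
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if len(s) > 1 and np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing")

    @property
    def n_steps(self) -> int:
        return len(self.time_points)

    @property
    def last_time(self) -> float:
        return float(self.time_points[-1]) if len(self.time_points) else 0.0

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous, flat-extended beyond the last step."""
        idx = np.searchsorted(self.time_points, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.time_points, "survival": self.survival}
        )


def km_from_arrays(times: np.ndarray, events: np.ndarray) -> KaplanMeierCurve:
    """Product-limit estimate from raw arrays (no dataset wrapper).

    At each distinct time t with d observed events out of n subjects still
    at risk (time >= t, censored-at-t included) the curve drops by the
    factor (1 - d/n).  Censoring-only times shrink the risk set but add no
    step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("cannot estimate a curve from zero subjects")
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    # distinct times, deaths per distinct time, at-risk just before it
    uniq, start_idx = np.unique(t, return_index=True)
    d = np.add.reduceat(e.astype(np.int64), start_idx)
    n_at_risk = len(t) - start_idx
    has_event = d > 0
    if not has_event.any():
        return KaplanMeierCurve(np.empty(0), np.empty(0))
    factors = 1.0 - d[has_event] / n_at_risk[has_event]
    return KaplanMeierCurve(uniq[has_event], np.cumprod(factors))


def km_estimate(data: SurvivalDataset) -> KaplanMeierCurve:
    """Kaplan-Meier estimate for a dataset (see :func:`km_from_arrays`)."""
    return km_from_arrays(data.times, data.events)


def median_survival_time(curve: KaplanMeierCurve) -> float | None:
    """Smallest time point at which the curve reaches <= 0.5.

    Returns None when the curve never drops to 0.5 — the median is then
    undefined (not observed within follow-up).
    """
    below = np.flatnonzero(curve.survival <= 0.5 + 1e-12)
    if below.size == 0:
        return None
    return float(curve.time_points[below[0]])


def end_survival_rate(curve: KaplanMeierCurve, t_N: float) -> float:
    """Survival probability at the horizon t_N (flat-extended)."""
    return curve.survival_at(t_N)
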