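"""Risk-group evaluation statistics and comparator utilities.

Predicted groups are judged by their Kaplan-Meier curves: group size,
median survival time (undefined when the curve never reaches 0.5), end
survival rate at the horizon t_N, and the low-minus-high end-survival
difference, whose sign flags crossing curves.  Also provided: quantile
cutting of any prognostic index into groups of prescribed sizes (so a
Cox-style comparator can be matched to the ensemble's group sizes), and
repeated stratified k-fold cross-validation over arbitrary model
factories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SurvivalDataset
from .ensemble import HIGH, INTERMEDIATE, LOW, RISK_LABELS
from .kaplan_meier import (
    KaplanMeierCurve,
    end_survival_rate,
    km_estimate,
    median_survival_time,
)

__all__ = [
    "GroupSummary",
    "summarize_groups",
    "end_survival_difference",
    "learn_index_cuts",
    "apply_index_cuts",
    "index_to_groups",
    "cross_validate",
    "end_survival_differences",
]


@dataclass(frozen=True)
class GroupSummary:
    """Size and survival-curve properties of one predicted risk group."""

    label: str
    size: int
    median_survival: float | None
    end_survival: float | None


def end_survival_difference(
    low_curve: KaplanMeierCurve, high_curve: KaplanMeierCurve, t_N: float
) -> float:
    """S_low(t_N) - S_high(t_N); negative means the curves crossed by t_N."""
    return end_survival_rate(low_curve, t_N) - end_survival_rate(
        high_curve, t_N
    )


def summarize_groups(
    data: SurvivalDataset,
    labels: np.ndarray,
    t_N: float | None = None,
) -> list[GroupSummary]:
    """Per-label size, median survival and end survival on ``data``.

    ``t_N`` defaults to the maximum follow-up in ``data`` so that end
    survival rates are comparable across groupings of the same subjects.
    Empty groups get size 0 and undefined statistics.
    """
    labels = np.asarray(labels)
    if len(labels) != len(data):
        raise ValueError("labels must align with the dataset")
    if t_N is None:
        t_N = data.max_time
    out = []
    for label in RISK_LABELS:
        mask = labels == label
        if not mask.any():
            out.append(GroupSummary(label, 0, None, None))
            continue
        curve = km_estimate(data.subset(mask))
        out.append(
            GroupSummary(
                label,
                int(mask.sum()),
                median_survival_time(curve),
                end_survival_rate(curve, t_N),
            )
        )
    return out


# ------------------------------------------------- prognostic-index cutting

def learn_index_cuts(
    index_values, n_high: int, n_low: int
) -> tuple[float, float]:
    """Cut values giving exactly n_low low / n_high high on this data.

    Higher index = higher risk.  Ties at a cut are broken by stable input
    order (earlier rows fall on the low side), so the learned cuts
    reproduce the requested sizes on the reference data for tie-free
    indices.  Returns (low_cut, high_cut): values <= low_cut are low,
    values >= high_cut are high.
    """
    v = np.asarray(index_values, dtype=float)
    n = len(v)
    if n_high + n_low > n:
        raise ValueError("n_high + n_low exceeds the number of subjects")
    order = np.argsort(v, kind="stable")
    low_cut = v[order[n_low - 1]] if n_low else -np.inf
    high_cut = v[order[n - n_high]] if n_high else np.inf
    return float(low_cut), float(high_cut)


def apply_index_cuts(index_values, cuts: tuple[float, float]) -> np.ndarray:
    """Label values by previously learned cut values (sizes may deviate
    on new data)."""
    v = np.asarray(index_values, dtype=float)
    low_cut, high_cut = cuts
    labels = np.full(len(v), INTERMEDIATE, dtype=object)
    labels[v >= high_cut] = HIGH
    labels[v <= low_cut] = LOW
    return labels.astype(str)


def index_to_groups(index_values, n_high: int, n_low: int) -> np.ndarray:
    """Label the n_high largest index values high, the n_low smallest low,
    everything else intermediate (on the reference data itself)."""
    v = np.asarray(index_values, dtype=float)
    if n_high + n_low > len(v):
        raise ValueError("n_high + n_low exceeds the number of subjects")
    order = np.argsort(v, kind="stable")
    labels = np.full(len(v), INTERMEDIATE, dtype=object)
    if n_low:
        labels[order[:n_low]] = LOW
    if n_high:
        labels[order[len(v) - n_high :]] = HIGH
    return labels.astype(str)


# --------------------------------------------------------- cross-validation

def _stratified_folds(
    events: np.ndarray, folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Partition subject indices into folds, stratified on censoring."""
    assignments = np.empty(len(events), dtype=int)
    for value in (0, 1):
        idx = rng.permutation(np.flatnonzero(events == value))
        for fold, chunk in enumerate(np.array_split(idx, folds)):
            assignments[chunk] = fold
    return [np.flatnonzero(assignments == f) for f in range(folds)]


def cross_validate(
    data: SurvivalDataset,
    model_factories: dict,
    folds: int = 3,
    repeats: int = 10,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Repeated censoring-stratified k-fold evaluation of risk groupers.

    Parameters
    ----------
    model_factories : dict of name -> callable
        Each factory takes the training :class:`SurvivalDataset` and
        returns a predictor ``f(validation_dataset) -> labels``.

    Returns
    -------
    DataFrame with one row per (repeat, fold, model, label) holding
    ``size``, ``median_survival``, ``end_survival`` and the fold horizon
    ``t_N`` (the maximum follow-up of the validation fold, common to all
    models within the fold).
    """
    if rng is None:
        rng = np.random.default_rng()
    if len(data) < 2 * folds:
        raise ValueError("dataset too small for the requested fold count")
    rows = []
    for repeat in range(repeats):
        fold_indices = _stratified_folds(data.events, folds, rng)
        for fold, val_idx in enumerate(fold_indices):
            train_idx = np.concatenate(
                [fold_indices[f] for f in range(folds) if f != fold]
            )
            train_data = data.subset(train_idx)
            val_data = data.subset(val_idx)
            t_N = val_data.max_time
            for name, factory in model_factories.items():
                predictor = factory(train_data)
                labels = np.asarray(predictor(val_data))
                for s in summarize_groups(val_data, labels, t_N):
                    rows.append(
                        {
                            "repeat": repeat,
                            "fold": fold,
                            "model": name,
                            "label": s.label,
                            "size": s.size,
                            "median_survival": s.median_survival,
                            "end_survival": s.end_survival,
                            "t_N": t_N,
                        }
                    )
    return pd.DataFrame(rows)


def end_survival_differences(table: pd.DataFrame) -> pd.DataFrame:
    """Low-minus-high end-survival per (repeat, fold, model) from a
    :func:`cross_validate` table; NaN where either group was empty."""
    wide = table.pivot_table(
        index=["repeat", "fold", "model"],
        columns="label",
        values="end_survival",
        aggfunc="first",
    )
    for col in (LOW, HIGH):
        if col not in wide:
            wide[col] = np.nan
    out = wide.reset_index()[["repeat", "fold", "model"]]
    out["end_survival_difference"] = (
        wide[LOW].to_numpy() - wide[HIGH].to_numpy()
    )
    return out
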