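"""Covariate preparation and data splitting.

The pipeline applied to every dataset before training:

1. categorical columns expanded into one indicator column per level;
2. missing values replaced by the column mean (computed on the data the
   parameters are fitted on — normally the training split);
3. each column z-normalized to zero mean and unit (sample, n-1) standard
   deviation; constant columns are dropped with a warning;
4. a censoring-stratified random split holds out a test fraction
   (default 1/4) whose censored proportion matches the full data to
   within one subject.

All statistics are fitted once and re-applied, so applying training
parameters to a test table never leaks test-set information.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SurvivalDataset

__all__ = [
    "PreprocessParams",
    "Preprocessor",
    "binarize_categoricals",
    "impute_mean",
    "normalize",
    "split_stratified",
]


@dataclass
class PreprocessParams:
    """Everything needed to replay the fitted pipeline on new data."""

    categorical_levels: dict = field(default_factory=dict)
    impute_values: dict = field(default_factory=dict)
    means: dict = field(default_factory=dict)
    stds: dict = field(default_factory=dict)
    dropped_columns: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "categorical_levels": {
                    k: [str(v) for v in levels]
                    for k, levels in self.categorical_levels.items()
                },
                "impute_values": self.impute_values,
                "means": self.means,
                "stds": self.stds,
                "dropped_columns": self.dropped_columns,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PreprocessParams":
        return cls(**json.loads(text))


def binarize_categoricals(
    table: pd.DataFrame,
    categorical_columns,
    levels: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Replace each categorical column of c levels by c 0/1 indicators.

    Indicator columns are named ``col=level``.  A missing value yields an
    all-zero indicator row.  When ``levels`` is supplied (transform mode)
    the stored level sets are used, so unseen levels map to all zeros.
    """
    for col in categorical_columns:
        if col not in table.columns:
            raise ValueError(f"categorical column {col!r} not in table")
    fitted = {}
    out = table.copy()
    for col in categorical_columns:
        values = out[col]
        if levels is None:
            lvls = sorted(values.dropna().astype(str).unique())
        else:
            lvls = [str(v) for v in levels[col]]
        fitted[col] = lvls
        as_str = values.astype("string")
        indicators = {
            f"{col}={lvl}": (as_str == lvl).fillna(False).astype(float)
            for lvl in lvls
        }
        pos = out.columns.get_loc(col)
        out = out.drop(columns=[col])
        for offset, (name, series) in enumerate(indicators.items()):
            out.insert(pos + offset, name, series)
    return out, fitted


def impute_mean(
    table: pd.DataFrame, impute_values: dict | None = None
) -> tuple[pd.DataFrame, dict]:
    """Fill missing entries with the (stored or fitted) column mean."""
    out = table.copy()
    if impute_values is None:
        impute_values = {}
        for col in out.columns:
            mean = out[col].mean()
            if pd.isna(mean):
                raise ValueError(
                    f"column {col!r} has no observed values to impute from"
                )
            impute_values[col] = float(mean)
    out = out.fillna(value=impute_values)
    return out, impute_values


def normalize(
    table: pd.DataFrame, params: tuple[dict, dict, list] | None = None
) -> tuple[pd.DataFrame, tuple[dict, dict, list]]:
    """z-normalize every column; constant columns are dropped.

    Uses the sample (n-1) standard deviation.  Returns the transformed
    table and (means, stds, dropped_columns).
    """
    out = table.copy()
    if params is None:
        means, stds, dropped = {}, {}, []
        for col in out.columns:
            sd = float(out[col].std(ddof=1)) if len(out) > 1 else 0.0
            if not np.isfinite(sd) or sd <= 0.0:
                dropped.append(col)
                continue
            means[col] = float(out[col].mean())
            stds[col] = sd
        if dropped:
            warnings.warn(
                f"dropping constant column(s) {dropped} before normalization",
                stacklevel=2,
            )
    else:
        means, stds, dropped = params
    out = out.drop(columns=[c for c in dropped if c in out.columns])
    for col in means:
        out[col] = (out[col] - means[col]) / stds[col]
    return out, (means, stds, list(dropped))


class Preprocessor:
    """Fit the binarize -> impute -> normalize pipeline, replay it later."""

    def __init__(self, categorical_columns=()):
        self.categorical_columns = list(categorical_columns)
        self.params: PreprocessParams | None = None

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        table, levels = binarize_categoricals(table, self.categorical_columns)
        table, impute_values = impute_mean(table)
        table, (means, stds, dropped) = normalize(table)
        self.params = PreprocessParams(
            categorical_levels=levels,
            impute_values=impute_values,
            means=means,
            stds=stds,
            dropped_columns=dropped,
        )
        return table

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.params is None:
            raise ValueError("call fit_transform before transform")
        p = self.params
        table, _ = binarize_categoricals(
            table, list(p.categorical_levels), levels=p.categorical_levels
        )
        missing = [c for c in p.impute_values if c not in table.columns]
        if missing:
            raise ValueError(f"input table lacks fitted column(s) {missing}")
        table, _ = impute_mean(table, p.impute_values)
        table, _ = normalize(table, (p.means, p.stds, p.dropped_columns))
        # column order as fitted
        return table[[c for c in p.means]]

    @classmethod
    def from_params(cls, params: PreprocessParams) -> "Preprocessor":
        pre = cls(list(params.categorical_levels))
        pre.params = params
        return pre


def split_stratified(
    data: SurvivalDataset,
    test_fraction: float = 0.25,
    rng: np.random.Generator | None = None,
) -> tuple[SurvivalDataset | None, SurvivalDataset | None]:
    """Random train/test split stratified on the censoring indicator.

    Allocation rounds to the nearest integer per stratum; any residual
    against the overall target size is assigned to the larger stratum.
    """
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    n = len(data)
    target_total = int(round(test_fraction * n))
    strata = [np.flatnonzero(data.events == v) for v in (0, 1)]
    for s in strata:
        if 0 < len(s) < 2:
            warnings.warn(
                "a censoring stratum has fewer than 2 subjects; the split "
                "is best-effort",
                stacklevel=2,
            )
    counts = [int(round(test_fraction * len(s))) for s in strata]
    residual = target_total - sum(counts)
    if residual:
        larger = int(np.argmax([len(s) for s in strata]))
        counts[larger] = int(
            np.clip(counts[larger] + residual, 0, len(strata[larger]))
        )
    test_idx = []
    for s, k in zip(strata, counts):
        perm = rng.permutation(s)
        test_idx.extend(perm[:k])
    test_mask = np.zeros(n, dtype=bool)
    test_mask[np.asarray(test_idx, dtype=int)] = True
    train = data.subset(~test_mask) if (~test_mask).any() else None
    test = data.subset(test_mask) if test_mask.any() else None
    return train, test
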