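"""Tabular censored survival data.

A :class:`SurvivalDataset` bundles one follow-up time and one event
indicator per subject with an optional covariate table.  Times share a
single unit (typically days); ``event == 1`` means the event was observed,
``event == 0`` means the subject was right-censored at that time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset"]

#: CSV columns that are reserved for the outcome.
TIME_COL = "time"
EVENT_COL = "event"


@dataclass
class SurvivalDataset:
    """Follow-up times, event indicators and covariates for a cohort.

    Parameters
    ----------
    times : array-like of float
        Non-negative follow-up durations, one per subject.
    events : array-like of int
        1 if the event was observed at ``times[i]``, 0 if censored there.
    covariates : pandas.DataFrame, optional
        One row per subject.  May be omitted for curve-only computations.
    """

    times: np.ndarray
    events: np.ndarray
    covariates: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events)
        if self.times.ndim != 1 or self.events.ndim != 1:
            raise ValueError("times and events must be one-dimensional")
        if len(self.times) != len(self.events):
            raise ValueError(
                f"times ({len(self.times)}) and events ({len(self.events)}) "
                "must have equal length"
            )
        if len(self.times) == 0:
            raise ValueError("a survival dataset needs at least one subject")
        if np.any(self.times < 0) or np.any(np.isnan(self.times)):
            raise ValueError("all follow-up times must be non-negative")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("events must be coded 0 (censored) / 1 (event)")
        self.events = self.events.astype(np.int8)
        if self.covariates is not None:
            self.covariates = pd.DataFrame(self.covariates)
            if len(self.covariates) != len(self.times):
                raise ValueError(
                    "covariate row count must equal the number of subjects"
                )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def censored_fraction(self) -> float:
        return 1.0 - self.n_events / len(self)

    @property
    def max_time(self) -> float:
        return float(self.times.max())

    def subset(self, index) -> "SurvivalDataset":
        """Rows selected by a boolean mask or integer index array.

        Integer indices may repeat (bootstrap resamples).
        """
        index = np.asarray(index)
        if index.dtype == bool:
            if len(index) != len(self):
                raise ValueError("boolean mask length must match dataset size")
            index = np.flatnonzero(index)
        cov = None
        if self.covariates is not None:
            cov = self.covariates.iloc[index].reset_index(drop=True)
        return SurvivalDataset(self.times[index], self.events[index], cov)

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({TIME_COL: self.times, EVENT_COL: self.events})
        if self.covariates is not None:
            df = pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalDataset":
        for col in (TIME_COL, EVENT_COL):
            if col not in df.columns:
                raise ValueError(f"required column {col!r} is missing")
        cov = df.drop(columns=[TIME_COL, EVENT_COL])
        return cls(
            df[TIME_COL].to_numpy(dtype=float),
            df[EVENT_COL].to_numpy(),
            cov if cov.shape[1] else None,
        )

    @classmethod
    def from_csv(cls, path) -> "SurvivalDataset":
        """Read the standard dialect: comma-separated, header row, ``NA`` or
        an empty cell marks a missing covariate value."""
        return cls.from_frame(pd.read_csv(path, na_values=["NA"]))
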