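"""Model/Results facade tying the pipeline together.

``RiskGroupModel`` holds raw data plus configuration; ``fit`` runs the
preprocessing pipeline and the genetic ensemble training and returns a
``RiskGroupResults`` carrying the trained ensemble, the fitted
preprocessing parameters, per-member training traces and summary tables.

Example
-------
>>> model = RiskGroupModel.from_dataframe(df, categorical=["stage"])
>>> res = model.fit(seed=7)
>>> print(res.summary())
>>> labels = res.predict(new_df)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import EVENT_COL, TIME_COL, SurvivalDataset
from .ensemble import EnsembleConfig, RiskEnsemble, train_ensemble
from .evaluate import GroupSummary, summarize_groups
from .preprocess import Preprocessor

__all__ = ["RiskGroupModel", "RiskGroupResults"]


class RiskGroupModel:
    """Three-way risk grouping of censored survival data.

    An ensemble of single-hidden-layer tanh perceptrons is evolved by a
    steady-state genetic algorithm; half the members chase the group with
    the largest area under its Kaplan-Meier curve (low risk), half the
    smallest (high risk), each under a hard minimum group size, and a
    two-stage majority vote fuses them into high / intermediate / low.

    Parameters
    ----------
    data : SurvivalDataset
        Raw (unnormalized) covariates with follow-up and event columns.
    categorical : sequence of column names to expand into indicators.
    config : EnsembleConfig, optional
        Ensemble layout and GA parameters; defaults to the full-scale
        configuration (34 members, population 200, 1000 generations).
    """

    def __init__(
        self,
        data: SurvivalDataset,
        categorical=(),
        config: EnsembleConfig | None = None,
    ):
        if data.covariates is None:
            raise ValueError("risk grouping requires covariates")
        self.data = data
        self.categorical = list(categorical)
        self.config = config if config is not None else EnsembleConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_col: str = TIME_COL,
        event_col: str = EVENT_COL,
        categorical=(),
        config: EnsembleConfig | None = None,
    ) -> "RiskGroupModel":
        df = df.rename(columns={time_col: TIME_COL, event_col: EVENT_COL})
        return cls(SurvivalDataset.from_frame(df), categorical, config)

    def fit(self, seed: int | None = None, keep_traces: bool = False):
        """Preprocess, train the ensemble, return a results object."""
        pre = Preprocessor(self.categorical)
        X = pre.fit_transform(self.data.covariates)
        train_data = SurvivalDataset(self.data.times, self.data.events, X)
        traces: dict | None = {} if keep_traces else None
        ensemble = train_ensemble(train_data, self.config, seed=seed, traces=traces)
        ensemble.preprocess_params = pre.params
        return RiskGroupResults(self, ensemble, pre, traces)


class RiskGroupResults:
    """Fitted ensemble plus everything needed to predict and report."""

    def __init__(
        self,
        model: RiskGroupModel,
        ensemble: RiskEnsemble,
        preprocessor: Preprocessor,
        traces: dict | None = None,
    ):
        self.model = model
        self.ensemble = ensemble
        self.preprocessor = preprocessor
        self.traces = traces
        self._train_labels = None

    # ------------------------------------------------------------ predict

    def _design(self, covariates: pd.DataFrame) -> np.ndarray:
        return self.preprocessor.transform(covariates).to_numpy(dtype=float)

    def predict(self, data) -> np.ndarray:
        """Risk labels for new subjects.

        ``data`` may be a covariate DataFrame or a SurvivalDataset; the
        stored preprocessing parameters are applied, so columns are
        matched by name.
        """
        cov = data.covariates if isinstance(data, SurvivalDataset) else data
        return self.ensemble.predict(self._design(cov))

    def vote_table(self, data) -> pd.DataFrame:
        """Per-subject vote counts and final label."""
        cov = data.covariates if isinstance(data, SurvivalDataset) else data
        X = self._design(cov)
        vh, vl = self.ensemble.votes(X)
        from .ensemble import combine_votes

        labels = combine_votes(
            vh, vl, self.ensemble.half, self.ensemble.config.vote_rule
        )
        return pd.DataFrame(
            {"votes_high": vh, "votes_low": vl, "label": labels}
        )

    # ------------------------------------------------------------ reports

    @property
    def train_labels(self) -> np.ndarray:
        if self._train_labels is None:
            self._train_labels = self.predict(self.model.data)
        return self._train_labels

    def group_summaries(
        self, data: SurvivalDataset | None = None
    ) -> list[GroupSummary]:
        if data is None:
            data = self.model.data
            labels = self.train_labels
        else:
            labels = self.predict(data)
        return summarize_groups(data, labels, t_N=data.max_time)

    def summary_frame(self, data: SurvivalDataset | None = None) -> pd.DataFrame:
        rows = [
            {
                "group": s.label,
                "size": s.size,
                "median_survival": s.median_survival,
                "end_survival": s.end_survival,
            }
            for s in self.group_summaries(data)
        ]
        return pd.DataFrame(rows).set_index("group")

    def summary(self, data: SurvivalDataset | None = None) -> str:
        """Plain-text report of the fitted grouping."""
        frame = self.summary_frame(data)
        cfg = self.ensemble.config
        low = frame.loc["low", "end_survival"]
        high = frame.loc["high", "end_survival"]
        diff = (
            float(low) - float(high)
            if pd.notna(low) and pd.notna(high)
            else float("nan")
        )
        lines = [
            "Risk-group ensemble (area-under-survival-curve objective)",
            "=" * 58,
            f"members: {cfg.size} ({cfg.half} high + {cfg.half} low), "
            f"hidden nodes: {cfg.n_hidden}",
            f"min group sizes: high={self.ensemble.m_high} "
            f"low={self.ensemble.m_low}; horizon t_N={self.ensemble.t_N:g}",
            f"GA: pop={cfg.ga.population_size} gens={cfg.ga.generations} "
            f"P_C={cfg.ga.crossover_prob} P_M={cfg.ga.mutation_prob} "
            f"M_std={cfg.ga.mutation_std}",
            "-" * 58,
            frame.to_string(float_format=lambda v: f"{v:.4g}"),
            "-" * 58,
            f"end-survival difference (low - high): {diff:.4g}"
            + ("  [curves crossed]" if diff == diff and diff < 0 else ""),
        ]
        return "\n".join(lines)

    def save(self, directory) -> None:
        self.ensemble.save(directory)

    @classmethod
    def load(cls, directory, model: RiskGroupModel | None = None):
        ensemble = RiskEnsemble.load(directory)
        if ensemble.preprocess_params is None:
            raise ValueError("saved ensemble lacks preprocessing parameters")
        pre = Preprocessor.from_params(ensemble.preprocess_params)
        return cls(model, ensemble, pre)
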