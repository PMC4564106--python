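"""Bagged ensembles of high-risk and low-risk classifiers.

Half of the members are trained to find a high-risk group (minimizing the
survival-curve area), the other half a low-risk group (maximizing it),
each on its own bootstrap resample of the training data.  At prediction
time every member casts a membership vote; a risk label is assigned when
its own half reaches a within-majority, with the more-voted side winning
if both do, and "intermediate" on a high/low tie or when neither half
votes the subject in.  Each half has an odd member count so "in vs not"
never ties within a half.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ann import Genome, MLPArchitecture, load_genome, raw_output, save_genome
from .data import SurvivalDataset
from .genetic import GAConfig, train
from .objective import FitnessSpec
from .preprocess import PreprocessParams

__all__ = [
    "RISK_LABELS",
    "EnsembleConfig",
    "RiskEnsemble",
    "bag_sample",
    "train_ensemble",
    "combine_votes",
]

#: the exhaustive three-way label set
RISK_LABELS = ("high", "intermediate", "low")

HIGH, INTERMEDIATE, LOW = RISK_LABELS


@dataclass(frozen=True)
class EnsembleConfig:
    """Ensemble layout and the shared training configuration.

    size : total member count; each half (size/2) must be odd so that a
        half's in-vs-not vote cannot tie.  Default 34 (17 + 17).
    m_high, m_low : minimum group sizes for the two modes.  ``None``
        defaults to a quarter of the training data at fit time (quartile
        risk groups being the common clinical convention).
    vote_rule : "majority" (a label needs its own half's majority) or
        "plurality" (most votes wins whenever either half has a
        majority); the two coincide for odd half sizes.
    """

    size: int = 34
    bagging: bool = True
    n_hidden: int = 4
    ga: GAConfig = field(default_factory=GAConfig)
    m_high: int | None = None
    m_low: int | None = None
    vote_rule: str = "majority"

    def __post_init__(self):
        if self.size < 2 or self.size % 2:
            raise ValueError("ensemble size must be a positive even number")
        if (self.size // 2) % 2 == 0:
            raise ValueError(
                "each ensemble half must have an odd member count "
                f"(got {self.size // 2})"
            )
        if self.vote_rule not in ("majority", "plurality"):
            raise ValueError("vote_rule must be 'majority' or 'plurality'")

    @property
    def half(self) -> int:
        return self.size // 2


def bag_sample(
    data: SurvivalDataset, rng: np.random.Generator
) -> SurvivalDataset:
    """Bootstrap resample: same size, drawn with replacement."""
    idx = rng.integers(0, len(data), size=len(data))
    return data.subset(idx)


def _member_rng(master_seed: int | None, index: int) -> np.random.Generator:
    # member index folded into the seed sequence: reproducible, independent
    entropy = 0 if master_seed is None else master_seed
    return np.random.default_rng(
        np.random.SeedSequence(entropy=entropy, spawn_key=(index,))
    )


def combine_votes(
    votes_high: np.ndarray,
    votes_low: np.ndarray,
    half: int,
    rule: str = "majority",
) -> np.ndarray:
    """Fuse per-subject vote counts into three-way labels.

    With h votes from the high half and l from the low half (of ``half``
    members each): no within-majority on either side -> intermediate;
    h = l -> intermediate; otherwise the majority-holding side with the
    most votes wins.
    """
    h = np.asarray(votes_high, dtype=int)
    l = np.asarray(votes_low, dtype=int)
    maj = half / 2.0
    high_maj = h > maj
    low_maj = l > maj
    labels = np.full(h.shape, INTERMEDIATE, dtype=object)
    if rule == "majority":
        only_high = high_maj & ~low_maj
        only_low = low_maj & ~high_maj
        both = high_maj & low_maj
        labels[only_high] = HIGH
        labels[only_low] = LOW
        labels[both & (h > l)] = HIGH
        labels[both & (l > h)] = LOW
    elif rule == "plurality":
        some_majority = high_maj | low_maj
        labels[some_majority & (h > l)] = HIGH
        labels[some_majority & (l > h)] = LOW
    else:
        raise ValueError(f"unknown vote rule {rule!r}")
    return labels.astype(str)


@dataclass
class RiskEnsemble:
    """Trained membership classifiers plus the metadata to reuse them."""

    high_members: list[Genome]
    low_members: list[Genome]
    arch: MLPArchitecture
    config: EnsembleConfig
    t_N: float
    seed: int | None = None
    preprocess_params: PreprocessParams | None = None
    m_high: int | None = None
    m_low: int | None = None

    def __post_init__(self):
        if len(self.high_members) != len(self.low_members):
            raise ValueError("high and low halves must be equally sized")

    @property
    def half(self) -> int:
        return len(self.high_members)

    def votes(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject counts of in-group votes from each half."""
        X = np.asarray(X, dtype=float)
        votes_high = np.zeros(len(X), dtype=int)
        votes_low = np.zeros(len(X), dtype=int)
        for g in self.high_members:
            votes_high += raw_output(g, self.arch, X) > 0.0
        for g in self.low_members:
            votes_low += raw_output(g, self.arch, X) > 0.0
        return votes_high, votes_low

    def predict(self, X) -> np.ndarray:
        """Three-way risk label per row of the (preprocessed) matrix X."""
        votes_high, votes_low = self.votes(X)
        return combine_votes(
            votes_high, votes_low, self.half, self.config.vote_rule
        )

    # -------------------------------------------------------- persistence

    def save(self, directory) -> None:
        """Directory layout: manifest.json + one plain-text genome file
        per member (high_00.genome.txt, low_00.genome.txt, ...)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "size": self.config.size,
            "bagging": self.config.bagging,
            "n_hidden": self.config.n_hidden,
            "vote_rule": self.config.vote_rule,
            "ga": {
                "population_size": self.config.ga.population_size,
                "crossover_prob": self.config.ga.crossover_prob,
                "mutation_prob": self.config.ga.mutation_prob,
                "mutation_std": self.config.ga.mutation_std,
                "generations": self.config.ga.generations,
                "seed": self.config.ga.seed,
            },
            "n_inputs": self.arch.n_inputs,
            "t_N": self.t_N,
            "seed": self.seed,
            "m_high": self.m_high,
            "m_low": self.m_low,
            "preprocess": None
            if self.preprocess_params is None
            else json.loads(self.preprocess_params.to_json()),
        }
        (directory / "manifest.json").write_text(
            # key order is meaningful: the preprocess means/stds dicts
            # carry the fitted column order
            json.dumps(manifest, indent=1) + "\n"
        )
        for side, members in (
            ("high", self.high_members),
            ("low", self.low_members),
        ):
            for i, g in enumerate(members):
                save_genome(directory / f"{side}_{i:02d}.genome.txt", g, self.arch)

    @classmethod
    def load(cls, directory) -> "RiskEnsemble":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        config = EnsembleConfig(
            size=manifest["size"],
            bagging=manifest["bagging"],
            n_hidden=manifest["n_hidden"],
            ga=GAConfig(**manifest["ga"]),
            m_high=manifest["m_high"],
            m_low=manifest["m_low"],
            vote_rule=manifest["vote_rule"],
        )
        arch = MLPArchitecture(manifest["n_inputs"], manifest["n_hidden"])
        half = manifest["size"] // 2
        high = [
            load_genome(directory / f"high_{i:02d}.genome.txt")[0]
            for i in range(half)
        ]
        low = [
            load_genome(directory / f"low_{i:02d}.genome.txt")[0]
            for i in range(half)
        ]
        params = None
        if manifest["preprocess"] is not None:
            params = PreprocessParams(**manifest["preprocess"])
        return cls(
            high_members=high,
            low_members=low,
            arch=arch,
            config=config,
            t_N=manifest["t_N"],
            seed=manifest["seed"],
            preprocess_params=params,
            m_high=manifest["m_high"],
            m_low=manifest["m_low"],
        )


def train_ensemble(
    data: SurvivalDataset,
    config: EnsembleConfig,
    seed: int | None = None,
    traces: dict | None = None,
) -> RiskEnsemble:
    """Train all members on their own bags of (preprocessed) data.

    The horizon t_N is the maximum follow-up in the full training data,
    shared by every member so that areas and complements stay comparable.
    Member seeds derive from the master ``seed`` and the member index.

    Parameters
    ----------
    traces : dict, optional
        If given, receives a per-member GA trace list under keys like
        ``"high_0"``.
    """
    if data.covariates is None:
        raise ValueError("ensemble training requires covariates")
    n = len(data)
    m_high = config.m_high if config.m_high is not None else max(1, n // 4)
    m_low = config.m_low if config.m_low is not None else max(1, n // 4)
    for m in (m_high, m_low):
        if m >= n:
            raise ValueError(
                f"minimum group size {m} must be below the dataset size {n}"
            )
    arch = MLPArchitecture(data.covariates.shape[1], config.n_hidden)
    t_N = data.max_time
    halves = {"high": [], "low": []}
    jobs = [("high", i) for i in range(config.half)] + [
        ("low", i) for i in range(config.half)
    ]
    for index, (side, i) in enumerate(jobs):
        rng = _member_rng(seed, index)
        sample = bag_sample(data, rng) if config.bagging else data
        spec = FitnessSpec(
            mode="minimize" if side == "high" else "maximize",
            m=m_high if side == "high" else m_low,
            t_N=t_N,
        )
        trace = None
        if traces is not None:
            trace = traces.setdefault(f"{side}_{i}", [])
        halves[side].append(
            train(sample, spec, arch, config.ga, rng=rng, trace=trace)
        )
    return RiskEnsemble(
        high_members=halves["high"],
        low_members=halves["low"],
        arch=arch,
        config=config,
        t_N=t_N,
        seed=seed,
        m_high=m_high,
        m_low=m_low,
    )
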