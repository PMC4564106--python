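"""Single-hidden-layer perceptron membership classifiers.

Each classifier answers one-vs-rest: "is this subject in the (high- or
low-risk) group?".  The network is a fully connected MLP with one hidden
layer of tanh units and a single tanh output; the sign of the output is
the binary answer, with 0 mapping to "not in group".  Weights live in a
flat genome vector — the unit the genetic algorithm evolves — ordered as
[hidden weights row-major incl. bias | output weights incl. bias].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["MLPArchitecture", "Genome", "decode", "classify"]


@dataclass(frozen=True)
class MLPArchitecture:
    n_inputs: int
    n_hidden: int = 4  # four hidden nodes suffice for tabular clinical data

    def __post_init__(self):
        if self.n_inputs < 1 or self.n_hidden < 1:
            raise ValueError("n_inputs and n_hidden must be positive")

    @property
    def genome_length(self) -> int:
        """(n_inputs + 1) * n_hidden hidden weights/biases plus
        (n_hidden + 1) output weights/bias."""
        return (self.n_inputs + 1) * self.n_hidden + (self.n_hidden + 1)

    def split(self, weights: np.ndarray):
        """Unflatten a genome into (W_hidden, b_hidden, w_out, b_out)."""
        nh, ni = self.n_hidden, self.n_inputs
        k = ni * nh
        W = weights[:k].reshape(nh, ni)
        b = weights[k : k + nh]
        v = weights[k + nh : k + nh + nh]
        b_out = weights[-1]
        return W, b, v, b_out


@dataclass(eq=False)
class Genome:
    """Flat weight vector plus a cached fitness value (None = unset)."""

    weights: np.ndarray
    fitness: float | None = field(default=None)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float).ravel()

    def __len__(self) -> int:
        return len(self.weights)

    def copy(self) -> "Genome":
        return Genome(self.weights.copy(), self.fitness)


def _check(genome: Genome, arch: MLPArchitecture) -> None:
    if len(genome) != arch.genome_length:
        raise ValueError(
            f"genome length {len(genome)} does not match architecture "
            f"({arch.n_inputs} inputs, {arch.n_hidden} hidden -> "
            f"{arch.genome_length})"
        )


def raw_output(genome: Genome, arch: MLPArchitecture, X: np.ndarray) -> np.ndarray:
    """Forward pass: tanh(v . tanh(W x + b) + b_out) for each row of X."""
    _check(genome, arch)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != arch.n_inputs:
        raise ValueError(
            f"covariate matrix has {X.shape[1]} columns, expected "
            f"{arch.n_inputs}"
        )
    W, b, v, b_out = arch.split(genome.weights)
    hidden = np.tanh(X @ W.T + b)
    return np.tanh(hidden @ v + b_out)


def decode(genome: Genome, arch: MLPArchitecture):
    """Return ``f(x) -> (raw score, in-group bool)`` for a single row."""
    _check(genome, arch)

    def membership_fn(x):
        out = raw_output(genome, arch, np.asarray(x, dtype=float)[None, :])
        score = float(out[0])
        return score, score > 0.0

    return membership_fn


def classify(genome: Genome, arch: MLPArchitecture, X: np.ndarray) -> np.ndarray:
    """Boolean membership mask over the rows of X (output > 0 = in group)."""
    return raw_output(genome, arch, X) > 0.0


# -------------------------------------------------------------- persistence

def save_genome(path, genome: Genome, arch: MLPArchitecture) -> None:
    """Plain-text format: a header line with the architecture, then one
    weight per line (full double precision)."""
    lines = [f"# n_inputs={arch.n_inputs} n_hidden={arch.n_hidden}"]
    lines += [repr(float(w)) for w in genome.weights]
    Path(path).write_text("\n".join(lines) + "\n")


def load_genome(path) -> tuple[Genome, MLPArchitecture]:
    lines = Path(path).read_text().strip().splitlines()
    header = dict(tok.split("=") for tok in lines[0].lstrip("# ").split())
    arch = MLPArchitecture(int(header["n_inputs"]), int(header["n_hidden"]))
    genome = Genome(np.array([float(v) for v in lines[1:]]))
    _check(genome, arch)
    return genome, arch
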