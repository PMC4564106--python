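"""Synthetic censored survival data with known risk structure.

Event times follow a Weibull proportional-hazards model: stratum s with
hazard multiplier h_s has survival S_s(t) = exp(-h_s (t/scale)^shape)
(shape 1 = exponential).  Censoring is an independent exponential time
whose rate is calibrated — analytically in the exponential case, by
root-finding otherwise — so the expected censored fraction hits the
requested target.  Covariates are the one-hot stratum indicators plus
optional pure-noise Gaussian columns; the latent stratum labels are
returned alongside for recovery tests but are never part of the
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

from .data import SurvivalDataset

__all__ = ["SimSpec", "simulate", "censoring_rate_for_target"]


@dataclass(frozen=True)
class SimSpec:
    """Study design of one simulated cohort.

    strata : list of (proportion, hazard multiplier) pairs; proportions
        must sum to 1 and multipliers must be positive.
    baseline_scale : Weibull scale of the unit-hazard stratum, in the
        time unit of the output.
    censor_rate : target expected censored fraction in [0, 1).
    p_noise : number of non-informative N(0,1) covariate columns.
    """

    n: int = 600
    strata: tuple = ((1.0, 1.0),)
    baseline_scale: float = 1.0
    weibull_shape: float = 1.0
    censor_rate: float = 0.0
    p_noise: int = 0
    seed: int | None = None

    def __post_init__(self):
        props = [p for p, _ in self.strata]
        if abs(sum(props) - 1.0) > 1e-9 or any(p < 0 for p in props):
            raise ValueError("stratum proportions must be >= 0 and sum to 1")
        if any(h <= 0 for _, h in self.strata):
            raise ValueError("hazard multipliers must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.n < 1 or self.baseline_scale <= 0 or self.weibull_shape <= 0:
            raise ValueError("n, baseline_scale, weibull_shape must be positive")


def _stratum_survival(t, h, scale, shape):
    return np.exp(-h * (t / scale) ** shape)


def censoring_rate_for_target(spec: SimSpec) -> float:
    """Exponential censoring rate c with P(C < T) = censor_rate.

    P(C < T) = sum_s p_s * integral_0^inf c e^(-c t) S_s(t) dt, solved in
    closed form for exponential event times and by Brent root-finding on
    log10(c) otherwise.
    """
    target = spec.censor_rate
    if target == 0.0:
        return 0.0
    props = np.array([p for p, _ in spec.strata])
    hazards = np.array([h for _, h in spec.strata])

    if spec.weibull_shape == 1.0:
        rates = hazards / spec.baseline_scale

        def censored_fraction(c):
            return float(np.sum(props * c / (c + rates)))

    else:

        # substitute x = c t so the integrand stays smooth for any rate:
        # P(C < T | stratum) = int_0^inf e^(-x) S(x/c) dx
        def censored_fraction(c):
            total = 0.0
            for p, h in zip(props, hazards):
                if p == 0:
                    continue
                val, _ = integrate.quad(
                    lambda x: np.exp(-x)
                    * _stratum_survival(
                        x / c, h, spec.baseline_scale, spec.weibull_shape
                    ),
                    0,
                    np.inf,
                    limit=200,
                )
                total += p * val
            return total

    lo, hi = -8.0, 8.0
    f = lambda logc: censored_fraction(10.0 ** logc) - target
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"cannot calibrate censoring rate for target {target}"
        )
    logc = optimize.brentq(f, lo, hi, xtol=1e-12)
    return 10.0 ** logc


def simulate(spec: SimSpec) -> tuple[SurvivalDataset, np.ndarray]:
    """Draw one cohort; returns (dataset, latent stratum labels)."""
    rng = np.random.default_rng(spec.seed)
    props = np.array([p for p, _ in spec.strata])
    hazards = np.array([h for _, h in spec.strata])
    strata = rng.choice(len(props), size=spec.n, p=props)
    # T = scale * (E / h)^(1/shape) with E ~ Exp(1) gives the Weibull PH model
    E = rng.exponential(1.0, size=spec.n)
    T = spec.baseline_scale * (E / hazards[strata]) ** (1.0 / spec.weibull_shape)
    c = censoring_rate_for_target(spec)
    if c > 0:
        C = rng.exponential(1.0 / c, size=spec.n)
    else:
        C = np.full(spec.n, np.inf)
    times = np.minimum(T, C)
    events = (T <= C).astype(int)
    import pandas as pd

    cov = {
        f"stratum_{s}": (strata == s).astype(float) for s in range(len(props))
    }
    for j in range(spec.p_noise):
        cov[f"noise_{j}"] = rng.standard_normal(spec.n)
    data = SurvivalDataset(times, events, pd.DataFrame(cov))
    return data, strata
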