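"""Loaders for the five public benchmark cohorts from the R `survival`
package (colon, flchain, nwtco, pbc, lung).

Each loader exports the data frame through ``Rscript`` and applies the
cohort definition used in the benchmark comparisons:

- colon: recurrence records only (etype == 1); status 1 = recurrence.
- flchain: subjects with positive follow-up; death is the event.
- nwtco: all subjects; relapse is the event.
- pbc: the 312 randomized-trial participants; death (status 2) is the
  event, transplant and alive are censored.
- lung: all subjects; status 2 = death.

Requires an R installation with the `survival` package on PATH; no
network access is needed.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .data import SurvivalDataset

__all__ = ["DATASETS", "load_dataset", "dataset_card", "have_r"]

#: per-cohort configuration: R name, time/event construction, features,
#: and which features are expanded as categoricals downstream.
DATASETS = {
    "colon": {
        "features": [
            "rx", "sex", "age", "obstruct", "perfor", "adhere",
            "nodes", "differ", "extent", "surg", "node4",
        ],
        "categorical": ["rx", "differ", "extent"],
    },
    "flchain": {
        "features": [
            "age", "sex", "kappa", "lambda", "flc.grp", "creatinine", "mgus",
        ],
        "categorical": ["sex"],
    },
    "nwtco": {
        "features": ["instit", "histol", "age", "stage"],
        "categorical": ["instit", "histol", "stage"],
    },
    "pbc": {
        "features": [
            "trt", "age", "sex", "ascites", "hepato", "spiders", "edema",
            "bili", "chol", "albumin", "copper", "alk.phos", "ast", "trig",
            "platelet", "protime", "stage",
        ],
        "categorical": ["sex", "stage"],
    },
    "lung": {
        "features": [
            "age", "sex", "ph.ecog", "ph.karno", "pat.karno",
            "meal.cal", "wt.loss",
        ],
        "categorical": [],
    },
}

_R_EXPORT = """
suppressMessages(library(survival))
data(cancer, package="survival")
name <- "{name}"
df <- switch(name,
  colon = {{
    d <- colon[colon$etype == 1, ]
    d$time <- d$time; d$event <- d$status
    d
  }},
  flchain = {{
    d <- flchain[flchain$futime > 0, ]
    d$time <- d$futime; d$event <- d$death
    d
  }},
  nwtco = {{
    d <- nwtco
    d$time <- d$edrel; d$event <- d$rel
    d
  }},
  pbc = {{
    d <- pbc[1:312, ]
    d$time <- d$time; d$event <- as.integer(d$status == 2)
    d
  }},
  lung = {{
    d <- lung
    d$time <- d$time; d$event <- as.integer(d$status == 2)
    d
  }})
write.csv(df, "{out}", row.names = FALSE)
"""


def have_r() -> bool:
    return shutil.which("Rscript") is not None


def _export(name: str) -> pd.DataFrame:
    if name not in DATASETS:
        raise ValueError(f"unknown dataset {name!r}; choose from {sorted(DATASETS)}")
    if not have_r():
        raise RuntimeError("Rscript not found on PATH; cannot export datasets")
    with tempfile.TemporaryDirectory() as tmp:
        out = Path(tmp) / f"{name}.csv"
        code = _R_EXPORT.format(name=name, out=out.as_posix())
        subprocess.run(
            ["Rscript", "-e", code], check=True, capture_output=True, text=True
        )
        return pd.read_csv(out)


def load_dataset(name: str) -> tuple[SurvivalDataset, list[str]]:
    """Cohort as a SurvivalDataset plus its categorical column names."""
    cfg = DATASETS[name]
    df = _export(name)
    cov = df[cfg["features"]].copy()
    data = SurvivalDataset(
        df["time"].to_numpy(dtype=float),
        df["event"].to_numpy(dtype=int),
        cov,
    )
    return data, list(cfg["categorical"])


def dataset_card(name: str) -> dict:
    """Subject and censoring counts of one cohort, computed from the data."""
    data, _ = load_dataset(name)
    n = len(data)
    censored = int(np.sum(data.events == 0))
    return {
        "name": name,
        "n": n,
        "censored": censored,
        "censored_pct": round(100.0 * censored / n),
    }
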