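"""Tabular and configuration I/O shared by the CLI and the examples.

CSV dialect throughout: comma-separated, header row required, UTF-8, '.'
decimal separator.  Age tables have an ``age`` column, an optional
``frequency`` column (default 1, expanded into individual records) and an
optional ``cause`` column (natural | anthropogenic | unknown).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .life_tables import AgeSample
from .siler import SilerParams
from .synthetic import ScenarioSpec

__all__ = ["read_age_table", "write_age_table", "read_priors",
           "read_scenario", "read_schedule_column", "write_run_metadata"]


def read_age_table(path) -> AgeSample:
    df = pd.read_csv(path)
    if "age" not in df.columns:
        raise ValueError(f"{path}: missing required column 'age'")
    ages = pd.to_numeric(df["age"], errors="coerce")
    if ages.isna().any():
        row = int(np.nonzero(ages.isna().to_numpy())[0][0])
        raise ValueError(f"{path}: non-numeric age at data row {row + 1}")
    freq = pd.to_numeric(df["frequency"], errors="raise").astype(int) \
        if "frequency" in df.columns else pd.Series(1, index=df.index)
    if (freq < 0).any():
        raise ValueError(f"{path}: negative frequency")
    expanded_ages = np.repeat(ages.to_numpy(float), freq.to_numpy())
    if expanded_ages.size == 0:
        raise ValueError("no ages")
    cause = None
    if "cause" in df.columns:
        cause = np.repeat(df["cause"].fillna("unknown").to_numpy(object),
                          freq.to_numpy())
    return AgeSample(expanded_ages, cause)


def write_age_table(sample: AgeSample, path) -> None:
    df = pd.DataFrame({"age": sample.ages})
    if sample.cause is not None:
        df["cause"] = sample.cause
    df.to_csv(path, index=False)


def read_priors(path) -> dict[str, tuple[float, float]]:
    """priors.yaml: nine entries, each ``{low: ..., high: ...}``."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    bounds = {}
    for name, entry in raw.items():
        try:
            bounds[name] = (float(entry["low"]), float(entry["high"]))
        except (TypeError, KeyError) as exc:
            raise ValueError(f"{path}: prior {name!r} needs low/high") from exc
    return bounds


def read_scenario(path) -> ScenarioSpec:
    """scenario.yaml mirroring :class:`strandmort.synthetic.ScenarioSpec`."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "siler" in kwargs:
        kwargs["siler"] = SilerParams(**kwargs["siler"])
    if "retention" in kwargs and kwargs["retention"] is not None:
        kwargs["retention"] = {int(k): float(v)
                               for k, v in kwargs["retention"].items()}
    return ScenarioSpec(**kwargs)


def read_schedule_column(path, column: str) -> np.ndarray:
    df = pd.read_csv(path)
    if column not in df.columns:
        raise ValueError(f"{path}: missing required column {column!r}")
    return df[column].to_numpy(float)


def write_run_metadata(path, *, command: str, seed, params: dict) -> None:
    """Sidecar JSON recording everything needed to regenerate an output."""
    from . import __version__
    meta = {"tool": "strandmort", "version": __version__,
            "command": command, "seed": seed, "params": params}
    Path(path).write_text(json.dumps(meta, indent=2, default=str) + "\n",
                          encoding="utf-8")
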