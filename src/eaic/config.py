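"""Experiment configuration and tidy metric output.

Configs are YAML (or JSON, a YAML subset) validated with pydantic; unknown
keys are rejected so typos fail loudly. Metric tables are written as tidy
CSV with a stable column order and 6 significant digits, so repeated runs
with the same config and seed are byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Literal, Optional, Sequence, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .criteria import CRITERION_NAMES, CriterionSpec
from .simulate import SimSetting, StudyMetrics

__all__ = [
    "MethodConfig",
    "SelectConfig",
    "StudyConfig",
    "ExperimentConfig",
    "load_config",
    "write_metrics",
]

METRIC_COLUMNS = [
    "family", "n", "p", "rho", "snr", "method",
    "fwer", "fwer_se", "fdr", "mean_tp", "sensitivity", "reps",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MethodConfig(_Strict):
    """One criterion-based selector: a name plus its constants."""

    criterion: Literal[CRITERION_NAMES + ("oracle",)]
    alpha: Optional[float] = None
    c: Optional[float] = None
    E: Optional[float] = None
    gamma: Optional[float] = None

    def to_spec(self, n: int, p: int) -> CriterionSpec:
        if self.criterion == "oracle":
            raise ValueError("the oracle selector has no CriterionSpec")
        constants = {
            k: v
            for k, v in (("alpha", self.alpha), ("c", self.c),
                         ("E", self.E), ("gamma", self.gamma))
            if v is not None
        }
        return CriterionSpec(self.criterion, n=n, p=p, constants=constants)


class SelectConfig(_Strict):
    """Inputs for a one-dataset selection run."""

    data: str
    outcome: str
    family: Literal["linear", "logistic"]
    method: MethodConfig = Field(default_factory=lambda: MethodConfig(criterion="EAIC", alpha=0.05))
    dfmax: int = 100
    output: Optional[str] = None


class StudyConfig(_Strict):
    """A grid of simulation settings plus the methods to compare."""

    kind: Literal["null", "full"]
    family: List[Literal["linear", "logistic"]] = ["linear"]
    n: List[int] = [100]
    p: List[int] = [100]
    rho: List[float] = [0.0]
    snr: List[float] = []
    alpha: float = 0.05          # null-study scan level
    n_active: int = 10
    reps: int = 1000
    seed: int = 0
    dfmax: int = 100
    methods: List[MethodConfig] = []
    include_oracle: bool = True
    output: str = "metrics.csv"

    @model_validator(mode="after")
    def _check_kind(self) -> "StudyConfig":
        if self.kind == "full" and not self.snr:
            raise ValueError("a full study needs at least one snr value")
        if self.kind == "null" and self.snr:
            raise ValueError("a null study takes no snr values")
        return self

    def settings(self) -> List[SimSetting]:
        out = []
        snrs: Sequence[Optional[float]] = self.snr or [None]
        for fam in self.family:
            for n in self.n:
                for p in self.p:
                    for rho in self.rho:
                        for snr in snrs:
                            out.append(
                                SimSetting(
                                    family=fam, n=n, p=p, rho=rho, snr=snr,
                                    n_active=self.n_active, reps=self.reps,
                                    seed=self.seed,
                                )
                            )
        return out


class ExperimentConfig(_Strict):
    """Top-level config: exactly one command block."""

    select: Optional[SelectConfig] = None
    study: Optional[StudyConfig] = None

    @model_validator(mode="after")
    def _exactly_one(self) -> "ExperimentConfig":
        if (self.select is None) == (self.study is None):
            raise ValueError("config must contain exactly one of 'select' or 'study'")
        return self


def load_config(path: Union[str, Path]) -> ExperimentConfig:
    """Parse and validate a YAML/JSON experiment config."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ValueError(f"config {path} must be a mapping")
    return ExperimentConfig.model_validate(payload)


def metrics_frame(
    rows: Sequence[tuple[SimSetting, StudyMetrics]]
) -> pd.DataFrame:
    """Tidy per-setting per-method metric table."""
    records = []
    for setting, m in rows:
        records.append(
            {
                "family": setting.family, "n": setting.n, "p": setting.p,
                "rho": setting.rho, "snr": setting.snr if setting.snr is not None else "",
                "method": m.method, "fwer": m.fwer, "fwer_se": m.fwer_se,
                "fdr": m.fdr, "mean_tp": m.mean_tp,
                "sensitivity": m.sensitivity, "reps": m.reps,
            }
        )
    return pd.DataFrame(records, columns=METRIC_COLUMNS)


def write_metrics(
    rows: Sequence[tuple[SimSetting, StudyMetrics]], path: Union[str, Path]
) -> pd.DataFrame:
    """Write the tidy metric CSV (stable column order, 6 significant digits)."""
    frame = metrics_frame(rows)
    frame.to_csv(path, index=False, float_format="%.6g")
    return frame
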