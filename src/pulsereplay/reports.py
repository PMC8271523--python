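"""Tabular evaluation reports shared by the verification protocols."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EvalReport:
    """Per-trial NRMSE / R^2 rows plus derived summary statistics.

    ``per_trial`` has columns ``subject`` (set id), ``force`` (regime
    label), ``nrmse`` and ``r_squared``.
    """

    per_trial: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject", "force", "nrmse", "r_squared"}
        if not required.issubset(self.per_trial.columns):
            raise ValueError(f"per_trial must have columns {sorted(required)}")
        if (self.per_trial["nrmse"] < 0).any():
            raise ValueError("nrmse must be non-negative")
        if (self.per_trial["r_squared"] > 1).any():
            raise ValueError("r_squared cannot exceed 1")

    @property
    def n_trials(self) -> int:
        return len(self.per_trial)

    def mean(self, column: str, force: str | None = None) -> float:
        df = self.per_trial
        if force is not None:
            df = df[df["force"] == force]
        return float(df[column].mean())

    def sd(self, column: str, force: str | None = None) -> float:
        df = self.per_trial
        if force is not None:
            df = df[df["force"] == force]
        if len(df) < 2:
            return 0.0
        return float(df[column].std(ddof=1))

    def summary(self) -> pd.DataFrame:
        """Average and S.D. of both metrics, per force level and overall."""
        rows = []
        forces = list(dict.fromkeys(self.per_trial["force"]))
        for force in forces + ["all"]:
            sel = None if force == "all" else force
            rows.append(
                {
                    "force": force,
                    "nrmse_mean": self.mean("nrmse", sel),
                    "nrmse_sd": self.sd("nrmse", sel),
                    "r_squared_mean": self.mean("r_squared", sel),
                    "r_squared_sd": self.sd("r_squared", sel),
                    "n": self.n_trials if sel is None
                         else int((self.per_trial["force"] == force).sum()),
                }
            )
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.per_trial.to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "per_trial": self.per_trial.to_dict(orient="records"),
            "summary": self.summary().to_dict(orient="records"),
        }


@dataclass
class ComparisonReport:
    """Two-sample t-test results comparing two models' fidelity metrics.

    ``table`` has one row per (metric, group) with the t statistic, the
    p-value and a significance flag at the chosen alpha.
    """

    table: pd.DataFrame
    alpha: float = 0.05

    def __post_init__(self) -> None:
        p = self.table["p_value"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")

    def p_value(self, metric: str, group: str = "all") -> float:
        sel = (self.table["metric"] == metric) & (self.table["group"] == group)
        return float(self.table.loc[sel, "p_value"].iloc[0])

    def significant(self, metric: str, group: str = "all") -> bool:
        return self.p_value(metric, group) < self.alpha

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)
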