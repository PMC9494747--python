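"""Linking cumulative modeling importance to ensemble prediction error.

The staged protocol releases variables stage by stage; by stage s the
modelers have accessed input data carrying cumulative importance
ΣP_s = Σ_{k ≤ s} (stage-k importance).  The model error rate

    MER_s = RRMSE_s / ΣP_s

expresses the ensemble's normalized prediction error per unit of modeling
importance accessed up to stage s, and stage-over-stage percent change in
MER (relative to stage 1) measures how much each additional data release
bought in accuracy.  An incremental variant ΔRRMSE/ΔΣP is also provided
(labeled distinctly) for readers of the ratio as a slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .protocol import RRMSESeries

__all__ = [
    "MERTable",
    "ErrorLinkError",
    "cumulative_importance",
    "mer",
    "mer_report",
]


class ErrorLinkError(ValueError):
    """Importance/error series cannot be linked."""


@dataclass(frozen=True)
class MERTable:
    """Per-stage RRMSE, cumulative importance, MER and percent change for
    one ensemble output."""

    output_name: str
    unit: str
    rrmse: np.ndarray
    sigma_p: np.ndarray
    mer: np.ndarray
    pct_change_vs_stage1: np.ndarray
    method: str  # "ratio" | "incremental"

    def __post_init__(self) -> None:
        for name in ("rrmse", "sigma_p", "mer", "pct_change_vs_stage1"):
            a = np.asarray(getattr(self, name), dtype=float).copy()
            a.flags.writeable = False
            object.__setattr__(self, name, a)

    @property
    def n_stages(self) -> int:
        return int(self.rrmse.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "output": self.output_name,
                "stage": np.arange(1, self.n_stages + 1),
                "rrmse": self.rrmse,
                "unit": self.unit,
                "sigma_p": self.sigma_p,
                "mer": self.mer,
                "pct_change_vs_stage1": self.pct_change_vs_stage1,
                "method": self.method,
            }
        )


def cumulative_importance(stage_totals: Sequence[float] | pd.Series) -> np.ndarray:
    """Running sum of per-stage importances ΣP_s.

    Stage totals must each be positive: a stage contributing zero importance
    would make the error-per-importance ratio at that stage undefined.
    """
    t = np.asarray(
        stage_totals.to_numpy() if isinstance(stage_totals, pd.Series) else stage_totals,
        dtype=float,
    )
    if t.ndim != 1 or t.size == 0:
        raise ErrorLinkError("stage totals must be a non-empty 1-d sequence")
    if np.any(t <= 0):
        s = int(np.argmax(t <= 0))
        raise ErrorLinkError(f"stage {s + 1} has non-positive total importance {t[s]}")
    return np.cumsum(t)


def mer(
    series: RRMSESeries,
    sigma_p: Sequence[float] | np.ndarray,
    incremental: bool = False,
) -> MERTable:
    """Model error rate per stage: RRMSE_s / ΣP_s (or ΔRRMSE/ΔΣP).

    ``sigma_p`` is the *cumulative* importance per stage (strictly positive,
    non-decreasing).  Percent change is reported against stage 1.  The RRMSE
    unit is carried through to the MER values unchanged.
    """
    sp = np.asarray(sigma_p, dtype=float)
    if sp.size != series.n_stages:
        raise ErrorLinkError(
            f"{series.output_name!r}: {series.n_stages} RRMSE stages but "
            f"{sp.size} importance stages"
        )
    if np.any(sp <= 0):
        raise ErrorLinkError("cumulative importance must be strictly positive at every stage")
    if np.any(np.diff(sp) < -1e-9):
        raise ErrorLinkError("cumulative importance must be non-decreasing")
    if incremental:
        d_r = np.diff(series.values, prepend=0.0)
        d_p = np.diff(sp, prepend=0.0)
        if np.any(d_p <= 0):
            s = int(np.argmax(d_p <= 0))
            raise ErrorLinkError(f"stage {s + 1}: zero incremental importance")
        values = d_r / d_p
        method = "incremental"
    else:
        values = series.values / sp
        method = "ratio"
    base = values[0]
    if base != 0:
        pct = 100.0 * (values - base) / base
    else:
        pct = np.where(values == 0, 0.0, np.inf)
    return MERTable(
        output_name=series.output_name,
        unit=series.unit,
        rrmse=series.values,
        sigma_p=sp,
        mer=values,
        pct_change_vs_stage1=pct,
        method=method,
    )


def mer_report(tables: Sequence[MERTable]) -> pd.DataFrame:
    """Long-format summary (output, stage, rrmse, ΣP, MER, pct change),
    ordered by output then stage — the table/bar-chart export."""
    if not tables:
        raise ErrorLinkError("no MER tables to report")
    frames = [t.to_frame() for t in tables]
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["output", "stage"], kind="stable").reset_index(drop=True)
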