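"""HG/IntG production-ratio trajectory across ontogenesis stages.

The ratio of the housekeeping group's per-age mean production to the
integrative group's is the study's scale-free indicator of resource
redistribution between cellular infrastructure and organismal function.
It is summarised per ontogenesis stage (mouse): Stage I 1-6 months
(development), Stage II 6-15 (reproductive), Stage III 15-21
(post-reproductive), Stage IV 21-27 (old age); shared boundary ages belong
to both adjacent stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregate import AgeSeries
from .trends import TrendFit, fit_line

__all__ = [
    "StageDefinition",
    "DEFAULT_STAGES",
    "RatioSeries",
    "StageSummary",
    "ratio_series",
    "interval_ratio_slope",
    "stage_summary",
]


@dataclass(frozen=True)
class StageDefinition:
    """A closed ontogenesis stage [start, end] in months."""

    name: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"stage {self.name!r}: start must precede end")


DEFAULT_STAGES: tuple[StageDefinition, ...] = (
    StageDefinition("Stage I", 1, 6),
    StageDefinition("Stage II", 6, 15),
    StageDefinition("Stage III", 15, 21),
    StageDefinition("Stage IV", 21, 27),
)


@dataclass(frozen=True)
class RatioSeries:
    """Per-age HG/IntG ratio of aggregated mean production (dimensionless)."""

    ages: np.ndarray
    ratio: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", np.asarray(self.ages, float))
        object.__setattr__(self, "ratio", np.asarray(self.ratio, float))
        if len(self.ages) != len(self.ratio):
            raise ValueError("ages and ratio must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "ratio": self.ratio})

    def export(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class StageSummary:
    """Per-stage mean ratio and within-stage slope."""

    stage: str
    n: int
    mean_ratio: float
    slope: float
    low_n: bool = False


def ratio_series(hg: AgeSeries, intg: AgeSeries) -> RatioSeries:
    """Elementwise HG-mean / IntG-mean on a shared age grid (raw ratio,
    not normalized to its own average)."""
    if not np.array_equal(hg.ages, intg.ages):
        raise ValueError("HG and IntG series are on different age grids")
    zero = np.flatnonzero(intg.mean <= 0)
    if zero.size:
        raise ValueError(
            f"IntG mean is not positive at age {intg.ages[zero[0]]}"
        )
    return RatioSeries(ages=hg.ages, ratio=hg.mean / intg.mean)


def interval_ratio_slope(ratio: RatioSeries, start: float, end: float) -> TrendFit:
    """OLS trend of the ratio within the closed age interval [start, end]."""
    sel = (ratio.ages >= start) & (ratio.ages <= end)
    if sel.sum() < 3:
        raise ValueError(
            f"interval [{start}, {end}] contains {int(sel.sum())} grid age(s); need >= 3"
        )
    return fit_line(ratio.ages[sel], ratio.ratio[sel])


def stage_summary(
    ratio: RatioSeries, stages: Sequence[StageDefinition] = DEFAULT_STAGES
) -> list[StageSummary]:
    """Mean ratio and slope per ontogenesis stage (closed intervals).

    Stages holding only 2 grid ages report the two-point slope with a
    ``low_n`` flag instead of an OLS fit.
    """
    out = []
    for st in stages:
        sel = (ratio.ages >= st.start) & (ratio.ages <= st.end)
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"stage {st.name!r} lies outside the age grid")
        x, y = ratio.ages[sel], ratio.ratio[sel]
        if n >= 3:
            slope = fit_line(x, y).slope
            low_n = False
        elif n == 2:
            slope = float((y[1] - y[0]) / (x[1] - x[0]))
            low_n = True
        else:
            raise ValueError(f"stage {st.name!r} holds a single grid age")
        out.append(StageSummary(st.name, n, float(y.mean()), slope, low_n))
    return out


def export_stage_report(summaries: Sequence[StageSummary], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {
                    "stage": s.stage,
                    "n": s.n,
                    "mean_ratio": s.mean_ratio,
                    "slope": s.slope,
                    "low_n": s.low_n,
                }
                for s in summaries
            ],
            indent=2,
        )
    )
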