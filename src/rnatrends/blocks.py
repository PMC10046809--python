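"""Trajectory analysis of named gene blocks.

A block (the DNA-repair set, the HOXA developmental Block I, the
cardiovascular/metabolic Block II) is treated as its own gene group: its
per-age mean series comes from the same aggregation as the HG/IntG groups,
and its early/late behaviour from the same segmented fits, so there is no
independent fitting code path to drift out of sync.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .aggregate import AgeSeries, ExpressionDataset, group_age_series
from .catalog import GeneBlock
from .trends import TrendFit, segment_fits

__all__ = ["BlockDeclineReport", "block_trajectory", "block_decline_report"]


@dataclass(frozen=True)
class BlockDeclineReport:
    """Start level and per-month segment slopes of a block trajectory.

    ``start_level`` is the early-segment fitted value at the first grid age;
    the observed first-age mean is reported alongside so either reading of a
    "level - decline per month" summary can be checked.
    """

    block: str
    n_genes: int
    start_level: float
    observed_start: float
    early_slope: float
    late_slope: float
    breakpoint: float
    early_fit: TrendFit
    late_fit: TrendFit

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "block": self.block,
                    "n_genes": self.n_genes,
                    "start_level": self.start_level,
                    "observed_start": self.observed_start,
                    "early_slope": self.early_slope,
                    "late_slope": self.late_slope,
                    "breakpoint": self.breakpoint,
                },
                indent=2,
            )
        )


def block_trajectory(dataset: ExpressionDataset, block: GeneBlock, **kw) -> AgeSeries:
    """Per-age mean production series of a gene block."""
    return group_age_series(dataset, block, **kw)


def block_decline_report(
    series: AgeSeries, breakpoint: float = 9.0, *, block: str = "", n_genes: int = 0
) -> BlockDeclineReport:
    """Summarise a block series as (start level, early slope, late slope)."""
    early, late = segment_fits(series, breakpoint)
    return BlockDeclineReport(
        block=block,
        n_genes=n_genes or int(series.n_genes[0]),
        start_level=float(early.predict(series.ages[0])),
        observed_start=float(series.mean[0]),
        early_slope=early.slope,
        late_slope=late.slope,
        breakpoint=float(breakpoint),
        early_fit=early,
        late_fit=late,
    )
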