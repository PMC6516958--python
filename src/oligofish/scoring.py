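"""Proportion tallies for all-or-nothing staining-style scoring."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd


@dataclass(frozen=True)
class ScoreTally:
    label: str
    successes: int
    total: int

    def __post_init__(self) -> None:
        if self.total == 0:
            raise ValueError(f"tally {self.label!r} has total 0")
        if not (0 <= self.successes <= self.total):
            raise ValueError(
                f"tally {self.label!r}: successes {self.successes} not in [0, {self.total}]"
            )

    @property
    def percent(self) -> int:
        """Percentage rounded half-up to the nearest integer."""
        return int(math.floor(100.0 * self.successes / self.total + 0.5))


def scoring_summary(tallies: Sequence[ScoreTally], totals_row: bool = False
                    ) -> pd.DataFrame:
    """One row per tally (label, successes, total, percent), optional totals."""
    if not tallies:
        raise ValueError("need at least one tally")
    rows = [{"label": t.label, "successes": t.successes,
             "total": t.total, "percent": t.percent} for t in tallies]
    if totals_row:
        pooled = ScoreTally("total",
                            sum(t.successes for t in tallies),
                            sum(t.total for t in tallies))
        rows.append({"label": pooled.label, "successes": pooled.successes,
                     "total": pooled.total, "percent": pooled.percent})
    return pd.DataFrame(rows)
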