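"""Even-density probe selection and per-chromosome summary statistics.

Candidates are decimated to every Nth probe, restarting the count inside
each 500 kb segment so that every addressable sub-pool stays populated.
The summary table mirrors the library design report: one row per
chromosome plus a totals row whose count columns are sums and whose
per-kb / distance columns are unweighted means across chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_model import KB500
from .probe_mining import CandidateProbe


@dataclass
class SelectionParams:
    """Decimation step or target density (mutually exclusive)."""

    step: int | None = 5
    target_density: float | None = None  # probes per kb
    gap_threshold: int = 5_000
    segment_size: int = KB500

    def __post_init__(self) -> None:
        if (self.step is None) == (self.target_density is None):
            raise ValueError("specify exactly one of step / target_density")
        if self.step is not None and self.step < 1:
            raise ValueError("step must be >= 1")
        if self.gap_threshold <= 0:
            raise ValueError("gap_threshold must be positive")


def _starts(probes: Sequence) -> list[int]:
    return [p.start if hasattr(p, "start") else int(p) for p in probes]


def subsample(candidates: Sequence[CandidateProbe], params: SelectionParams
              ) -> list[CandidateProbe]:
    """Keep every Nth candidate, restarting within each 500 kb segment.

    When ``target_density`` is given, N = round(candidate density /
    target density) computed over the candidate span, floored at 1.
    """
    if not candidates:
        return []
    starts = _starts(candidates)
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("candidates must be sorted by start")
    step = params.step
    if step is None:
        span_kb = (starts[-1] - starts[0]) / 1000.0
        if span_kb <= 0:
            step = 1
        else:
            density = len(candidates) / span_kb
            step = max(1, round(density / params.target_density))
    selected: list[CandidateProbe] = []
    seg_key = None
    within = 0
    for cand, start in zip(candidates, starts):
        key = (getattr(cand, "chrom", None), start // params.segment_size)
        if key != seg_key:
            seg_key = key
            within = 0
        if within % step == 0:
            selected.append(cand)
        within += 1
    return selected


@dataclass(frozen=True)
class SpacingStats:
    n_selected: int
    first_coord: int
    last_coord: int
    mean_adjacent: float
    sd_adjacent: float
    endpoint_mean: float
    density_per_kb: float
    gaps_over_threshold: int
    max_gap: int


def endpoint_mean_spacing(first_coord: float, last_coord: float, n: int) -> float:
    """Mean spacing as span divided by the number of probes (by n, not n-1)."""
    if n < 1:
        raise ValueError("need at least one probe")
    return (last_coord - first_coord) / n


def density_per_kb(count: int, first_coord: float, last_coord: float) -> float:
    """Probes per kb of spanned sequence."""
    span_kb = (last_coord - first_coord) / 1000.0
    if span_kb <= 0:
        raise ValueError("nonpositive span")
    return count / span_kb


def spacing_stats(selected: Sequence, gap_threshold: int = 5_000) -> SpacingStats:
    """Spacing/gap statistics over a sorted probe selection (>= 2 probes)."""
    starts = _starts(selected)
    if len(starts) < 2:
        raise ValueError(
            f"spacing statistics need at least 2 probes, got {len(starts)}"
        )
    arr = np.asarray(starts, dtype=np.int64)
    if np.any(np.diff(arr) < 0):
        raise ValueError("selection must be sorted by start")
    gaps = np.diff(arr)
    return SpacingStats(
        n_selected=len(arr),
        first_coord=int(arr[0]),
        last_coord=int(arr[-1]),
        mean_adjacent=float(gaps.mean()),
        sd_adjacent=float(gaps.std(ddof=1)) if len(gaps) > 1 else 0.0,
        endpoint_mean=endpoint_mean_spacing(arr[0], arr[-1], len(arr)),
        density_per_kb=density_per_kb(len(arr), arr[0], arr[-1]),
        gaps_over_threshold=int(np.count_nonzero(gaps > gap_threshold)),
        max_gap=int(gaps.max()),
    )


SUMMARY_COLUMNS = [
    "chrom", "first_coord", "last_coord",
    "n_candidates", "candidates_per_kb",
    "n_chosen", "chosen_per_kb",
    "mean_distance", "sd_distance",
]

_SUM_COLS = ["n_candidates", "n_chosen"]
_MEAN_COLS = ["candidates_per_kb", "chosen_per_kb", "mean_distance", "sd_distance"]


def chromosome_row(chrom: str, first_coord: int, last_coord: int,
                   n_candidates: int, n_chosen: int,
                   mean_distance: float, sd_distance: float) -> dict:
    """One summary row; per-kb densities are derived from the inputs."""
    return {
        "chrom": chrom,
        "first_coord": first_coord,
        "last_coord": last_coord,
        "n_candidates": n_candidates,
        "candidates_per_kb": density_per_kb(n_candidates, first_coord, last_coord),
        "n_chosen": n_chosen,
        "chosen_per_kb": density_per_kb(n_chosen, first_coord, last_coord),
        "mean_distance": mean_distance,
        "sd_distance": sd_distance,
    }


def summarize_library(rows: Iterable[dict]) -> pd.DataFrame:
    """Assemble the per-chromosome summary plus a totals row.

    Totals semantics: SUM for the two count columns, UNWEIGHTED MEAN
    across chromosomes for the per-kb and distance columns.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("need at least one chromosome row")
    for r in rows:
        missing = set(SUMMARY_COLUMNS) - set(r)
        if missing:
            raise ValueError(f"row for {r.get('chrom')!r} missing fields: {sorted(missing)}")
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    totals = {"chrom": "total", "first_coord": np.nan, "last_coord": np.nan}
    for col in _SUM_COLS:
        totals[col] = df[col].sum()
    for col in _MEAN_COLS:
        totals[col] = df[col].mean()
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


def summary_from_probes(candidates_by_chrom: dict[str, Sequence],
                        selected_by_chrom: dict[str, Sequence],
                        gap_threshold: int = 5_000) -> pd.DataFrame:
    """Build the summary table directly from candidate/selected probe sets."""
    rows = []
    for chrom in candidates_by_chrom:
        sel = selected_by_chrom[chrom]
        stats = spacing_stats(sel, gap_threshold)
        rows.append(chromosome_row(
            chrom, stats.first_coord, stats.last_coord,
            len(candidates_by_chrom[chrom]), stats.n_selected,
            stats.mean_adjacent, stats.sd_adjacent,
        ))
    return summarize_library(rows)


def summary_to_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def summary_from_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def selected_to_bed(selected: Sequence[CandidateProbe], path) -> None:
    with open(path, "w") as fh:
        for c in selected:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t"
                     f"{c.chrom}:{c.start}-{c.end}\t{c.tm:.2f}\t{c.strand}\n")
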