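"""Germination statistics computed from a single time course.

Three lot-level summaries are standard in seed-vigor work:

* final germination percentage — germinated seeds / sown seeds x 100 at the
  end of the assay;
* germination rate (GR, per day) — the sum over days of (seeds newly
  germinated that day) / (day number), which weights early germination
  heavily;
* germination index (GI) — the same daily-count-over-day-number sum, cited
  under a different name in the agronomy literature.

The two printed formulas are algebraically identical, so both are served by
one kernel over daily bins.  Because assays often count sub-daily early on
(every 8 h for the first days here), :func:`germination_rate` optionally uses
fractional day indices (time_h / 24) instead of integer daily bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

import pandas as pd

from .errors import UndefinedStatisticError
from .germdata import GerminationTimeCourse, group_by_lot

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class DailyGermination:
    """Seeds newly germinated during one day of the assay."""

    day: int
    count: float

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError(f"day must be >= 1 (got {self.day})")
        if self.count < 0:
            raise ValueError(f"count must be >= 0 (got {self.count})")


def final_germination_percentage(tc: GerminationTimeCourse) -> float:
    """Final cumulative germination as a percentage of seeds sown."""
    if tc.n_sown == 0:
        raise UndefinedStatisticError("n_sown is zero; percentage undefined")
    return 100.0 * tc.final_count / tc.n_sown


def daily_bins(tc: GerminationTimeCourse) -> list[DailyGermination]:
    """Aggregate a (possibly sub-daily) time course into daily new-germination counts.

    Day ``d`` covers the half-open interval ``(24(d-1), 24d]`` hours, so an
    observation at exactly 24 h belongs to day 1.  Days with no new
    germination are omitted.  The counts sum to the final cumulative count.
    """
    days = np.ceil(tc.times_h / HOURS_PER_DAY).astype(int)
    new = np.diff(tc.cum_germinated, prepend=0.0)
    out: dict[int, float] = {}
    for d, c in zip(days, new):
        if c != 0:
            out[int(d)] = out.get(int(d), 0.0) + float(c)
    return [DailyGermination(day=d, count=c) for d, c in sorted(out.items())]


def _rate_kernel(bins: Sequence[DailyGermination]) -> float:
    return float(sum(b.count / b.day for b in bins if b.count > 0))


def germination_rate(
    bins_or_tc: Sequence[DailyGermination] | GerminationTimeCourse,
    day_resolution: Literal["integer", "fractional"] = "integer",
) -> float:
    """Germination rate GR = sum over days of (new germinations / day number), per day.

    With ``day_resolution="integer"`` (default) the sum runs over integer
    daily bins.  With ``"fractional"`` each observation interval contributes
    at its exact time in days (time_h / 24), honoring sub-daily counting; this
    variant requires a :class:`GerminationTimeCourse` input.
    """
    if day_resolution == "fractional":
        if not isinstance(bins_or_tc, GerminationTimeCourse):
            raise TypeError("fractional day resolution requires a time course")
        tc = bins_or_tc
        new = np.diff(tc.cum_germinated, prepend=0.0)
        frac_days = tc.times_h / HOURS_PER_DAY
        mask = new > 0
        return float(np.sum(new[mask] / frac_days[mask]))
    bins = (
        daily_bins(bins_or_tc)
        if isinstance(bins_or_tc, GerminationTimeCourse)
        else bins_or_tc
    )
    return _rate_kernel(bins)


def lot_summary(courses) -> pd.DataFrame:
    """Per-lot germination summary averaged over all water potentials and replicates.

    Returns a lot-indexed frame with columns ``germination_pct``,
    ``germination_rate`` and ``germination_index`` — the unweighted mean of
    each statistic over every (water potential, replicate) time course of
    the lot, the convention used when screening lot summaries against
    fitted parameters.
    """
    rows = []
    for lot_id, lot_courses in group_by_lot(courses).items():
        sgp = [final_germination_percentage(tc) for tc in lot_courses]
        gr = [germination_rate(tc) for tc in lot_courses]
        gi = [germination_index(tc) for tc in lot_courses]
        rows.append(
            {
                "lot_id": lot_id,
                "germination_pct": float(np.mean(sgp)),
                "germination_rate": float(np.mean(gr)),
                "germination_index": float(np.mean(gi)),
            }
        )
    return pd.DataFrame(rows).set_index("lot_id")


def germination_index(
    bins_or_tc: Sequence[DailyGermination] | GerminationTimeCourse,
) -> float:
    """Germination index GI = sum over days of (new germinations / day number)."""
    bins = (
        daily_bins(bins_or_tc)
        if isinstance(bins_or_tc, GerminationTimeCourse)
        else bins_or_tc
    )
    return _rate_kernel(bins)
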