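"""Sleep, bout, wake-activity and death scoring from binned beam-break counts.

The fly-sleep field's operational definitions, applied at bin resolution:

* **sleep** — at least 5 consecutive minutes without a beam break.  With the
  DAM's 5-minute acquisition bins this is exactly one zero-count bin; the
  threshold is configurable in whole bins for other bin widths.
* **death** — a terminal run of zero-count bins longer than 24 hours; the
  death time is placed at the *start* of that run (the fly's last movement),
  so the silent tail is excluded from lifespan.
* **analysis horizon** — behavioural and survival analysis is restricted to
  the first 30 days of the recording; flies alive at the horizon are
  right-censored there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .dam_io import ActivityRecording, assign_zt

log = logging.getLogger("flychrono")

__all__ = [
    "SleepSeries",
    "FlyVitals",
    "find_bouts",
    "score_sleep",
    "call_death",
    "wake_activity",
    "daily_summaries",
    "score_cohort",
]

MINUTES_PER_DAY = 1440.0


@dataclass
class SleepSeries:
    """Per-bin sleep state for one fly; False in masked and post-death bins."""

    fly_id: str
    asleep: np.ndarray
    threshold_bins: int = 1

    def __post_init__(self) -> None:
        self.asleep = np.asarray(self.asleep, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.asleep.size


@dataclass
class FlyVitals:
    """Death/censoring call for one fly.

    ``death_bin`` is the first bin of the terminal silent run when dead,
    None when censored.  ``lifespan_days`` is the time from recording start
    to death (dead) or to the censoring time (alive), capped at the horizon.
    """

    fly_id: str
    genotype: str
    dead: bool
    death_bin: int | None
    lifespan_days: float
    censor_day: float
    dead_on_arrival: bool = False


def find_bouts(asleep: Sequence[bool] | np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive True values as (start_bin, length_bins)."""
    a = np.asarray(asleep, dtype=bool)
    if a.size == 0:
        return []
    padded = np.concatenate(([False], a, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def score_sleep(
    rec: ActivityRecording,
    sleep_threshold_min: int = 5,
    death_bin: int | None = None,
) -> SleepSeries:
    """Score per-bin sleep: zero-count runs of at least the threshold length.

    Masked bins and bins at/after ``death_bin`` are never asleep and break
    runs.  The threshold must be a whole number of bins.
    """
    bin_min = rec.bin_minutes
    if sleep_threshold_min % bin_min != 0 or sleep_threshold_min <= 0:
        raise ValueError(
            f"sleep threshold {sleep_threshold_min} min is not a positive whole "
            f"number of {bin_min}-min bins"
        )
    k = sleep_threshold_min // bin_min
    inactive = (rec.counts == 0) & ~rec.masked
    if death_bin is not None:
        inactive[death_bin:] = False
    if k == 1:
        asleep = inactive
    else:
        asleep = np.zeros_like(inactive)
        for start, length in find_bouts(inactive):
            if length >= k:
                asleep[start : start + length] = True
    return SleepSeries(fly_id=rec.fly_id, asleep=asleep, threshold_bins=k)


def call_death(
    rec: ActivityRecording,
    threshold_hours: float = 24.0,
    horizon_days: float = 30.0,
) -> FlyVitals:
    """Call death from the terminal silent run; censor survivors at the horizon.

    A fly is dead iff the recording ends in a run of zero-count bins strictly
    longer than ``threshold_hours``; the death bin is the first bin of that
    run.  Deaths falling beyond the horizon are reported as censored at the
    horizon.  The threshold must be a whole number of bins.
    """
    bin_min = rec.bin_minutes
    threshold_min = threshold_hours * 60.0
    if threshold_min % bin_min != 0:
        raise ValueError(
            f"death threshold {threshold_hours} h is not a whole number of "
            f"{bin_min}-min bins"
        )
    threshold_bins = int(threshold_min // bin_min)

    zero = rec.counts == 0
    horizon = min(horizon_days, rec.duration_days)
    if zero[-1]:
        nonzero_idx = np.flatnonzero(~zero)
        run_start = int(nonzero_idx[-1]) + 1 if nonzero_idx.size else 0
        run_len = rec.n_bins - run_start
        if run_len > threshold_bins:
            lifespan = run_start * bin_min / MINUTES_PER_DAY
            if lifespan <= horizon_days:
                doa = lifespan < 1.0
                if doa:
                    log.info("%s: dead on arrival (death at bin %d)", rec.fly_id, run_start)
                # floor at one bin so lifespans stay positive
                lifespan = max(lifespan, bin_min / MINUTES_PER_DAY)
                return FlyVitals(rec.fly_id, rec.genotype, True, run_start,
                                 lifespan, horizon_days, dead_on_arrival=doa)
    return FlyVitals(rec.fly_id, rec.genotype, False, None, horizon, horizon_days)


def _window_mask(rec: ActivityRecording, window: str) -> np.ndarray:
    zt = assign_zt(rec)
    light = zt < rec.schedule.photoperiod_minutes
    if window == "day":
        return light
    if window == "night":
        return ~light
    if window == "24h":
        return np.ones(rec.n_bins, dtype=bool)
    raise ValueError(f"window must be 'day', 'night' or '24h', got {window!r}")


def wake_activity(
    rec: ActivityRecording,
    sleep: SleepSeries,
    window: Literal["day", "night", "24h"] = "24h",
    vitals: FlyVitals | None = None,
) -> float:
    """Beam breaks per waking minute over the chosen window.

    Restricted to living, unmasked bins; NaN when the fly is never awake in
    the window (missing, not zero).
    """
    sel = _window_mask(rec, window) & ~rec.masked
    if vitals is not None and vitals.dead and vitals.death_bin is not None:
        sel[vitals.death_bin:] = False
    awake = sel & ~sleep.asleep
    n_awake = int(awake.sum())
    if n_awake == 0:
        return float("nan")
    return float(rec.counts[awake].sum()) / (rec.bin_minutes * n_awake)


def daily_summaries(
    rec: ActivityRecording,
    sleep: SleepSeries,
    vitals: FlyVitals,
    horizon_days: float = 30.0,
    young_max_day: int = 13,
) -> pd.DataFrame:
    """Per-day behavioural summary for one fly over its living days.

    Days run ZT0→ZT0 (a leading partial day is discarded); the day of death
    and everything after is excluded, as are days past the horizon.  Sleep
    bouts are counted separately for the light and dark phase, a bout
    spanning the ZT12 boundary contributing one bout to each.  ``age_class``
    is "young" through ``young_max_day`` and "old" after.
    """
    sched = rec.schedule
    zt = assign_zt(rec)
    dpb = sched.bins_per_period
    day_bins = sched.photoperiod_minutes // sched.bin_minutes
    zt0_idx = np.flatnonzero(zt == 0)
    if zt0_idx.size == 0:
        return pd.DataFrame()
    start0 = int(zt0_idx[0])
    if start0 > 0:
        log.debug("%s: discarding %d leading bins before first ZT0", rec.fly_id, start0)
    n_days = (rec.n_bins - start0) // dpb
    bin_min = sched.bin_minutes

    rows = []
    for d in range(n_days):
        lo = start0 + d * dpb
        hi = lo + dpb
        day_index = d + 1
        if day_index > horizon_days:
            break
        if vitals.dead and vitals.death_bin is not None and vitals.death_bin < hi:
            break  # partial death day and beyond excluded
        counts = rec.counts[lo:hi]
        masked = rec.masked[lo:hi]
        asleep = sleep.asleep[lo:hi]
        um = ~masked
        light = np.zeros(dpb, dtype=bool)
        light[:day_bins] = True  # day window starts at ZT0 by construction

        sleep_day = int((asleep & light).sum())
        sleep_night = int((asleep & ~light).sum())
        awake_day = um & light & ~asleep
        awake_night = um & ~light & ~asleep
        wa_day = (
            float(counts[awake_day].sum()) / (bin_min * awake_day.sum())
            if awake_day.any() else float("nan")
        )
        wa_night = (
            float(counts[awake_night].sum()) / (bin_min * awake_night.sum())
            if awake_night.any() else float("nan")
        )
        rows.append(
            {
                "fly_id": rec.fly_id,
                "genotype": rec.genotype,
                "day_index": day_index,
                "total_counts": int(counts[um].sum()),
                "sleep_minutes": (sleep_day + sleep_night) * bin_min,
                "sleep_minutes_day": sleep_day * bin_min,
                "sleep_minutes_night": sleep_night * bin_min,
                "wake_activity_day": wa_day,
                "wake_activity_night": wa_night,
                "n_sleep_bouts_day": len(find_bouts(asleep & light)),
                "n_sleep_bouts_night": len(find_bouts(asleep & ~light)),
                "n_unmasked_bins": int(um.sum()),
                "age_class": "young" if day_index <= young_max_day else "old",
            }
        )
    return pd.DataFrame(rows)


def score_cohort(
    recordings: Sequence[ActivityRecording],
    sleep_threshold_min: int = 5,
    death_threshold_h: float = 24.0,
    horizon_days: float = 30.0,
    young_max_day: int = 13,
) -> tuple[pd.DataFrame, pd.DataFrame, list[SleepSeries], list[FlyVitals]]:
    """Score a whole cohort: vitals table, daily-summary table, and per-fly series.

    Dead-on-arrival flies (death within the first day) are kept in the vitals
    table for survival analysis but contribute no daily summaries.
    """
    vitals_rows, daily_frames, sleeps, vitals_list = [], [], [], []
    for rec in recordings:
        vit = call_death(rec, death_threshold_h, horizon_days)
        slp = score_sleep(rec, sleep_threshold_min, death_bin=vit.death_bin)
        vitals_list.append(vit)
        sleeps.append(slp)
        vitals_rows.append(
            {
                "fly_id": vit.fly_id,
                "genotype": vit.genotype,
                "dead": vit.dead,
                "lifespan_days": vit.lifespan_days,
                "dead_on_arrival": vit.dead_on_arrival,
            }
        )
        if not vit.dead_on_arrival:
            daily_frames.append(
                daily_summaries(rec, slp, vit, horizon_days, young_max_day)
            )
    n_doa = sum(r["dead_on_arrival"] for r in vitals_rows)
    if n_doa:
        log.info("excluded %d dead-on-arrival flies from behavioural summaries", n_doa)
    vitals_df = pd.DataFrame(vitals_rows)
    daily_df = (
        pd.concat([f for f in daily_frames if not f.empty], ignore_index=True)
        if any(not f.empty for f in daily_frames)
        else pd.DataFrame()
    )
    return vitals_df, daily_df, sleeps, vitals_list
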