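"""Population activity/sleep profiles, anticipation indices, actograms.

Profiles follow the convention of averaging within fly across days first and
then across flies, so that long-lived flies do not dominate the group mean
(the fly is the biological replicate); pooling all fly-days is available as a
switch.  The anticipation index quantifies the build-up of activity before a
light transition as the fraction of the 6-h pre-transition activity that
falls in the final 3 h — 0.5 for flat activity, 1.0 when all of it is packed
into the last 3 h.
"""

from __future__ import annotations

import logging
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .dam_io import ActivityRecording, assign_zt
from .sleep_activity import FlyVitals, SleepSeries
from .survival_stats import two_sample_t

log = logging.getLogger("flychrono")

__all__ = [
    "fly_day_matrix",
    "population_profile",
    "anticipation_index",
    "actogram_matrix",
    "age_strata_compare",
]


def fly_day_matrix(
    rec: ActivityRecording,
    sleep: SleepSeries,
    vitals: FlyVitals | None,
    metric: Literal["activity", "sleep"] = "activity",
    horizon_days: float = 30.0,
) -> np.ndarray:
    """(living days × bins-per-day) matrix of one fly's metric, NaN where masked.

    Days run ZT0→ZT0; a leading partial day, the death day and days past the
    horizon are dropped.  Returns an empty array when no complete living day
    exists.
    """
    sched = rec.schedule
    dpb = sched.bins_per_period
    zt = assign_zt(rec)
    zt0_idx = np.flatnonzero(zt == 0)
    if zt0_idx.size == 0:
        return np.empty((0, dpb))
    start0 = int(zt0_idx[0])
    n_days = (rec.n_bins - start0) // dpb
    n_days = min(n_days, int(horizon_days))
    if vitals is not None and vitals.dead and vitals.death_bin is not None:
        n_days = min(n_days, (vitals.death_bin - start0) // dpb)
    if n_days <= 0:
        return np.empty((0, dpb))
    sl = slice(start0, start0 + n_days * dpb)
    if metric == "activity":
        values = rec.counts[sl].astype(float)
    elif metric == "sleep":
        values = sleep.asleep[sl].astype(float)
    else:
        raise ValueError(f"metric must be 'activity' or 'sleep', got {metric!r}")
    values = values.copy()
    values[rec.masked[sl]] = np.nan
    return values.reshape(n_days, dpb)


def population_profile(
    flies: Sequence[tuple[ActivityRecording, SleepSeries, FlyVitals | None]],
    metric: Literal["activity", "sleep"] = "activity",
    mode: Literal["fly_mean", "pooled", "percent_asleep"] = "fly_mean",
    horizon_days: float = 30.0,
) -> pd.DataFrame:
    """Across-fly mean ± sem of activity or sleep per ZT bin, by genotype.

    * ``fly_mean`` (default): average each fly across its living days, then
      mean/sem across flies (n = flies, sample sd with n−1).
    * ``pooled``: mean/sem across all fly-days.
    * ``percent_asleep`` (sleep only): per day, the fraction of living flies
      asleep at each bin; mean/sem across days.
    """
    if not flies:
        raise ValueError("no flies to profile")
    dpb = flies[0][0].schedule.bins_per_period
    bin_min = flies[0][0].schedule.bin_minutes

    by_genotype: dict[str, list[np.ndarray]] = {}
    for rec, slp, vit in flies:
        mat = fly_day_matrix(rec, slp, vit, metric=metric, horizon_days=horizon_days)
        if mat.shape[0] == 0:
            continue
        by_genotype.setdefault(rec.genotype, []).append(mat)

    frames = []
    for genotype in sorted(by_genotype):
        mats = by_genotype[genotype]
        if not mats:
            raise ValueError(f"genotype group {genotype!r} has no living fly-days")
        if mode == "fly_mean":
            per_fly = np.vstack([np.nanmean(m, axis=0) for m in mats])  # flies × dpb
            mean = np.nanmean(per_fly, axis=0)
            n = np.sum(~np.isnan(per_fly), axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                sem = np.nanstd(per_fly, axis=0, ddof=1) / np.sqrt(n)
            sem = np.where(n > 1, sem, np.nan)
        elif mode == "pooled":
            stacked = np.vstack(mats)
            mean = np.nanmean(stacked, axis=0)
            n = np.sum(~np.isnan(stacked), axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                sem = np.nanstd(stacked, axis=0, ddof=1) / np.sqrt(n)
            sem = np.where(n > 1, sem, np.nan)
        elif mode == "percent_asleep":
            if metric != "sleep":
                raise ValueError("percent_asleep mode applies to the sleep metric")
            max_days = max(m.shape[0] for m in mats)
            cube = np.full((len(mats), max_days, dpb), np.nan)
            for i, m in enumerate(mats):
                cube[i, : m.shape[0], :] = m
            with np.errstate(invalid="ignore"):
                frac = np.nanmean(cube, axis=0)  # days × dpb, fraction asleep
            valid_days = ~np.isnan(frac).all(axis=1)
            frac = frac[valid_days]
            mean = np.nanmean(frac, axis=0)
            n = np.sum(~np.isnan(frac), axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                sem = np.nanstd(frac, axis=0, ddof=1) / np.sqrt(n)
            sem = np.where(n > 1, sem, np.nan)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        frames.append(
            pd.DataFrame(
                {
                    "genotype": genotype,
                    "zt_bin": np.arange(dpb),
                    "zt_minutes": np.arange(dpb) * bin_min,
                    "mean": mean,
                    "sem": sem,
                    "n": n,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def anticipation_index(
    rec: ActivityRecording,
    transition: Literal["ZT0", "ZT12"] = "ZT12",
    pre_minutes: int = 360,
    near_minutes: int = 180,
    vitals: FlyVitals | None = None,
) -> float:
    """Pre-transition activity ratio, averaged across cycles.

    For each complete pre-transition window: (activity in the last
    ``near_minutes``) / (activity in the full ``pre_minutes``).  Cycles with a
    zero denominator or any masked/post-death bin in the window are skipped;
    NaN when no cycle qualifies.  Scale-invariant by construction.
    """
    sched = rec.schedule
    if near_minutes >= pre_minutes:
        raise ValueError("near_minutes must be smaller than pre_minutes")
    if pre_minutes % sched.bin_minutes or near_minutes % sched.bin_minutes:
        raise ValueError("windows must be whole numbers of bins")
    pre_bins = pre_minutes // sched.bin_minutes
    near_bins = near_minutes // sched.bin_minutes
    target_zt = 0 if transition == "ZT0" else sched.photoperiod_minutes
    if transition not in ("ZT0", "ZT12"):
        raise ValueError(f"transition must be 'ZT0' or 'ZT12', got {transition!r}")

    zt = assign_zt(rec)
    end = rec.n_bins
    if vitals is not None and vitals.dead and vitals.death_bin is not None:
        end = vitals.death_bin
    ratios = []
    for t in np.flatnonzero(zt == target_zt):
        t = int(t)
        if t < pre_bins or t > end:
            continue
        window = slice(t - pre_bins, t)
        if rec.masked[window].any():
            continue
        total = float(rec.counts[window].sum())
        if total <= 0:
            continue
        near = float(rec.counts[t - near_bins : t].sum())
        ratios.append(near / total)
    return float(np.mean(ratios)) if ratios else float("nan")


def actogram_matrix(rec: ActivityRecording) -> np.ndarray:
    """Double-plotted actogram: row d = counts of day d followed by day d+1.

    With fewer than two complete days a single-plot (one row per day) matrix
    is returned with a warning.  The left half of row d equals the right half
    of row d−1 by construction.
    """
    dpb = rec.schedule.bins_per_period
    zt = assign_zt(rec)
    zt0_idx = np.flatnonzero(zt == 0)
    start0 = int(zt0_idx[0]) if zt0_idx.size else 0
    n_days = (rec.n_bins - start0) // dpb
    if n_days < 1:
        raise ValueError("recording shorter than one complete day")
    days = rec.counts[start0 : start0 + n_days * dpb].reshape(n_days, dpb)
    if n_days < 2:
        log.warning("%s: <2 complete days; single-plot actogram", rec.fly_id)
        return days.astype(float)
    return np.hstack([days[:-1], days[1:]]).astype(float)


def age_strata_compare(
    daily: pd.DataFrame,
    metric: str,
    group_a: str,
    group_b: str,
    welch: bool = False,
) -> pd.DataFrame:
    """Young/old comparison of a daily-summary metric between two genotypes.

    Each fly contributes one value per stratum (its mean over the stratum's
    days); groups are then compared with an unpaired two-tailed t-test.
    Strata with fewer than two flies in a group report missing statistics.
    """
    if metric not in daily.columns:
        raise ValueError(f"metric {metric!r} not in daily summary columns")
    rows = []
    for stratum in ("young", "old"):
        sub = daily[daily["age_class"] == stratum]
        per_fly = sub.groupby(["genotype", "fly_id"])[metric].mean().reset_index()
        va = per_fly.loc[per_fly["genotype"] == group_a, metric].to_numpy()
        vb = per_fly.loc[per_fly["genotype"] == group_b, metric].to_numpy()
        res = two_sample_t(va, vb, welch=welch)
        rows.append(
            {
                "stratum": stratum,
                "metric": metric,
                "group_a": group_a,
                "group_b": group_b,
                "mean_a": res.mean_a,
                "sem_a": res.sem_a,
                "n_a": res.n_a,
                "mean_b": res.mean_b,
                "sem_b": res.sem_b,
                "n_b": res.n_b,
                "t": res.statistic,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)
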