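"""Reading and normalising TriKinetics Drosophila Activity Monitor (DAM) files.

A DAM monitor records one fly per channel as infrared beam-break counts
accumulated over fixed-width time bins (5 minutes in the standard acquisition
setup).  The common "Monitor" file dialect is tab-separated with one row per
timestamp: a row index, date, time, a status code, further metadata columns,
and then one count column per channel (32 channels per monitor).

This module parses that dialect into :class:`ActivityRecording` objects, maps
bins onto Zeitgeber time (ZT; minutes since lights-on), and merges a cohort
manifest that assigns a genotype to each (monitor, channel).
"""

from __future__ import annotations

import datetime as dt
import itertools
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("flychrono")

__all__ = [
    "LightSchedule",
    "ActivityRecording",
    "DamParseError",
    "DamIntegrityError",
    "EmptyInputError",
    "parse_monitor_file",
    "rebin",
    "assign_zt",
    "light_mask",
    "read_manifest",
    "apply_manifest",
    "to_tidy",
    "recordings_from_tidy",
]

DAM_DATE_FORMAT = "%d %b %y"
DAM_N_META_COLUMNS = 10  # index, date, time, status + 6 acquisition fields
DAM_N_CHANNELS = 32
DAM_OK_STATUS = 1


class DamParseError(ValueError):
    """A monitor file row could not be parsed (names the offending line)."""


class DamIntegrityError(ValueError):
    """Rows parsed but violate file-level invariants (e.g. time order)."""


class EmptyInputError(ValueError):
    """The monitor file contains no data rows."""


def _coerce_time(value: dt.time | str) -> dt.time:
    if isinstance(value, dt.time):
        return value
    if isinstance(value, str):
        parts = value.split(":")
        if len(parts) not in (2, 3):
            raise ValueError(f"cannot parse clock time {value!r}; expected HH:MM[:SS]")
        return dt.time(*(int(p) for p in parts))
    raise TypeError(f"lights_on_clock must be a datetime.time or 'HH:MM' string, got {type(value)}")


@dataclass(frozen=True)
class LightSchedule:
    """Light:dark schedule of the incubator.

    ZT0 is defined as lights-on; under the default 12:12 cycle lights are on
    for ``photoperiod_minutes`` = 720 of each 1440-minute period.  The
    lights-on clock time has no universal default and must be supplied — ZT
    anchoring is meaningless if guessed.
    """

    lights_on_clock: dt.time
    period_minutes: int = 1440
    photoperiod_minutes: int = 720
    bin_minutes: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "lights_on_clock", _coerce_time(self.lights_on_clock))
        if self.photoperiod_minutes >= self.period_minutes:
            raise ValueError("photoperiod_minutes must be < period_minutes")
        if self.period_minutes % self.bin_minutes != 0:
            raise ValueError("period_minutes must be divisible by bin_minutes")

    @property
    def lights_on_minutes(self) -> int:
        t = self.lights_on_clock
        return t.hour * 60 + t.minute

    @property
    def bins_per_period(self) -> int:
        return self.period_minutes // self.bin_minutes


@dataclass
class ActivityRecording:
    """Beam-break counts for one fly in contiguous, uniform time bins.

    ``masked`` marks bins whose monitor status code was not OK; they are
    retained (bins stay contiguous) but excluded from all scoring
    denominators downstream.
    """

    fly_id: str
    genotype: str
    start_time: dt.datetime
    counts: np.ndarray
    schedule: LightSchedule
    masked: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if (self.counts < 0).any():
            raise ValueError("beam-break counts must be non-negative")
        if self.masked is None:
            self.masked = np.zeros(self.counts.size, dtype=bool)
        else:
            self.masked = np.asarray(self.masked, dtype=bool)
            if self.masked.shape != self.counts.shape:
                raise ValueError("masked must have the same length as counts")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def bin_minutes(self) -> int:
        return self.schedule.bin_minutes

    @property
    def duration_days(self) -> float:
        return self.n_bins * self.bin_minutes / 1440.0


def parse_monitor_file(
    path: str | os.PathLike,
    schedule: LightSchedule,
    *,
    n_channels: int = DAM_N_CHANNELS,
    n_meta_columns: int = DAM_N_META_COLUMNS,
    ok_status: int = DAM_OK_STATUS,
    genotype: str = "unknown",
) -> list[ActivityRecording]:
    """Parse one TriKinetics monitor file into per-channel recordings.

    The expected dialect is tab-separated with ``n_meta_columns`` metadata
    columns (row index, date, time, status code, then acquisition fields)
    followed by ``n_channels`` per-channel count columns.  Column count is
    validated per row; rows with a status code other than ``ok_status`` are
    kept but flagged ``masked``.

    Raises
    ------
    EmptyInputError
        if the file has no data rows.
    DamParseError
        naming the line number, for a row with the wrong column count or
        unparseable fields.
    DamIntegrityError
        if timestamps are not strictly increasing or bin spacing does not
        match ``schedule.bin_minutes``.
    """
    expected_cols = n_meta_columns + n_channels
    timestamps: list[dt.datetime] = []
    statuses: list[int] = []
    count_rows: list[list[int]] = []

    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != expected_cols:
                raise DamParseError(
                    f"{path}: line {lineno}: expected {expected_cols} tab-separated "
                    f"columns, found {len(fields)}"
                )
            try:
                date = dt.datetime.strptime(fields[1].strip(), DAM_DATE_FORMAT).date()
                time = dt.time.fromisoformat(fields[2].strip())
                status = int(fields[3])
                counts = [int(v) for v in fields[n_meta_columns:]]
            except (ValueError, TypeError) as exc:
                raise DamParseError(f"{path}: line {lineno}: {exc}") from exc
            if any(c < 0 for c in counts):
                raise DamParseError(f"{path}: line {lineno}: negative count")
            timestamps.append(dt.datetime.combine(date, time))
            statuses.append(status)
            count_rows.append(counts)

    if not timestamps:
        raise EmptyInputError(f"{path}: no data rows")

    ts = np.array(timestamps)
    if len(ts) > 1:
        deltas = np.diff(ts).astype("timedelta64[s]").astype(np.int64)
        if (deltas <= 0).any():
            bad = int(np.argmax(deltas <= 0)) + 2
            raise DamIntegrityError(f"{path}: non-monotone timestamps at data row {bad}")
        step = deltas[0]
        if (deltas != step).any():
            raise DamIntegrityError(f"{path}: non-uniform bin spacing")
        if step != schedule.bin_minutes * 60:
            raise DamIntegrityError(
                f"{path}: bin spacing {step / 60:g} min does not match schedule "
                f"bin_minutes={schedule.bin_minutes}"
            )

    matrix = np.array(count_rows, dtype=np.int64)  # rows × channels
    masked = np.array(statuses) != ok_status
    if masked.any():
        log.warning("%s: %d/%d rows with non-OK status retained but masked",
                    path, int(masked.sum()), len(statuses))

    monitor = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    recordings = []
    for ch in range(n_channels):
        recordings.append(
            ActivityRecording(
                fly_id=f"{monitor}#{ch + 1:02d}",
                genotype=genotype,
                start_time=timestamps[0],
                counts=matrix[:, ch],
                schedule=schedule,
                masked=masked.copy(),
            )
        )
    return recordings


def rebin(rec: ActivityRecording, target_bin_minutes: int) -> ActivityRecording:
    """Aggregate counts to a coarser bin width (sum within each target bin).

    The target width must be a positive multiple of the recording's bin
    width.  A trailing partial bin is discarded with a logged warning; a
    target bin is masked if any constituent source bin was masked.
    """
    src = rec.bin_minutes
    if target_bin_minutes <= 0 or target_bin_minutes % src != 0:
        raise ValueError(
            f"target_bin_minutes={target_bin_minutes} is not a positive multiple "
            f"of the recording bin width {src}"
        )
    factor = target_bin_minutes // src
    if factor == 1:
        return replace(rec, counts=rec.counts.copy(), masked=rec.masked.copy())
    n_full = rec.n_bins // factor
    dropped = rec.n_bins - n_full * factor
    if dropped:
        log.warning("rebin %s: discarding trailing partial bin (%d source bins)",
                    rec.fly_id, dropped)
    counts = rec.counts[: n_full * factor].reshape(n_full, factor).sum(axis=1)
    masked = rec.masked[: n_full * factor].reshape(n_full, factor).any(axis=1)
    schedule = replace(rec.schedule, bin_minutes=target_bin_minutes)
    return replace(rec, counts=counts, masked=masked, schedule=schedule)


def assign_zt(rec: ActivityRecording) -> np.ndarray:
    """Zeitgeber time (minutes in [0, period)) of each bin's start.

    ZT = (clock time of bin start − lights-on clock time) mod period.
    """
    sched = rec.schedule
    start_min = rec.start_time.hour * 60 + rec.start_time.minute
    offset = (start_min - sched.lights_on_minutes) % sched.period_minutes
    idx = np.arange(rec.n_bins, dtype=np.int64)
    return (offset + idx * sched.bin_minutes) % sched.period_minutes


def light_mask(rec: ActivityRecording) -> np.ndarray:
    """Boolean per bin: True where lights are on (ZT < photoperiod)."""
    return assign_zt(rec) < rec.schedule.photoperiod_minutes


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a cohort manifest CSV with columns monitor_file, channel, genotype."""
    df = pd.read_csv(path)
    required = {"monitor_file", "channel", "genotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    if df["genotype"].isna().any() or (df["genotype"].astype(str).str.strip() == "").any():
        raise ValueError("manifest contains empty genotype labels")
    if not df["channel"].between(1, DAM_N_CHANNELS).all():
        raise ValueError("manifest channel out of range 1..32")
    if df.duplicated(subset=["monitor_file", "channel"]).any():
        raise ValueError("manifest contains duplicate (monitor_file, channel) rows")
    return df


def apply_manifest(
    recordings: Sequence[ActivityRecording],
    manifest: pd.DataFrame,
    monitor_file: str,
) -> list[ActivityRecording]:
    """Assign genotypes from a manifest; keep only channels listed for this monitor."""
    name = os.path.basename(monitor_file)
    rows = manifest[manifest["monitor_file"].map(os.path.basename) == name]
    by_channel = {int(r.channel): str(r.genotype) for r in rows.itertuples()}
    out = []
    for rec in recordings:
        channel = int(rec.fly_id.rsplit("#", 1)[-1])
        if channel in by_channel:
            out.append(replace(rec, genotype=by_channel[channel]))
    return out


def to_tidy(recordings: Iterable[ActivityRecording]) -> pd.DataFrame:
    """Long-format table: one row per (fly, bin) with ZT and light annotation."""
    frames = []
    for rec in recordings:
        zt = assign_zt(rec)
        frames.append(
            pd.DataFrame(
                {
                    "fly_id": rec.fly_id,
                    "genotype": rec.genotype,
                    "bin_index": np.arange(rec.n_bins),
                    "zt_minutes": zt,
                    "light": zt < rec.schedule.photoperiod_minutes,
                    "counts": rec.counts,
                    "masked": rec.masked,
                }
            )
        )
    if not frames:
        raise EmptyInputError("no recordings to tabulate")
    return pd.concat(frames, ignore_index=True)


def recordings_from_tidy(
    df: pd.DataFrame,
    schedule: LightSchedule,
    start_time: dt.datetime | None = None,
) -> list[ActivityRecording]:
    """Rebuild recordings from the tidy long format written by :func:`to_tidy`.

    The tidy table carries ZT but not the wall-clock start; unless given, the
    start time is reconstructed from the first bin's ZT relative to lights-on
    on an arbitrary date (ZT, not the calendar, drives all downstream
    analysis).
    """
    out = []
    for (fly_id, genotype), grp in df.groupby(["fly_id", "genotype"], sort=True):
        grp = grp.sort_values("bin_index")
        if start_time is None:
            zt0 = int(grp["zt_minutes"].iloc[0])
            clock = (schedule.lights_on_minutes + zt0) % 1440
            start = dt.datetime(2000, 1, 1, clock // 60, clock % 60)
        else:
            start = start_time
        out.append(
            ActivityRecording(
                fly_id=str(fly_id),
                genotype=str(genotype),
                start_time=start,
                counts=grp["counts"].to_numpy(),
                schedule=schedule,
                masked=grp["masked"].to_numpy(dtype=bool),
            )
        )
    return out
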