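"""Synthetic cohort generator with ground-truth labels.

Emulates the statistical structure of a Drosophila activity-monitor
experiment so that every pipeline stage can be exercised, and its parameter
recovery checked, at desk scale:

* **activity** — awake bins emit Poisson counts with a bimodal circadian
  mean template (peaks near ZT0 and ZT12, a midday siesta trough, a low
  night baseline) attenuated by a multiplicative per-day age decline;
* **sleep** — a two-state (wake/sleep) Markov chain with ZT-dependent
  transition probabilities; sleep gates the Poisson process, so asleep bins
  emit zero counts (optional low-rate false beam breaks stress-test the
  scorer, default off);
* **death** — a per-fly lifespan drawn from a Weibull (aging-type, default)
  or exponential distribution; all bins after the death bin are exactly
  zero;
* **fixtures** — negative-binomial DE tables with programmed up/down gene
  sets, and overdispersed (lognormal) per-unit count tables for
  haemocyte/glia comparisons.

All generators are bit-reproducible given (config, seed); each fly draws
from its own stream derived from (cohort seed, fly index), so enlarging a
cohort never reshuffles existing flies.
"""

from __future__ import annotations

import datetime as dt
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dam_io import (
    DAM_DATE_FORMAT,
    DAM_N_CHANNELS,
    DAM_N_META_COLUMNS,
    DAM_OK_STATUS,
    ActivityRecording,
    LightSchedule,
)

__all__ = [
    "GenotypeSimConfig",
    "GroundTruth",
    "default_activity_template",
    "default_sleep_chain",
    "simulate_fly",
    "simulate_cohort",
    "write_dam_file",
    "simulate_counts_and_de",
    "make_overlap_tables",
    "simulate_counts",
]

DEFAULT_SCHEDULE = LightSchedule(lights_on_clock=dt.time(8, 0))
DEFAULT_START = dt.datetime(2024, 1, 1, 8, 0)  # recordings start at lights-on


def default_activity_template(
    peak: float = 12.0,
    day_baseline: float = 4.0,
    night_fraction: float = 0.3,
    sigma_minutes: float = 60.0,
    schedule: LightSchedule = DEFAULT_SCHEDULE,
) -> np.ndarray:
    """Bimodal circadian template of mean awake counts per bin.

    Gaussian bumps (sd ``sigma_minutes``) centred on the two light
    transitions (ZT0 and lights-off) over a baseline that drops to
    ``night_fraction`` of its daytime value in the dark phase; the dip
    between the bumps is the siesta.
    """
    nb = schedule.bins_per_period
    zt = (np.arange(nb) + 0.5) * schedule.bin_minutes  # bin centres, minutes
    period = float(schedule.period_minutes)

    def bump(centre: float) -> np.ndarray:
        d = np.abs(zt - centre)
        d = np.minimum(d, period - d)  # circular distance
        return np.exp(-0.5 * (d / sigma_minutes) ** 2)

    base = np.where(
        zt < schedule.photoperiod_minutes, day_baseline, day_baseline * night_fraction
    )
    return base + peak * (bump(0.0) + bump(float(schedule.photoperiod_minutes)))


def default_sleep_chain(
    schedule: LightSchedule = DEFAULT_SCHEDULE,
    siesta_window: tuple[int, int] = (300, 600),
) -> tuple[np.ndarray, np.ndarray]:
    """ZT-dependent (wake→sleep, sleep→wake) transition probabilities per bin.

    Sleep pressure is high at night and during the midday siesta window, low
    around the morning and evening activity peaks.
    """
    nb = schedule.bins_per_period
    zt = np.arange(nb) * schedule.bin_minutes
    night = zt >= schedule.photoperiod_minutes
    siesta = (zt >= siesta_window[0]) & (zt < siesta_window[1])
    p_ws = np.where(night, 0.35, np.where(siesta, 0.25, 0.08))
    p_sw = np.where(night, 0.12, np.where(siesta, 0.20, 0.45))
    return p_ws.astype(float), p_sw.astype(float)


@dataclass
class GenotypeSimConfig:
    """Simulation parameters for one genotype's cohort.

    ``lifespan_shape`` is a Weibull shape parameter (k > 1 gives the
    sigmoidal, aging-type survival seen in real fly cohorts; the scale is
    set from ``lifespan_median_days``); None selects an exponential
    distribution with that median.  Transition probabilities may be scalars
    (homogeneous chain, closed-form stationary sleep probability) or per-bin
    vectors.
    """

    label: str
    n_flies: int
    activity_template: np.ndarray | None = None
    p_wake_to_sleep: float | np.ndarray | None = None
    p_sleep_to_wake: float | np.ndarray | None = None
    lifespan_median_days: float = 24.5
    lifespan_shape: float | None = 4.0
    age_decline: float = 0.995
    noise_rate: float = 0.0
    schedule: LightSchedule = field(default_factory=lambda: DEFAULT_SCHEDULE)

    def __post_init__(self) -> None:
        if self.n_flies <= 0:
            raise ValueError("n_flies must be positive")
        if self.lifespan_median_days <= 0:
            raise ValueError("lifespan_median_days must be positive")
        if not 0 < self.age_decline <= 1:
            raise ValueError("age_decline must be in (0, 1]")
        if self.activity_template is None:
            self.activity_template = default_activity_template(schedule=self.schedule)
        self.activity_template = np.asarray(self.activity_template, dtype=float)
        if self.activity_template.size != self.schedule.bins_per_period:
            raise ValueError("activity_template length must equal bins per period")
        if (self.activity_template < 0).any():
            raise ValueError("activity_template must be non-negative")
        if self.p_wake_to_sleep is None or self.p_sleep_to_wake is None:
            p_ws, p_sw = default_sleep_chain(self.schedule)
            if self.p_wake_to_sleep is None:
                self.p_wake_to_sleep = p_ws
            if self.p_sleep_to_wake is None:
                self.p_sleep_to_wake = p_sw
        for name in ("p_wake_to_sleep", "p_sleep_to_wake"):
            p = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if p.size == 1:
                p = np.full(self.schedule.bins_per_period, float(p[0]))
            if p.size != self.schedule.bins_per_period:
                raise ValueError(f"{name} must be scalar or one value per ZT bin")
            if ((p < 0) | (p > 1)).any():
                raise ValueError(f"{name} probabilities must lie in [0, 1]")
            setattr(self, name, p)

    @property
    def stationary_sleep(self) -> float | None:
        """Closed-form stationary sleep probability for a homogeneous chain."""
        p_ws, p_sw = self.p_wake_to_sleep, self.p_sleep_to_wake
        if np.ptp(p_ws) > 0 or np.ptp(p_sw) > 0:
            return None
        ws, sw = float(p_ws[0]), float(p_sw[0])
        if ws + sw == 0:
            return 0.0
        return ws / (ws + sw)


@dataclass
class GroundTruth:
    """Programmed labels for a simulated cohort.

    ``death_bin`` is -1 for flies surviving the recording; ``sleep_state``
    holds the chain state for pre-death bins and False afterwards.
    """

    label: str
    fly_ids: list[str]
    death_bin: np.ndarray
    lifespan_days: np.ndarray  # continuous programmed lifespan (may exceed record)
    sleep_state: np.ndarray    # bool, (n_flies, n_bins)
    stationary_sleep: float | None

    def sleep_fraction(self, fly: int) -> float:
        """Programmed sleep fraction over the fly's living bins."""
        end = self.death_bin[fly]
        end = self.sleep_state.shape[1] if end < 0 else int(end)
        if end == 0:
            return float("nan")
        return float(self.sleep_state[fly, :end].mean())


def _draw_lifespan(cfg: GenotypeSimConfig, rng: np.random.Generator) -> float:
    if cfg.lifespan_shape is None:
        return float(rng.exponential(cfg.lifespan_median_days / math.log(2)))
    k = float(cfg.lifespan_shape)
    scale = cfg.lifespan_median_days / math.log(2) ** (1.0 / k)
    return float(scale * rng.weibull(k))


def _simulate_flies(
    cfg: GenotypeSimConfig,
    rngs: Sequence[np.random.Generator],
    n_days: int,
    start_time: dt.datetime,
    fly_ids: Sequence[str],
) -> tuple[list[ActivityRecording], GroundTruth]:
    """Simulate several flies at once (chain stepped jointly across flies).

    Each fly consumes draws only from its own generator, in a fixed order
    (lifespan, initial state, chain uniforms, activity, noise), so results
    are independent of how many flies share the call.
    """
    sched = cfg.schedule
    nb_day = sched.bins_per_period
    n_bins = n_days * nb_day
    n = len(rngs)
    zt_idx = np.arange(n_bins) % nb_day
    day_idx = np.arange(n_bins) // nb_day
    lam = cfg.activity_template[zt_idx] * cfg.age_decline**day_idx

    p_ws = cfg.p_wake_to_sleep[zt_idx]
    p_sw = cfg.p_sleep_to_wake[zt_idx]
    denom = p_ws[0] + p_sw[0]
    pi0 = p_ws[0] / denom if denom > 0 else 0.0

    lifespans = np.empty(n)
    u_init = np.empty(n)
    U = np.empty((n, n_bins))
    pois = np.empty((n, n_bins), dtype=np.int64)
    noise = np.zeros((n, n_bins), dtype=np.int64)
    for f, rng in enumerate(rngs):
        lifespans[f] = _draw_lifespan(cfg, rng)
        u_init[f] = rng.random()
        U[f] = rng.random(n_bins)
        pois[f] = rng.poisson(lam)
        if cfg.noise_rate > 0:
            noise[f] = rng.poisson(cfg.noise_rate, n_bins)

    death_bin = np.floor(lifespans * nb_day).astype(np.int64)
    death_bin[death_bin >= n_bins] = -1

    asleep = np.empty((n, n_bins), dtype=bool)
    asleep[:, 0] = u_init < pi0
    for t in range(1, n_bins):
        prev = asleep[:, t - 1]
        asleep[:, t] = np.where(prev, U[:, t] >= p_sw[t], U[:, t] < p_ws[t])

    alive = (death_bin[:, None] < 0) | (np.arange(n_bins)[None, :] < death_bin[:, None])
    counts = np.where(alive & ~asleep, pois, 0)
    if cfg.noise_rate > 0:
        counts = np.where(alive & asleep, noise, counts)
    assert not np.logical_and(~alive, counts > 0).any(), "counts after death"

    sleep_state = asleep & alive
    recordings = [
        ActivityRecording(
            fly_id=fly_ids[f],
            genotype=cfg.label,
            start_time=start_time,
            counts=counts[f],
            schedule=sched,
        )
        for f in range(n)
    ]
    truth = GroundTruth(
        label=cfg.label,
        fly_ids=list(fly_ids),
        death_bin=death_bin,
        lifespan_days=lifespans,
        sleep_state=sleep_state,
        stationary_sleep=cfg.stationary_sleep,
    )
    return recordings, truth


def simulate_fly(
    cfg: GenotypeSimConfig,
    fly_seed: int,
    n_days: int = 31,
    start_time: dt.datetime = DEFAULT_START,
    fly_id: str | None = None,
) -> tuple[ActivityRecording, GroundTruth]:
    """Simulate a single fly from its own seed."""
    rng = np.random.default_rng(np.random.SeedSequence(fly_seed))
    fid = fly_id or f"{cfg.label}#{fly_seed}"
    recs, truth = _simulate_flies(cfg, [rng], n_days, start_time, [fid])
    return recs[0], truth


def simulate_cohort(
    cfg: GenotypeSimConfig,
    seed: int,
    n_days: int = 31,
    start_time: dt.datetime = DEFAULT_START,
) -> tuple[list[ActivityRecording], GroundTruth]:
    """Simulate a genotype cohort; fly f draws from stream (seed, f)."""
    rngs = [
        np.random.default_rng(np.random.SeedSequence([int(seed), f]))
        for f in range(cfg.n_flies)
    ]
    fly_ids = [f"{cfg.label}#{f + 1:02d}" for f in range(cfg.n_flies)]
    return _simulate_flies(cfg, rngs, n_days, start_time, fly_ids)


def write_dam_file(
    recordings: Sequence[ActivityRecording],
    path: str | os.PathLike,
) -> None:
    """Write recordings as one TriKinetics monitor file (32 channels).

    Recordings occupy channels 1..n in order; unused channels are zero.
    Round-trips exactly through :func:`flychrono.dam_io.parse_monitor_file`.
    """
    recs = list(recordings)
    if not recs:
        raise ValueError("no recordings to write")
    if len(recs) > DAM_N_CHANNELS:
        raise ValueError(f"at most {DAM_N_CHANNELS} recordings per monitor file")
    n_bins = recs[0].n_bins
    start = recs[0].start_time
    bin_min = recs[0].bin_minutes
    for r in recs[1:]:
        if r.n_bins != n_bins or r.start_time != start or r.bin_minutes != bin_min:
            raise ValueError("all recordings in a monitor must be aligned")

    matrix = np.zeros((n_bins, DAM_N_CHANNELS), dtype=np.int64)
    for ch, r in enumerate(recs):
        matrix[:, ch] = r.counts

    meta_pad = "\t".join(["0"] * (DAM_N_META_COLUMNS - 4))
    with open(path, "wt", encoding="utf-8") as fh:
        for i in range(n_bins):
            ts = start + dt.timedelta(minutes=i * bin_min)
            row = "\t".join(
                [
                    str(i + 1),
                    ts.strftime(DAM_DATE_FORMAT),
                    ts.strftime("%H:%M:%S"),
                    str(DAM_OK_STATUS),
                    meta_pad,
                ]
                + [str(int(v)) for v in matrix[i]]
            )
            fh.write(row + "\n")


def _nb_counts(
    mu: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial counts via the gamma–Poisson mixture."""
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_counts_and_de(
    n_genes: int,
    n_replicates: int = 3,
    de_fraction: float = 0.05,
    lfc_location: float = 2.0,
    lfc_scale: float = 0.5,
    base_mean: float = 200.0,
    dispersion: float = 0.1,
    n_low_count: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, frozenset]]:
    """Simulate a two-condition DE result table with programmed true DEG sets.

    Counts are negative-binomial; programmed DE genes carry a log2
    fold-change of ±(``lfc_location`` + half-normal(``lfc_scale``)) so they
    clear the |log2FC| >= 1 rule in expectation.  Empirical log2FC, a
    per-gene Welch t on log2(count+1), and BH-adjusted p-values are reported;
    ``total_reads`` is the realised read sum so prefiltering is consistent
    with the counts.  ``n_low_count`` genes are given near-zero expression to
    exercise the <10-read prefilter.

    Returns the table and the programmed truth ``{"up": ..., "down": ...}``.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    gene_ids = np.array([f"gene{i:05d}" for i in range(n_genes)])

    mu_base = rng.lognormal(math.log(base_mean), 0.5, n_genes)
    low = np.zeros(n_genes, dtype=bool)
    if n_low_count:
        low_idx = rng.choice(n_genes, size=n_low_count, replace=False)
        low[low_idx] = True
        mu_base[low] = 0.3  # expected total well below 10 reads

    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(np.flatnonzero(~low), size=min(n_de, (~low).sum()), replace=False)
    lfc_true = np.zeros(n_genes)
    signs = rng.choice([-1.0, 1.0], size=de_idx.size)
    lfc_true[de_idx] = signs * (lfc_location + np.abs(rng.normal(0, lfc_scale, de_idx.size)))

    mu_ctrl = np.repeat(mu_base[:, None], n_replicates, axis=1)
    mu_trt = mu_ctrl * 2.0 ** lfc_true[:, None]
    counts_ctrl = _nb_counts(mu_ctrl, dispersion, rng)
    counts_trt = _nb_counts(mu_trt, dispersion, rng)

    log_c = np.log2(counts_ctrl + 1.0)
    log_t = np.log2(counts_trt + 1.0)
    res = stats.ttest_ind(log_t, log_c, axis=1, equal_var=False)
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    padj = stats.false_discovery_control(pvals, method="bh")

    mean_c = counts_ctrl.mean(axis=1)
    mean_t = counts_trt.mean(axis=1)
    log2fc = np.log2((mean_t + 0.5) / (mean_c + 0.5))
    total_reads = counts_ctrl.sum(axis=1) + counts_trt.sum(axis=1)

    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": log2fc,
            "padj": padj,
            "total_reads": total_reads,
        }
    )
    truth = {
        "up": frozenset(gene_ids[lfc_true > 0]),
        "down": frozenset(gene_ids[lfc_true < 0]),
    }
    return table, truth


def make_overlap_tables(
    labels: Sequence[str] = ("mutantA", "mutantB"),
    shared_up: int = 5,
    shared_down: int = 8,
    unique_up: Sequence[int] = (7, 14),
    unique_down: Sequence[int] = (9, 4),
    n_null: int = 50,
    n_below_prefilter: int = 0,
) -> dict[str, pd.DataFrame]:
    """Deterministic DE tables engineered for exact overlap accounting.

    Every table shares the same gene universe; the programmed shared and
    unique up/down genes carry log2FC ±2 and padj 0.001, all other genes are
    null (log2FC 0, padj 1).  ``n_below_prefilter`` genes per table get a
    read sum of 5 to exercise the <10-read prefilter.
    """
    if len(labels) != len(set(labels)):
        raise ValueError("labels must be unique")
    if len(unique_up) != len(labels) or len(unique_down) != len(labels):
        raise ValueError("unique_up/unique_down need one entry per label")

    gene_sets: dict[str, dict[str, list[str]]] = {
        lab: {"up": [], "down": []} for lab in labels
    }
    universe: list[str] = []

    def add(name: str) -> str:
        universe.append(name)
        return name

    for i in range(shared_up):
        g = add(f"shared_up_{i:03d}")
        for lab in labels:
            gene_sets[lab]["up"].append(g)
    for i in range(shared_down):
        g = add(f"shared_down_{i:03d}")
        for lab in labels:
            gene_sets[lab]["down"].append(g)
    for lab, n_up, n_down in zip(labels, unique_up, unique_down):
        for i in range(n_up):
            gene_sets[lab]["up"].append(add(f"{lab}_up_{i:03d}"))
        for i in range(n_down):
            gene_sets[lab]["down"].append(add(f"{lab}_down_{i:03d}"))
    for i in range(n_null):
        add(f"null_{i:04d}")
    low_genes = [add(f"lowcount_{i:03d}") for i in range(n_below_prefilter)]

    tables = {}
    for lab in labels:
        up = set(gene_sets[lab]["up"])
        down = set(gene_sets[lab]["down"])
        rows = []
        for g in universe:
            lfc = 2.0 if g in up else (-2.0 if g in down else 0.0)
            padj = 0.001 if (g in up or g in down) else 1.0
            rows.append(
                {
                    "gene_id": g,
                    "log2fc": lfc,
                    "padj": padj,
                    "total_reads": 5 if g in low_genes else 500,
                }
            )
        tables[lab] = pd.DataFrame(rows)
    return tables


def simulate_counts(
    unit_kind: str,
    group_means: Mapping[str, float],
    cv: float,
    n_per_group: int | Mapping[str, int],
    seed: int,
) -> pd.DataFrame:
    """Overdispersed per-unit count table (lognormal with the stated CV).

    Default use: haemocyte concentrations per larva or glia counts per brain.
    ``cv = 0`` yields exactly the group means.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for genotype in group_means:
        mean = float(group_means[genotype])
        if mean <= 0:
            raise ValueError(f"group mean for {genotype!r} must be positive")
        n = n_per_group if isinstance(n_per_group, int) else int(n_per_group[genotype])
        if cv == 0:
            values = np.full(n, mean)
        else:
            sigma2 = math.log(1.0 + cv**2)
            mu = math.log(mean) - sigma2 / 2.0
            values = rng.lognormal(mu, math.sqrt(sigma2), n)
        for i, v in enumerate(values):
            rows.append(
                {
                    "unit_id": f"{genotype}_{unit_kind}_{i + 1:03d}",
                    "genotype": genotype,
                    "value": float(v),
                    "unit_kind": unit_kind,
                }
            )
    return pd.DataFrame(rows)
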