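"""Survival and count statistics: Kaplan–Meier, log-rank, t-tests, eclosion.

The product-limit estimator and the two-group Mantel–Haenszel (log-rank,
Mantel–Cox) test are implemented directly from their defining formulas:

    S(t) = prod_{t_i <= t} (1 - d_i / n_i)

    chi^2 = (sum_j (O_Aj - E_Aj))^2 / sum_j V_j,   df = 1

with E_Aj = n_Aj d_j / n_j and the hypergeometric variance
V_j = d_j (n_Aj/n_j)(n_Bj/n_j)(n_j - d_j)/(n_j - 1), which carries the tie
correction.  "Mantel–Haenszel test" follows Prism's naming for this test.

Group comparisons of eclosion percentages, haemocyte concentrations and cell
counts use the unpaired two-tailed Student t-test (pooled variance; Welch
behind a flag).  Degenerate zero-variance groups fall back to a label
permutation test instead of dividing by zero.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("flychrono")

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "TTestResult",
    "km_estimate",
    "median_survival",
    "logrank_test",
    "two_sample_t",
    "eclosion_stats",
    "count_compare",
    "haemocyte_concentration",
]


@dataclass
class SurvivalCurve:
    """Kaplan–Meier step function for one group."""

    label: str
    times: np.ndarray        # distinct event times, ascending
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray     # S(t) just after each event time
    n_total: int

    @property
    def median_survival_days(self) -> float:
        return median_survival(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
            }
        )


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


@dataclass
class TTestResult:
    statistic: float
    p_value: float
    df: float
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    method: str = "student"


def _durations_events(group) -> tuple[np.ndarray, np.ndarray]:
    """Accept (durations, events) arrays, a vitals DataFrame, or FlyVitals list."""
    if isinstance(group, tuple) and len(group) == 2:
        d, e = group
        return np.asarray(d, dtype=float), np.asarray(e, dtype=bool)
    if isinstance(group, pd.DataFrame):
        return group["lifespan_days"].to_numpy(dtype=float), group["dead"].to_numpy(dtype=bool)
    seq = list(group)
    if seq and hasattr(seq[0], "lifespan_days"):
        return (
            np.array([v.lifespan_days for v in seq], dtype=float),
            np.array([v.dead for v in seq], dtype=bool),
        )
    raise TypeError("expected (durations, events), a vitals DataFrame, or FlyVitals")


def km_estimate(group, label: str = "") -> SurvivalCurve:
    """Product-limit survival estimate with right censoring.

    ``group`` may be a ``(durations, events)`` pair, a vitals DataFrame with
    ``lifespan_days``/``dead`` columns, or a sequence of FlyVitals.
    """
    durations, events = _durations_events(group)
    if durations.size == 0:
        raise ValueError(f"empty group {label!r}")
    order = np.argsort(durations, kind="stable")
    durations, events = durations[order], events[order]

    event_times = np.unique(durations[events])
    n_at_risk = np.array([(durations >= t).sum() for t in event_times], dtype=np.int64)
    n_events = np.array(
        [((durations == t) & events).sum() for t in event_times], dtype=np.int64
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        survival = np.cumprod(1.0 - n_events / n_at_risk)
    return SurvivalCurve(
        label=label,
        times=event_times,
        n_at_risk=n_at_risk,
        n_events=n_events,
        survival=survival,
        n_total=int(durations.size),
    )


def median_survival(curve: SurvivalCurve, interpolation: str = "step") -> float:
    """Smallest time with S(t) <= 0.5; NaN if S never reaches 0.5.

    ``interpolation="midpoint"`` reproduces the convention of reporting the
    midpoint of an exact S = 0.5 plateau (as spreadsheet survival tools do
    for even-sized cohorts), yielding fractional medians such as 22.5 days.
    """
    below = curve.survival <= 0.5
    if not below.any():
        return float("nan")
    i = int(np.argmax(below))
    t = float(curve.times[i])
    if (
        interpolation == "midpoint"
        and np.isclose(curve.survival[i], 0.5)
        and i + 1 < curve.times.size
    ):
        return (t + float(curve.times[i + 1])) / 2.0
    if interpolation not in ("step", "midpoint"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return t


def logrank_test(group_a, group_b) -> LogRankResult:
    """Two-group Mantel–Haenszel (log-rank) test with tie-corrected variance."""
    da, ea = _durations_events(group_a)
    db, eb = _durations_events(group_b)
    if da.size == 0 or db.size == 0:
        raise ValueError("both groups must be non-empty")

    all_d = np.concatenate([da, db])
    all_e = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(da.size, bool), np.zeros(db.size, bool)])
    event_times = np.unique(all_d[all_e])
    if event_times.size == 0:
        raise ValueError("no events in either group")

    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = all_d >= t
        n_j = int(at_risk.sum())
        n_aj = int((at_risk & in_a).sum())
        died = (all_d == t) & all_e
        d_j = int(died.sum())
        d_aj = int((died & in_a).sum())
        e_aj = n_aj * d_j / n_j
        o_minus_e += d_aj - e_aj
        if n_j > 1:
            var += d_j * (n_aj / n_j) * (1 - n_aj / n_j) * (n_j - d_j) / (n_j - 1)
    if var == 0.0:
        return LogRankResult(chi_square=0.0, df=1, p_value=1.0)
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(chi_square=float(chi2), df=1, p_value=max(p, np.nextafter(0, 1)))


def _permutation_p(a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator) -> float:
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n_a = a.size
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(pooled[:n_a].mean() - pooled[n_a:].mean()) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    welch: bool = False,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> TTestResult:
    """Unpaired two-tailed t-test (Student by default, Welch behind a flag).

    When both groups have zero variance the t statistic is undefined; a label
    permutation test is used instead and the p-value is bounded below by
    1/(n_perm+1).  Groups with fewer than two observations yield NaN
    statistics (reported missing, not an error).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    summary = dict(
        mean_a=float(a.mean()) if a.size else float("nan"),
        mean_b=float(b.mean()) if b.size else float("nan"),
        sem_a=float(stats.sem(a)) if a.size > 1 else float("nan"),
        sem_b=float(stats.sem(b)) if b.size > 1 else float("nan"),
        n_a=int(a.size),
        n_b=int(b.size),
    )
    if a.size < 2 or b.size < 2:
        log.warning("t-test skipped: group with <2 observations")
        return TTestResult(float("nan"), float("nan"), float("nan"), method="skipped", **summary)
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, float(a.size + b.size - 2), method="student", **summary)
        rng = rng if rng is not None else np.random.default_rng(0)
        p = _permutation_p(a.copy(), b.copy(), n_perm, rng)
        log.warning("zero-variance groups: permutation fallback, p bounded at 1/%d", n_perm + 1)
        return TTestResult(float("inf"), p, float("nan"), method="permutation", **summary)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else float(a.size + b.size - 2)
    return TTestResult(
        float(res.statistic), float(res.pvalue), df,
        method="welch" if welch else "student", **summary,
    )


def eclosion_stats(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Eclosion percentages per replicate vial and pairwise genotype t-tests.

    ``table`` needs columns genotype, n_input_larvae, n_eclosed (one row per
    replicate vial; the vial is the unit of replication).  Returns a
    per-genotype summary (mean % ± sem, n replicates) and a pairwise
    comparison table.
    """
    required = {"genotype", "n_input_larvae", "n_eclosed"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"eclosion table missing columns: {sorted(missing)}")
    if (table["n_eclosed"] > table["n_input_larvae"]).any():
        raise ValueError("n_eclosed exceeds n_input_larvae")
    tab = table.copy()
    tab["percent_eclosed"] = 100.0 * tab["n_eclosed"] / tab["n_input_larvae"]

    summary = (
        tab.groupby("genotype")["percent_eclosed"]
        .agg(mean_percent="mean", sem_percent=lambda x: stats.sem(x) if len(x) > 1 else np.nan,
             n_replicates="count")
        .reset_index()
    )
    rows = []
    for g1, g2 in itertools.combinations(sorted(tab["genotype"].unique()), 2):
        res = two_sample_t(
            tab.loc[tab["genotype"] == g1, "percent_eclosed"],
            tab.loc[tab["genotype"] == g2, "percent_eclosed"],
        )
        rows.append({"group_a": g1, "group_b": g2, "t": res.statistic,
                     "p_value": res.p_value, "method": res.method})
    return summary, pd.DataFrame(rows)


def count_compare(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    value_col: str = "value",
    welch: bool = False,
) -> TTestResult:
    """Compare per-unit counts (haemocytes/mL per larva, cells per brain, ...)
    between two genotypes with an unpaired two-tailed t-test."""
    va = table.loc[table["genotype"] == group_a, value_col].to_numpy(dtype=float)
    vb = table.loc[table["genotype"] == group_b, value_col].to_numpy(dtype=float)
    if va.size == 0 or vb.size == 0:
        raise ValueError(f"empty group among {group_a!r}, {group_b!r}")
    return two_sample_t(va, vb, welch=welch)


def haemocyte_concentration(
    cells_counted: float,
    chamber_factor: float = 1e4,
    dilution_factor: float = 2.0,
) -> float:
    """Cells per mL of haemolymph from a haemocytometer chamber count.

    ``chamber_factor`` converts the chamber count to cells/mL of the loaded
    sample (10^4 for a standard 0.1 µL Neubauer large square);
    ``dilution_factor`` undoes the bleed dilution — 2 for the protocol of
    bleeding into 10 µL PBS plus 10 µL trypan blue.
    """
    if cells_counted < 0:
        raise ValueError("cell count must be non-negative")
    return cells_counted * chamber_factor * dilution_factor
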