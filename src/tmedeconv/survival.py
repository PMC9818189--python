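"""Survival stratification by estimated cell fractions.

The cohort is ordered by descending fraction of one cell type and every
rank split (1:n-1 through n-1:1) is scored with a two-group log-rank test.
The split with the lowest p-value is kept when it reaches ``alpha``;
otherwise the cohort is split at the median rank. Kaplan-Meier curves are
fitted per group for plotting.

Because the minimum p-value over all cuts is taken without any
multiple-testing correction, the procedure is anti-conservative under the
null (the empirical rate of min-p < 0.05 exceeds 5%); this is a property of
the exhaustive-search strategy itself and is surfaced in the split report
rather than corrected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from sksurv.nonparametric import kaplan_meier_estimator

from .errors import ConfigurationError, DataError

log = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.4375  # 365.25 / 12
MONTHS_PER_YEAR = 12.0
SMALL_GROUP = 5  # optimised splits below this size are flagged, not overridden


@dataclass(frozen=True)
class SurvivalRecord:
    """One follow-up record: time in months, event=True for an observed event."""

    sample_id: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DataError(f"sample {self.sample_id!r}: negative survival time")


def to_months(time: float, unit: str) -> float:
    """Convert a survival length to months (days / 30.4375; years x 12)."""
    if time < 0:
        raise DataError(f"negative survival time: {time}")
    if unit == "days":
        return time / DAYS_PER_MONTH
    if unit == "months":
        return time
    if unit == "years":
        return time * MONTHS_PER_YEAR
    raise ConfigurationError(
        f"unknown time unit {unit!r}; valid units: ['days', 'months', 'years']"
    )


def records_from_frame(df: pd.DataFrame) -> list[SurvivalRecord]:
    """Build records from a table with sample_id / time / event columns."""
    need = {"sample_id", "time", "event"}
    if not need <= set(df.columns):
        raise DataError(f"survival table needs columns {sorted(need)}, has {list(df.columns)}")
    return [
        SurvivalRecord(str(r.sample_id), float(r.time), bool(int(r.event)))
        for r in df.itertuples(index=False)
    ]


def _split_arrays(records: Iterable[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    recs = list(records)
    return (
        np.array([r.time for r in recs], dtype=float),
        np.array([r.event for r in recs], dtype=bool),
    )


@dataclass
class LogrankResult:
    statistic: float
    p_value: float


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> LogrankResult:
    """Two-group log-rank test (chi-squared, 1 df, hypergeometric variance)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise DataError("log-rank test requires two non-empty groups")
    ta, ea = _split_arrays(group_a)
    tb, eb = _split_arrays(group_b)
    if not (ea.any() or eb.any()):
        raise DataError("log-rank test undefined: no observed events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogrankResult(float(res.test_statistic), float(res.p_value))


@dataclass
class KMCurve:
    """Right-continuous Kaplan-Meier step function (S(t)=1 before the first time)."""

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray

    def __call__(self, t: float) -> float:
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return 1.0 if i < 0 else float(self.survival[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "n_at_risk": self.n_at_risk}
        )


def km_curve(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit survival estimate over a group of records."""
    if len(records) == 0:
        raise DataError("cannot fit a Kaplan-Meier curve to an empty group")
    times, events = _split_arrays(records)
    uniq, prob = kaplan_meier_estimator(events, times)
    at_risk = np.array([(times >= t).sum() for t in uniq])
    return KMCurve(np.asarray(uniq, dtype=float), np.asarray(prob, dtype=float), at_risk)


@dataclass
class SplitResult:
    """Outcome of the exhaustive cut-point search.

    ``cut_rank`` is the size of the high-fraction group (1-based rank of the
    cut). ``all_p`` holds one log-rank p-value per tested cut, in cut order
    ``tested_cuts``. ``small_group`` flags an optimised split that isolated
    fewer than 5 samples on one side (meaningless-grouping warning).
    """

    cut_rank: int
    p_value: float
    strategy: str  # "optimised" | "median"
    group_assignment: dict[str, str]  # sample_id -> "high" | "low"
    all_p: np.ndarray
    tested_cuts: np.ndarray
    small_group: bool = False
    tie_at_cut: bool = False

    def groups(self, cohort: Sequence[SurvivalRecord]) -> tuple[list[SurvivalRecord], list[SurvivalRecord]]:
        high = [r for r in cohort if self.group_assignment[r.sample_id] == "high"]
        low = [r for r in cohort if self.group_assignment[r.sample_id] == "low"]
        return high, low


def optimal_split(
    fractions: Sequence[float],
    cohort: Sequence[SurvivalRecord],
    min_group: int = 1,
    alpha: float = 0.05,
) -> SplitResult:
    """Exhaustive log-rank cut-point search with median fallback.

    The cohort is sorted by descending fraction (ties broken by sample_id,
    stable); each cut size k from ``min_group`` to n-``min_group`` places
    the top-k samples in the high group and is scored by log-rank. If the
    minimum p-value is <= ``alpha`` the arg-min cut is returned
    (``strategy="optimised"``); otherwise the cohort is split at the median
    rank (``strategy="median"``, groups differing in size by at most one).
    """
    cohort = list(cohort)
    frac = np.asarray(fractions, dtype=float)
    n = len(cohort)
    if frac.shape != (n,):
        raise DataError(
            f"fractions ({frac.size}) and cohort ({n}) lengths do not match"
        )
    if n < 4:
        raise DataError(f"cut-point search needs n >= 4 samples, got {n}")
    if not (1 <= min_group <= n // 2):
        raise ConfigurationError(f"min_group must be in [1, n//2], got {min_group}")
    ids = [r.sample_id for r in cohort]
    if len(set(ids)) != n:
        raise DataError("cohort sample_ids are not unique")

    times, events = _split_arrays(cohort)
    if not events.any():
        raise DataError("cut-point search undefined: cohort has no observed events")

    order = np.lexsort((np.array(ids, dtype=object), -frac))
    t_sorted, e_sorted = times[order], events[order]

    all_same = bool(np.all(frac == frac[0]))
    if all_same:
        log.warning("all fractions identical: ordering arbitrary, using median split")

    cuts = np.arange(min_group, n - min_group + 1)
    all_p = np.empty(cuts.size)
    for i, k in enumerate(cuts):
        res = _ll_logrank(
            t_sorted[:k], t_sorted[k:],
            event_observed_A=e_sorted[:k], event_observed_B=e_sorted[k:],
        )
        p = float(res.p_value)
        all_p[i] = 1.0 if math.isnan(p) else p

    median_cut = (n + 1) // 2  # high group gets the extra sample when n is odd
    if not all_same and all_p.min() <= alpha:
        i_best = int(np.argmin(all_p))
        cut = int(cuts[i_best])
        p_value = float(all_p[i_best])
        strategy = "optimised"
    else:
        cut = median_cut
        i_med = int(np.flatnonzero(cuts == cut)[0]) if (cuts == cut).any() else None
        p_value = float(all_p[i_med]) if i_med is not None else float(all_p.min())
        strategy = "median"

    tie = bool(frac[order[cut - 1]] == frac[order[cut]]) if not all_same else True
    if tie and not all_same:
        log.warning(
            "tied fractions straddle the chosen cut (rank %d); group membership "
            "among tied samples follows sample_id order", cut,
        )
    small = strategy == "optimised" and min(cut, n - cut) < SMALL_GROUP
    if small:
        log.warning(
            "optimised split isolates a group of %d (< %d) samples; consider "
            "rerunning with a larger min_group", min(cut, n - cut), SMALL_GROUP,
        )
    assignment = {
        ids[order[i]]: ("high" if i < cut else "low") for i in range(n)
    }
    return SplitResult(
        cut_rank=cut,
        p_value=p_value,
        strategy=strategy,
        group_assignment=assignment,
        all_p=all_p,
        tested_cuts=cuts,
        small_group=small,
        tie_at_cut=tie,
    )
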