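"""Kaplan-Meier estimation and Fleming-Harrington weighted log-rank tests.

The two-sample test implemented here is the G^rho family: the classic
log-rank at ``rho = 0`` and the Peto-Peto test at ``rho = 1`` (weights equal
to the left limit of the pooled Kaplan-Meier estimate raised to ``rho``),
which up-weights early survival differences.  The two-sample statistic is
kept in signed standardized form so that one-sided alternatives — "group A's
survival is lower" — are available; that direction is what the Bliss
synergism test needs.

The k-sample omnibus test and the Holm-corrected pairwise comparisons follow
the standard survival-analysis workflow for comparing treatment arms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous product-limit survival curve.

    ``times`` are the distinct observed times (events or censorings),
    ``survival`` the estimate S(t) at each, ``at_risk`` the number at risk
    just before each time and ``events`` the number of deaths at each.
    ``S(0-) = 1``; deaths precede censorings at tied times.
    """

    times: tuple
    survival: tuple
    at_risk: tuple
    events: tuple
    n0: int

    def probability_at(self, t: float) -> float:
        """S(t) by right-continuous step evaluation (1 before first time)."""
        idx = np.searchsorted(np.asarray(self.times), t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


@dataclass(frozen=True)
class TestResult:
    """Outcome of a (weighted) log-rank test.

    For two-sample tests ``statistic`` is the signed standardized statistic
    Z (positive when the first group dies earlier); for the omnibus test it
    is the chi-squared statistic on ``df`` degrees of freedom.
    """

    statistic: float
    df: int
    p_value: float
    alternative: str  # "two_sided" or "observed_less"
    rho: float


def _durations_events(records) -> tuple:
    t = np.asarray([r.last_time for r in records], dtype=float)
    e = np.asarray([r.event for r in records], dtype=int)
    return t, e


def kaplan_meier(records) -> SurvivalCurve:
    """Product-limit estimate from right-censored records.

    S(t) = prod_{t_k <= t} (1 - d_k / n_k) over distinct death times t_k;
    censored-only times appear in the curve but do not change S.
    """
    if len(records) == 0:
        raise ValueError("kaplan_meier requires at least one record")
    t, e = _durations_events(records)
    if np.any(t <= 0):
        raise ValueError("all observation times must be positive")
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    uts, first = np.unique(ts, return_index=True)
    n_at_risk = len(ts) - first
    d = np.add.reduceat(es, first)
    surv = np.cumprod(1.0 - d / n_at_risk)
    return SurvivalCurve(
        times=tuple(uts),
        survival=tuple(surv),
        at_risk=tuple(int(n) for n in n_at_risk),
        events=tuple(int(x) for x in d),
        n0=len(ts),
    )


def _fh_logrank_arrays(
    t1: np.ndarray,
    e1: np.ndarray,
    t2: np.ndarray,
    e2: np.ndarray,
    rho: float,
) -> tuple:
    """Signed standardized G^rho statistic for group 1 vs group 2.

    Returns ``(z, var)``; ``z`` is positive when group 1 has the earlier
    deaths (lower survival).  Weights are S_pool(t-)^rho with S_pool the
    pooled Kaplan-Meier estimate.
    """
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    uts, first = np.unique(ts, return_index=True)
    n_tot = len(ts) - first
    d_tot = np.add.reduceat(es, first)

    t1s = np.sort(t1)
    n1 = len(t1) - np.searchsorted(t1s, uts, side="left")
    # deaths in group 1 at each distinct time
    d1 = np.zeros_like(d_tot, dtype=float)
    death_times = t1[e1 == 1]
    if death_times.size:
        pos = np.searchsorted(uts, death_times)
        np.add.at(d1, pos, 1.0)

    # pooled KM left limit at each distinct time
    s_pool = np.cumprod(1.0 - d_tot / n_tot)
    s_left = np.concatenate([[1.0], s_pool[:-1]])
    w = s_left**rho

    mask = d_tot > 0
    n, dd, nn1, ww, dd1 = (
        n_tot[mask].astype(float),
        d_tot[mask].astype(float),
        n1[mask].astype(float),
        w[mask],
        d1[mask],
    )
    expected = nn1 * dd / n
    score = float(np.sum(ww * (dd1 - expected)))
    with np.errstate(divide="ignore", invalid="ignore"):
        v_terms = np.where(
            n > 1,
            dd * (nn1 / n) * (1 - nn1 / n) * (n - dd) / (n - 1),
            0.0,
        )
    var = float(np.sum(ww**2 * v_terms))
    z = score / np.sqrt(var) if var > 0 else 0.0
    return z, var


def fh_weighted_logrank(
    a,
    b,
    rho: float = 0.0,
    alternative: str = "two_sided",
) -> TestResult:
    """Two-sample Fleming-Harrington G^rho test of records ``a`` vs ``b``.

    ``alternative="observed_less"`` tests the one-sided hypothesis that
    group ``a``'s survival lies below group ``b``'s (i.e. ``a`` dies
    earlier); its p-value is the upper normal tail of the signed statistic.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if rho < 0:
        raise ValueError("rho must be >= 0")
    if alternative not in ("two_sided", "observed_less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    t1, e1 = _durations_events(a)
    t2, e2 = _durations_events(b)
    z, var = _fh_logrank_arrays(t1, e1, t2, e2, rho)
    if var == 0:
        p = 1.0
    elif alternative == "two_sided":
        p = float(stats.chi2.sf(z * z, 1))
    else:
        p = float(stats.norm.sf(z))
    return TestResult(
        statistic=float(z), df=1, p_value=p, alternative=alternative, rho=rho
    )


def omnibus_logrank(groups: Mapping[str, Sequence]) -> TestResult:
    """k-sample log-rank test (rho = 0) across labelled record groups."""
    if len(groups) < 2:
        raise ValueError("omnibus test needs at least 2 groups")
    durations, events, labels = [], [], []
    for label, records in groups.items():
        if len(records) == 0:
            raise ValueError(f"group {label!r} is empty")
        t, e = _durations_events(records)
        durations.append(t)
        events.append(e)
        labels.extend([label] * len(records))
    res = multivariate_logrank_test(
        np.concatenate(durations), labels, np.concatenate(events)
    )
    df = len(groups) - 1
    return TestResult(
        statistic=float(res.test_statistic),
        df=df,
        p_value=float(res.p_value),
        alternative="two_sided",
        rho=0.0,
    )


def pairwise_logrank_holm(
    groups: Mapping[str, Sequence], rho: float = 0.0
) -> pd.DataFrame:
    """Holm-adjusted two-sided pairwise G^rho p-values between all groups.

    Returns a symmetric DataFrame indexed by group label; the diagonal is
    NaN.  Adjusted p-values are never smaller than the raw ones.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("pairwise comparison needs at least 2 groups")
    pairs = [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]
    raw = [
        fh_weighted_logrank(groups[x], groups[y], rho=rho).p_value
        for x, y in pairs
    ]
    adjusted = multipletests(raw, method="holm")[1]
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for (x, y), p in zip(pairs, adjusted):
        mat.loc[x, y] = p
        mat.loc[y, x] = p
    return mat
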