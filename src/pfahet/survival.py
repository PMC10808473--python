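"""Kaplan-Meier estimation, two-group log-rank testing, and maximally selected
cutoff search over a continuous covariate.

The stratification question: does the fraction of cell-dense tumor area
predict progression-free or overall survival?  Two dichotomizations are
used — the median split, and the "best cutoff" found by an exhaustive scan
over every possible split of the cohort, taking the cutoff with the smallest
log-rank p.  The scanned minimum p is strongly anti-conservative (a
maximally selected statistic); an optional permutation adjustment quantifies
that selection effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "CutoffSearchResult",
    "km_estimate",
    "logrank_test",
    "split_at_median",
    "best_cutoff_search",
    "permutation_adjusted_p",
    "plot_km",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate: S(t) at each distinct event time."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time

    def survival_at(self, t: float) -> float:
        """Step-function evaluation: S(t), with S = 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class CutoffSearchResult:
    best_cutoff: float
    best_p: float
    n_low: int
    n_high: int
    scan: pd.DataFrame = field(repr=False)  # columns: cutoff, statistic, p, n_low, n_high


def _check_records(time: np.ndarray, event: np.ndarray) -> None:
    if len(time) == 0:
        raise ValueError("no survival records")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if not np.all(np.isin(event, (0, 1))):
        raise ValueError("event indicator must be 0 (censored) or 1 (event)")


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Ties are handled by reducing the risk set simultaneously for all events
    at a time; censorings at an event time leave the risk set after the
    events at that time.  A dataset with no events returns S identical to 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _check_records(time, event)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    n = len(time)

    ev_times = np.unique(time[event == 1])
    at_risk = np.empty(len(ev_times))
    d = np.empty(len(ev_times))
    for i, t in enumerate(ev_times):
        at_risk[i] = np.sum(time >= t)
        d[i] = np.sum((time == t) & (event == 1))
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(times=ev_times, survival=surv, at_risk=at_risk)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    At each distinct event time, observed minus expected events in group 1
    are accumulated with hypergeometric variance; the statistic is
    (sum O-E)^2 / sum V, referred to chi-square with 1 df.  Ties across
    groups are handled through the hypergeometric formulation.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    _check_records(time, event)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError(f"exactly two non-empty groups required, got {list(labels)}")
    g1 = group == labels[1]

    ev_times = np.unique(time[event == 1])
    if len(ev_times) == 0:
        return 0.0, 1.0
    # risk sets and event counts at each distinct event time, via sorted search
    st_all = np.sort(time)
    st_g1 = np.sort(time[g1])
    et_all = np.sort(time[event == 1])
    et_g1 = np.sort(time[(event == 1) & g1])
    n_t = len(st_all) - np.searchsorted(st_all, ev_times, side="left")
    n1_t = len(st_g1) - np.searchsorted(st_g1, ev_times, side="left")
    d_t = np.searchsorted(et_all, ev_times, side="right") - np.searchsorted(
        et_all, ev_times, side="left"
    )
    d1_t = np.searchsorted(et_g1, ev_times, side="right") - np.searchsorted(
        et_g1, ev_times, side="left"
    )
    frac1 = n1_t / n_t
    o_minus_e = float(np.sum(d1_t - d_t * frac1))
    ok = n_t > 1
    var = float(
        np.sum(d_t[ok] * frac1[ok] * (1 - frac1[ok]) * (n_t[ok] - d_t[ok]) / (n_t[ok] - 1))
    )
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def split_at_median(covariate) -> np.ndarray:
    """Median split: "low" for covariate below the median, "high" at or above.

    With an even number of distinct values this yields an n/2 vs n/2 split.
    Raises if every covariate value is identical (no split exists).
    """
    cov = np.asarray(covariate, dtype=float)
    if len(cov) < 2:
        raise ValueError("need at least two records to split")
    if np.all(cov == cov[0]):
        raise ValueError("all covariate values identical: no median split exists")
    med = np.median(cov)
    return np.where(cov < med, "low", "high")


def _candidate_cutoffs(cov: np.ndarray) -> np.ndarray:
    vals = np.unique(cov)
    if len(vals) < 2:
        raise ValueError("need at least two distinct covariate values")
    return (vals[:-1] + vals[1:]) / 2.0


def best_cutoff_search(time, event, covariate, min_group_size: int = 1) -> CutoffSearchResult:
    """Exhaustive best-cutoff scan: the dichotomization with the smallest log-rank p.

    Candidate cutoffs are the midpoints between consecutive distinct
    covariate values, so every possible two-group allocation of the cohort
    is tested exactly once.  Cutoffs leaving either group below
    ``min_group_size`` are not admissible.  No multiplicity correction is
    applied to ``best_p`` (see :func:`permutation_adjusted_p`).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    cov = np.asarray(covariate, dtype=float)
    _check_records(time, event)
    rows = []
    for cut in _candidate_cutoffs(cov):
        high = cov >= cut
        n_high = int(high.sum())
        n_low = len(cov) - n_high
        if min(n_low, n_high) < min_group_size:
            continue
        stat, p = logrank_test(time, event, np.where(high, "high", "low"))
        rows.append({"cutoff": cut, "statistic": stat, "p": p, "n_low": n_low, "n_high": n_high})
    if not rows:
        raise ValueError("no admissible cutoff under min_group_size")
    scan = pd.DataFrame(rows)
    i_best = int(scan["p"].idxmin())  # first minimum -> smallest cutoff on ties
    best = scan.loc[i_best]
    return CutoffSearchResult(
        best_cutoff=float(best["cutoff"]),
        best_p=float(best["p"]),
        n_low=int(best["n_low"]),
        n_high=int(best["n_high"]),
        scan=scan,
    )


def permutation_adjusted_p(
    time, event, covariate, min_group_size: int = 1, n_permutations: int = 200, seed: int = 0
) -> float:
    """Selection-adjusted p for the best-cutoff search.

    Permutes the covariate against (time, event) ``n_permutations`` times,
    re-runs the full scan, and reports the fraction of permutations whose
    minimum p is at most the observed minimum (add-one estimator).  This is
    an extension beyond the unadjusted scan: it quantifies how anti-
    conservative the maximally selected p is.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    cov = np.asarray(covariate, dtype=float)
    observed = best_cutoff_search(time, event, cov, min_group_size).best_p
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(cov)
        if best_cutoff_search(time, event, perm, min_group_size).best_p <= observed:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def plot_km(curves: dict[str, KMCurve], ax=None, xlabel: str = "months"):
    """Step-plot one or more KM curves; returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in curves.items():
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    return ax
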