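"""Kaplan-Meier, log-rank, median split, and the exhaustive cutoff search."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank

from pfahet import synth
from pfahet.survival import (
    best_cutoff_search,
    km_estimate,
    logrank_test,
    permutation_adjusted_p,
    split_at_median,
)


def naive_logrank_stat(time, event, group):
    """Independent per-event-time accumulation of the log-rank statistic,
    written row-by-row with explicit risk sets."""
    df = pd.DataFrame({"t": time, "e": event, "g": group}).sort_values("t")
    labels = sorted(df["g"].unique())
    num, var = 0.0, 0.0
    for t in sorted(df.loc[df["e"] == 1, "t"].unique()):
        risk = df[df["t"] >= t]
        deaths = df[(df["t"] == t) & (df["e"] == 1)]
        n, d = len(risk), len(deaths)
        n1 = len(risk[risk["g"] == labels[1]])
        d1 = len(deaths[deaths["g"] == labels[1]])
        num += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return 0.0 if var == 0 else num**2 / var


# ------------------------------------------------------------------- KM ----

def test_km_closed_form():
    """Events at 1 and 2, censoring at 3: S(1) = 2/3, S(2) = 1/3."""
    curve = km_estimate([1, 2, 3], [1, 1, 0])
    assert curve.survival_at(1) == pytest.approx(2 / 3)
    assert curve.survival_at(2) == pytest.approx(1 / 3)
    assert curve.survival_at(0.5) == 1.0


def test_km_all_censored_is_unity():
    curve = km_estimate([1, 2, 3], [0, 0, 0])
    assert curve.survival_at(10) == 1.0


def test_km_nonpositive_time_errors():
    with pytest.raises(ValueError):
        km_estimate([0.0, 1.0], [1, 1])


def test_km_monotone_bounded(rng):
    t = rng.exponential(10, size=200)
    e = rng.integers(0, 2, size=200)
    e[0] = 1
    curve = km_estimate(t, e)
    assert np.all(np.diff(curve.survival) <= 1e-12)
    assert np.all((curve.survival >= 0) & (curve.survival <= 1))
    assert np.all(np.diff(curve.at_risk) <= 0)


def test_km_tracks_exponential_truth(rng):
    """n=500 uncensored exponential(lambda): sup |S_hat - exp(-lambda t)| small."""
    lam = 0.1
    t = rng.exponential(1 / lam, size=500)
    curve = km_estimate(t, np.ones(500, dtype=int))
    sup = np.max(np.abs(curve.survival - np.exp(-lam * curve.times)))
    assert sup < 0.08  # ~ KS quantile at n=500


# -------------------------------------------------------------- log-rank ----

def test_logrank_identical_groups_zero():
    t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
    e = np.array([1, 1, 0, 1, 1, 1, 0, 1])
    g = np.array(["a"] * 4 + ["b"] * 4)
    stat, p = logrank_test(t, e, g)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == 1.0


def test_logrank_label_swap_invariant(rng):
    t = rng.exponential(10, size=40)
    e = rng.integers(0, 2, size=40)
    e[:2] = 1
    g = rng.integers(0, 2, size=40)
    g[:2] = [0, 1]
    s1, p1 = logrank_test(t, e, np.where(g == 1, "x", "y"))
    s2, p2 = logrank_test(t, e, np.where(g == 1, "y", "x"))
    assert s1 == pytest.approx(s2)
    assert p1 == pytest.approx(p2)


def test_logrank_one_group_errors():
    with pytest.raises(ValueError):
        logrank_test([1, 2], [1, 1], ["a", "a"])


def test_logrank_matches_naive_oracle_exhaustive_ties():
    """All n=4 datasets over times {1,2}, events {0,1}, both groups non-empty:
    the vectorized statistic equals the naive per-event-time accumulation."""
    checked = 0
    for tmask in range(16):
        for emask in range(16):
            for gmask in range(1, 15):
                t = np.array([1.0 + ((tmask >> i) & 1) for i in range(4)])
                e = np.array([(emask >> i) & 1 for i in range(4)])
                g = np.array([(gmask >> i) & 1 for i in range(4)])
                if e.sum() == 0:
                    continue
                stat, _ = logrank_test(t, e, g)
                assert stat == pytest.approx(naive_logrank_stat(t, e, g), abs=1e-10)
                checked += 1
    assert checked > 1000


def test_logrank_matches_naive_and_lifelines_random(rng):
    for _ in range(30):
        n = int(rng.integers(4, 13))
        t = rng.choice([1.0, 2.0, 3.0, 4.0], size=n)
        e = rng.integers(0, 2, size=n)
        g = rng.integers(0, 2, size=n)
        if e.sum() == 0 or len(np.unique(g)) < 2:
            continue
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(naive_logrank_stat(t, e, g), abs=1e-10)
        ref = lifelines_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert stat == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-8)


# ---------------------------------------------------------- median split ----

def test_median_split_even_cohort_is_half_half():
    """58 distinct covariate values split 29 vs 29."""
    cov = np.linspace(0.01, 0.58, 58)
    groups = split_at_median(cov)
    assert (groups == "low").sum() == 29
    assert (groups == "high").sum() == 29


def test_median_split_two_records():
    assert list(split_at_median([0.2, 0.8])) == ["low", "high"]


def test_median_split_ties_go_high():
    groups = split_at_median([0.1, 0.5, 0.5, 0.9])
    assert list(groups) == ["low", "high", "high", "high"]


def test_median_split_identical_errors():
    with pytest.raises(ValueError):
        split_at_median([0.5, 0.5, 0.5])


# ---------------------------------------------------------- cutoff search ----

def test_best_cutoff_two_distinct_values_single_candidate():
    t = [1.0, 2.0, 3.0, 4.0]
    e = [1, 1, 1, 1]
    cov = [0.2, 0.2, 0.8, 0.8]
    res = best_cutoff_search(t, e, cov)
    assert len(res.scan) == 1
    assert res.best_cutoff == pytest.approx(0.5)
    assert res.n_low == res.n_high == 2


def test_best_cutoff_scan_covers_every_gap(rng):
    cov = rng.uniform(size=30)
    t = rng.exponential(10, size=30)
    e = np.ones(30, dtype=int)
    res = best_cutoff_search(t, e, cov)
    vals = np.sort(np.unique(cov))
    assert len(res.scan) == len(vals) - 1
    assert res.best_p == pytest.approx(res.scan["p"].min())
    # each candidate sits strictly between its neighbors
    assert np.all(res.scan["cutoff"].to_numpy() > vals[:-1])
    assert np.all(res.scan["cutoff"].to_numpy() < vals[1:])


def test_best_cutoff_beats_median_split():
    rec, _ = synth.gen_survival_cohort(synth.SynthCohortSpec(n_cases=80, seed=3))
    t, e, cov = rec["time_months"], rec["event"], rec["covariate"]
    res = best_cutoff_search(t, e, cov)
    _, p_median = logrank_test(t, e, split_at_median(cov))
    assert res.best_p <= p_median


def test_best_cutoff_min_group_size_respected():
    rec, _ = synth.gen_survival_cohort(synth.SynthCohortSpec(n_cases=40, seed=4))
    res = best_cutoff_search(rec["time_months"], rec["event"], rec["covariate"], min_group_size=10)
    assert res.scan[["n_low", "n_high"]].min().min() >= 10


def test_best_cutoff_no_admissible_errors():
    with pytest.raises(ValueError):
        best_cutoff_search([1.0, 2.0], [1, 1], [0.1, 0.9], min_group_size=2)


def test_null_best_p_is_anticonservative():
    """Under HR = 1 the scanned minimum p is far smaller than a single
    pre-specified test: its median over replicates falls below 0.05."""
    best_ps = []
    for rep in range(100):
        rec, _ = synth.gen_survival_cohort(
            synth.SynthCohortSpec(n_cases=60, hazard_ratio=1.0, seed=10_000 + rep)
        )
        best_ps.append(
            best_cutoff_search(rec["time_months"], rec["event"], rec["covariate"]).best_p
        )
    assert np.median(best_ps) < 0.05


def test_permutation_adjustment_restores_calibration():
    """The permutation-adjusted p of a null cohort is not extreme."""
    rec, _ = synth.gen_survival_cohort(
        synth.SynthCohortSpec(n_cases=40, hazard_ratio=1.0, seed=77)
    )
    p_adj = permutation_adjusted_p(
        rec["time_months"], rec["event"], rec["covariate"], n_permutations=99, seed=1
    )
    assert p_adj > 0.05


# ------------------------------------------------------ cohort generator ----

def test_cohort_no_censoring_all_events():
    spec = synth.SynthCohortSpec(n_cases=50, censor_rate=0.0, follow_up_max=np.inf, seed=1)
    rec, _ = synth.gen_survival_cohort(spec)
    assert (rec["event"] == 1).all()


def test_cohort_seed_deterministic():
    spec = synth.SynthCohortSpec(seed=9)
    a, _ = synth.gen_survival_cohort(spec)
    b, _ = synth.gen_survival_cohort(spec)
    pd.testing.assert_frame_equal(a, b)


def test_cohort_null_pvalues_uniform():
    """HR = 1: log-rank p at a fixed median split is U(0,1) (KS check)."""
    from scipy.stats import kstest

    ps = []
    for rep in range(200):
        rec, _ = synth.gen_survival_cohort(
            synth.SynthCohortSpec(n_cases=60, hazard_ratio=1.0, seed=20_000 + rep)
        )
        groups = split_at_median(rec["covariate"])
        ps.append(logrank_test(rec["time_months"], rec["event"], groups)[1])
    assert kstest(ps, "uniform").pvalue > 0.01
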