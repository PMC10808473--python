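"""Survival stratification by dense-area fraction: median vs best cutoff.

Simulates a cohort whose event hazard quadruples once the dense-area
fraction exceeds 0.7, then compares the median split with the exhaustive
best-cutoff scan (the maximally selected log-rank statistic), including the
permutation-adjusted p that accounts for the scan's selection effect.
"""

from pfahet import synth
from pfahet.survival import (best_cutoff_search, km_estimate, logrank_test,
                             permutation_adjusted_p, split_at_median)

spec = synth.SynthCohortSpec(n_cases=120, density_cutoff_true=0.7,
                             hazard_ratio=4.0, seed=5)
records, truth = synth.gen_survival_cohort(spec)
t = records["time_months"].to_numpy()
e = records["event"].to_numpy()
cov = records["covariate"].to_numpy()

stat, p_median = logrank_test(t, e, split_at_median(cov))
# a small group-size floor guards against 1-vs-(n-1) splits driven by a
# single extreme survivor; with the default floor of 1 the scan may pick one
res = best_cutoff_search(t, e, cov, min_group_size=5)
p_adj = permutation_adjusted_p(t, e, cov, min_group_size=5, n_permutations=200, seed=1)

km = km_estimate(t[cov >= res.best_cutoff], e[cov >= res.best_cutoff])
print(f"true cutoff            : {truth['density_cutoff_true']}")
print(f"median split           : p = {p_median:.4g}")
print(f"best cutoff            : {res.best_cutoff:.3f} "
      f"(groups {res.n_low}/{res.n_high}), p = {res.best_p:.3g}")
print(f"permutation-adjusted p : {p_adj:.3f}  ({200} permutations)")
print(f"12-month survival above cutoff: {km.survival_at(12):.2f}")
# The scan recovers the planted 0.7 cutoff; its unadjusted p is smaller than
# the median-split p by construction, and the permutation adjustment shows
# how much of that is the selection effect of scanning every split.
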