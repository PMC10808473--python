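"""Per-nucleus FISH scoring and the 10% area rule.

A clonal mixture (40% aberrant nuclei in the dense area, 5% in the sparse
area) is scored for chromosome 1q gain: a nucleus is aberrant with three or
more test signals or a test/control ratio above one, and a whole area is
called aberrant when at least 10% of its 100 scored nuclei are.
"""

from pfahet import synth
from pfahet.fish import FishNucleus, call_areas_table, score_nucleus_1q

spec = synth.SynthClonalSpec(clone_fraction_dense=0.40, clone_fraction_sparse=0.05,
                             n_nuclei_per_area=100, probe_noise=0.02, seed=3)
counts = synth.gen_fish_counts(spec, "gain_1q")
calls = call_areas_table(counts, "gain_1q", min_fraction=0.10)
print(calls.to_string(index=False))

for t, c in [(3, 2), (2, 2), (2, 1)]:
    print(f"nucleus test={t} control={c} -> {score_nucleus_1q(FishNucleus(t, c))}")
# The dense area crosses the 10% threshold easily; the sparse area sits near
# the boundary, where the binomial sampling of 100 nuclei decides the call.
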