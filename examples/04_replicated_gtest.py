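"""Test transmission bias with replicated G-tests of goodness-of-fit.

Reconstructs class counts from per-sample proportions, then decomposes
the total G into a pooled (shared deviation) and a heterogeneity
(among-replicate) part.
"""

from iseseg import (
    SegParams,
    reconstruct_counts,
    repeated_g_test,
    simulate_segregation,
)

# Twelve replicate samples of a one-ISE clone with drag (tb = -0.1):
# the ISE-free class should exceed its unbiased expectation of 0.5.
replicates = []
for rep in range(12):
    counts = simulate_segregation(1, SegParams(tb=-0.1), 200, seed=(3, rep))
    p0 = counts[0] / counts.sum()
    replicates.append(reconstruct_counts(200, [p0, 1 - p0], replicate_id=f"r{rep}"))

total, pooled, het = repeated_g_test(replicates, (0.5, 0.5))
for r in (total, pooled, het):
    print(f"{r.kind:>13}: G = {r.G:7.3f}  df = {r.df:2d}  p = {r.p:.3g}")
# A significant pooled G with a non-significant heterogeneity G means
# the replicates agree on one shared transmission bias.
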