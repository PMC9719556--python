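"""Evaluate the two-parameter segregation model for small clones.

Builds class distributions for a one-ISE and a two-ISE clone and prints
the O/E ratios that diagnose drive and repulsion.
"""

import numpy as np

from iseseg import SegParams, class_distribution, oe_ratios, unbiased_distribution

# A single ISE with mild drive: tb = 0.1 means the element reaches the
# egg pole with probability 0.55 instead of 0.5.
d1 = class_distribution(1, SegParams(tb=0.1, cb=0.0))
print("1 ISE, tb=0.1:  class frequencies =", d1.freqs)

# Two ISEs with repulsion: cb = -0.3 raises the chance the pair splits
# to opposite poles, inflating the intermediate class.
d2 = class_distribution(2, SegParams(tb=0.0, cb=-0.3))
table = oe_ratios(d2, unbiased_distribution(2))
print("2 ISEs, cb=-0.3: class frequencies =", d2.freqs)
print("               O/E ratios        =", table.ratio)

# Both biases together: O/E rises with class number (drive) while the
# extreme classes stay underrepresented (repulsion).
d4 = class_distribution(4, SegParams(tb=0.15, cb=-0.35))
t4 = oe_ratios(d4, unbiased_distribution(4))
print("4 ISEs, tb=0.15, cb=-0.35: O/E =", np.round(t4.ratio, 3))
# O/E = 1 everywhere would mean unbiased Mendelian-like segregation.
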