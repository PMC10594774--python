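"""Exhaustive enumeration of valid seeds for short reads.

All valid seeds for a read length are found by extending shorter valid
seeds with a run of zeros and a final 1, pruning candidates whose suffix
seed is not itself valid.  The highest-weight survivors are the design
goal: each extra unit of weight cuts candidate positions four-fold.
"""

from spacedseeds import ValidationSpec, enumerate_valid_seeds, max_weight_seeds

spec = ValidationSpec(n_r=17, n_m=3)
catalog = enumerate_valid_seeds(spec)
print(f"valid seeds of length <= 17 for (17, 3): {len(catalog.entries)}")
print("maximum weight:", catalog.max_w)
for s in max_weight_seeds(spec, pairs=True):
    print(f"  {s}  (w={s.w}, n_s={s.n_s})")
# three seeds up to reversal attain the maximum weight 5; two of them
# satisfy the periodic relation n_r = n_s + T - 1 with a block of size 8.
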