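"""Building maximum-weight lossless seeds for a target read length.

Long seeds are assembled as n_b copies of a periodic block plus its
first n_d elements, under the relation n_r = n_s + T - 1.  Every
assembled seed is re-checked by the full validator before it is
reported.
"""

from spacedseeds import assemble_best_seeds, block_catalogs, min_read_for_weight

catalogs = block_catalogs(n_m=2, T_min=3, T_max=17)
table = assemble_best_seeds(n_r=35, n_m=2, catalogs=catalogs)
print(f"reads of length 35, 2 mismatches: max weight {table.w} "
      f"from block sizes {sorted(table.block_sizes)}")
for s, r in table.entries[:4]:
    print(f"  {s}  (T={r.block.T}, n_b={r.n_b}, n_d={r.n_d})")
# weight 17 is achievable with blocks of four different periods; an
# exhaustive enumeration at this size would be far slower.

n_r, entries = min_read_for_weight(16, 2, catalogs)
s, r = entries[0]
print(f"weight 16 first reachable at n_r={n_r}: {s} "
      f"(block {r.block}, n_b={r.n_b}, n_d={r.n_d})")
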