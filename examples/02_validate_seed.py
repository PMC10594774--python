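"""Deciding whether a seed is lossless for a read length and mismatch budget.

A seed is lossless (full sensitivity) for reads of length n_r with at
most n_m substitutions when every mismatch pattern is avoided by at
least one placement of the seed inside the read.  The validator reports
the verdict and, for an invalid seed, the defeating mismatch positions.
"""

from spacedseeds import (
    ValidationSpec,
    find_defeating_combo,
    is_full_sensitivity,
    min_valid_read_length,
    parse_seed,
)

s = parse_seed("110101011001011")
spec = ValidationSpec(n_r=20, n_m=2)
print(f"{s} valid for (n_r=20, n_m=2)?", is_full_sensitivity(s, spec, method="both"))
combo = find_defeating_combo(s, spec)
print("defeating mismatch positions (1-based):", [i + 1 for i in combo])
# reads of length 20 with substitutions at positions 4 and 13 can evade
# every placement of this seed, so filtration with it would lose hits.

s2 = parse_seed("10001110100100011101")
print(f"{s2} valid for (n_r=30, n_m=3)?",
      is_full_sensitivity(s2, ValidationSpec(30, 3), method="both"))

# audits of well-known seeds: the smallest read length at which each
# becomes lossless for two mismatches
for text in ("111010010100110111", "101100001", "11111"):
    print(f"{text}: lossless from n_r =", min_valid_read_length(parse_seed(text), 2, 80))
# the contiguous weight-5 seed needs q(n_m+1) = 15; the weight-11 spaced
# seed needs 27.
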