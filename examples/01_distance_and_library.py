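"""Distance profiles and the record library on a 25 bp desk example.

A read is compared against every offset of a short reference, first with
all symbols counted and then under a spaced mask; the same reference is
then indexed as a (position, packed seed value) record library and the
read's values are looked up to produce candidate alignment positions.
"""

from spacedseeds import (
    EncodedReference,
    build_library,
    distance_profile,
    encode_value,
    parse_seed,
    search_candidates,
)

x = "CTTGTCGTTGGAGATCGGAAGAGCA"  # reference
y = "TAGGTGCTCG"                 # read

print("all-ones distances :", distance_profile(x, y))
print("masked (1011011111):", distance_profile(x, y, parse_seed("1011011111")))
# the mask ignores two positions, so each masked distance can only drop:
# at offset 8 the count falls from 3 to 1.

print("CTTG packs to", encode_value("CTTG"), "| TAGG packs to", encode_value("TAGG"))

ref = EncodedReference(x)
for mask in ("1111", "101011"):
    lib = build_library(ref, parse_seed(mask))
    report = search_candidates(lib, y)
    print(f"seed {mask}: {len(lib)} records, hit values {report.hit_values}, "
          f"candidate read starts {report.candidates}")
# both seeds have weight 4, but only the spaced one produces candidates
# for this read: {5, 8} (1-based), and offset 8 is the best alignment.
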