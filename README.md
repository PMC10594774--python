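# spacedseeds

Design and audit **lossless (full-sensitivity) spaced seeds** for
substitution-tolerant read mapping.

## The problem

Seed-and-extend aligners index a reference genome as a sorted library of
(position, value) records, where each *value* packs the bases under the
1-elements of a binary mask — a *spaced seed*. A read's values are looked
up to produce candidate alignment positions, which are then verified. Two
forces pull against each other:

* higher seed **weight** `w` (number of 1-elements) cuts the expected
  candidate count, roughly `α (n_r − n_s + 1) / 4^w` for reads of length
  `n_r` and seeds of length `n_s`;
* every 1-element is a position where a substitution (SNP) destroys the
  hit, so heavy seeds risk missing true placements.

A seed has **full sensitivity** for `(n_r, n_m)` when *every* read
placement with at most `n_m` substitutions still yields at least one
exact seed-value hit — FN = 0, sensitivity ≡ 100 %. This package decides
that property, enumerates all such seeds for short reads, and constructs
very long maximum-weight ones from *periodic blocks*: a seed built as
`n_b` copies of a length-`T` block plus its first `n_d` elements is a
candidate lossless seed for reads of length `n_r = n_s + T − 1`, which
reduces the search from `2^{n_r−1}` seeds to a search over length-`T`
cyclic vectors.

## What's inside

| module | contents |
| --- | --- |
| `spacedseeds.seed` | `Seed` type, 0/1 and `#/-` parsing, reversal, subset relation, masked distance profiles |
| `spacedseeds.validate` | row- and column-method full-sensitivity deciders, column reduction, minimum lossless read length |
| `spacedseeds.expand` | exhaustive enumeration of valid seeds by rightward extension with suffix pruning |
| `spacedseeds.blocks` | periodic block validation, rotation/reversal equivalence classes, max-weight block search |
| `spacedseeds.assemble` | periodic seed assembly from block catalogs, per-weight seed tables |
| `spacedseeds.library` | 4-channel reference encoding, record library, candidate search, match counting |
| `spacedseeds.simulate` | synthetic references, planted-mutation reads, sensitivity harness |
| `spacedseeds.cli` | `spacedseeds` command with `validate`, `enumerate`, `gen-blocks`, `assemble`, `search`, `simulate`, … |

## Worked example

```python
from spacedseeds import (
    EncodedReference, ValidationSpec, build_library, distance_profile,
    is_full_sensitivity, parse_seed, search_candidates,
)

x = "CTTGTCGTTGGAGATCGGAAGAGCA"   # reference
y = "TAGGTGCTCG"                  # read

print(distance_profile(x, y))
print(distance_profile(x, y, parse_seed("1011011111")))

lib = build_library(EncodedReference(x), parse_seed("101011"))
report = search_candidates(lib, y)
print(len(lib), report.hit_values, report.candidates)

s = parse_seed("110101011001011")
print(is_full_sensitivity(s, ValidationSpec(n_r=20, n_m=2)))
```

prints

```
(6, 5, 9, 7, 6, 9, 9, 3, 7, 8, 7, 8, 8, 8, 7, 7)
(5, 3, 7, 6, 5, 7, 7, 1, 5, 6, 7, 6, 7, 6, 5, 5)
20 [187, 104, 122] [5, 8]
False
```

Reading the output: aligning the read at offset 8 leaves 3 mismatches,
only 1 of which falls under a 1-element of the mask `1011011111`. The
weight-4 seed `101011` indexes the 25 bp reference into 20 records; the
read hits three packed values and, after shift-correction and range
filtering, positions 5 and 8 (1-based) remain as candidates — offset 8 is
the true best alignment. The last line shows that the weight-8 seed
`110101011001011` is *not* lossless for 20 bp reads with 2 mismatches
(substitutions at positions 4 and 13 defeat every placement).

The `examples/` directory holds one short script per capability —
distance profiles and libraries, validation, enumeration, periodic
blocks, assembly, and the planted-mutation losslessness demonstration —
each printing the numbers it computes with a note on what they mean.

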