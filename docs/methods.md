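# Methods

## Model and definitions

A *spaced seed* `s` is a binary mask of length `n_s` with weight `w`
(count of 1-elements); its first and last elements are 1. Applied at an
offset of a read, the seed selects the `w` bases under its 1-elements;
packed in base 4 (A=0, C=1, G=2, T=3, first covered symbol least
significant) these form the *value* looked up in the reference record
library. The only error type modelled is the substitution (SNP): a read
of length `n_r` differs from its true reference window in at most `n_m`
positions. Insertions, deletions, quality scores and probabilistic
(lossy) sensitivity are out of scope.

`s` is **valid** (full sensitivity, lossless) for `(n_r, n_m)` iff for
every set of `n_m` mismatch positions inside the read, at least one of
the `n_r − n_s + 1` placements of the seed puts 1-elements only on
unmutated positions. Then every alignable read retains at least one
exact value hit, so the candidate list provably contains the true
placement: FN = 0 by construction, not by measurement.

Mismatch budgets larger than the read are truncated: "at most `n_m`
mismatches" is decided with combinations of size `min(n_m, n_r)`. This
keeps validity monotone in `n_r` and anti-monotone in `n_m` on all
inputs, including degenerate ones. `n_m = 0` is accepted and always
valid for `n_s ≤ n_r`.

## Validation

Two deciders are implemented over Python integers as bitsets.

* **Rows.** The seed is shifted by `δ = 0 .. n_r − n_s` and zero-padded
  to `n_r` (first row aligns seed start with read start; each next row
  shifts right by one). A mismatch combination defeats the seed iff every
  row has a 1 on some mismatch position. Enumeration is lexicographic
  with early exit at the first defeating combination, which is also the
  witness reported to the adversarial harness.
* **Columns.** Column `U_t` records which rows place a 1 on read
  position `t`. The seed fails iff some ≤ `n_m` columns OR to the
  saturated all-ones vector. Duplicate columns and columns that are
  subsets of kept columns are removed first — any saturating combination
  survives with supersets substituted — and the search is a DFS that
  skips columns already contained in the running accumulator. The
  "≤ `n_m`" form (rather than exactly `n_m`) is what makes the reduced
  search equivalent to the raw exact-size criterion.

Both deciders are contract-equal on every input; the test suite also
checks them against a third, structurally independent oracle that builds
an actual record library over a random reference and plants a read for
every mismatch combination. Bitsets may be padded to machine width with
1-elements without affecting verdicts; the contract covers the logical
`n_r` positions only.

`min_valid_read_length` scans `n_r` upward from `n_s` (monotonicity makes
the first hit the answer). For a contiguous seed of weight `q` the
closed form `q(n_m + 1)` is recovered exactly.

## Enumeration by extension

All `2^{n_r−1}` candidate seeds arise by appending `0^z 1` to shorter
seeds. Since every subset of a valid seed is valid, a candidate is
validated only if (a) the seed it extends and (b) its maximal proper
suffix-seed are already catalogued. Enumeration proceeds level by level
in length so suffix lookups always hit a completed level. A guard cap
(default 10⁸, configurable) bounds the worst-case candidate count; the
practical limit of this route is `n_r` around 40, which is exactly the
regime the periodic-block route takes over.

## Periodic blocks and assembly

Empirically, maximum-weight seeds for a given `n_r` are almost always
*periodic*: `n_b` copies of a length-`T` block plus the block's first
`n_d` elements, with `n_r = n_s + T − 1` (hence `T ≤ n_r / 2`). A block
is valid for `n_m` iff no `n_m` of its cyclic rotations OR to the
saturated vector; this is necessary for any seed built from it and is
re-verified per assembled seed rather than proven sufficient
analytically.

Block search details:

* every valid block contains a cyclic run of ≥ `n_m` zeros, so
  candidates are generated with the first `n_m` elements forced to 0 and
  the last forced to 1, descending from weight `T − n_m` until a weight
  admits a valid block;
* the first rotation index of a combination may be pinned (any
  saturating combination can be cyclically shifted onto rotation 0), and
  rotations contained in the accumulator are skipped; a `prune=False`
  path runs the plain loop for oracle comparisons;
* rotation+reversal equivalence classes are reported by one canonical
  representative: the member ending in 1 with the longest leading zero
  run, ties broken by lexicographically smallest bit string. The
  published convention for the tie-break is under-specified beyond the
  leading-run stage, so representatives here may differ textually from
  other listings; class counts and weights are representative-invariant,
  and the tests assert those.
* results are independent of how the candidate space is partitioned, so
  the search can be sharded trivially; the in-package implementation is
  serial.

Assembly for a target `n_r` considers every catalogued block size
`T ≤ n_r / 2`, every class member (rotation) whose first and `n_d`-th
elements are 1 (the assembled seed must start and end with 1), expands
`n_s = n_b·T + n_d`, keeps the maximum weight, and re-validates each
survivor with the column method — a re-validation failure is a hard
error, not a filter. Rotations of reversed blocks only produce reversed
seeds and are suppressed by default. Ties are ordered by descending seed
length (longer seeds mean fewer values to look up per read), then by bit
string. Lower-weight blocks are not searched: descending from the top
weight, the first weight admitting a valid block is taken as the block
catalog for that `T`, matching the observation that non-maximum blocks
never assembled heavier seeds.

## Record library and search

References are held as four boolean lanes (one per base; `N` sets no
lane). The library stores one record per window whose seed-covered
symbols are all ACGT, as a value-sorted multimap; multi-sequence
references are concatenated with `N` runs at least a seed length long so
no record spans sources, and reported coordinates are mapped back.
Candidate search packs the read's value at each of the `n_r − n_s + 1`
offsets, shift-corrects hits to the read's first element, discards
starts outside `[1, |ref| − n_r + 1]`, and deduplicates. Match counting
ANDs the lane slices and popcounts the OR of the four intersections, so
`N` never matches; it equals `n_r` minus the all-ones distance wherever
both are defined and `N`-free. Reads containing `N` are skipped by
default, mirroring common practice of dropping such reads. The on-disk
16-bit-chunked index layout used by large-scale implementations is not
reproduced; libraries live in memory at this package's desk scale.

## Synthetic data and what it shows

`make_reference` draws uniform i.i.d. bases; `plant_read` copies a
window and plants exactly `k ≤ n_m` substitutions at distinct positions,
each to a different base. All randomness flows through explicit
`numpy.random.Generator` seeds; there is no global RNG state.

The harness distinguishes two modes deliberately. Random planting over
many trials measures sensitivity (for a validator-approved seed the
result must be *exactly* 100 %, e.g. 1000/1000 recoveries). Random
planting cannot reliably exhibit invalidity — most mismatch placements
are harmless — so the adversarial mode plants substitutions at the
validator's defeating combination, which yields a guaranteed concrete
miss for any rejected seed.

The generator emulates none of the structure of real genomes: no
repeats, no base-composition bias, no `N` tracts, no indels, no
sequencing-error profile. Passing tests therefore demonstrate the
combinatorial guarantee (lossless candidate generation under the
substitution model) and nothing about candidate-count economics on
repetitive real references, where the `α` in the candidate estimate can
vary by orders of magnitude across values.

## Problem sizes and numerical choices

The test and acceptance workloads are chosen at desk scale: exhaustive
three-way validator agreement over all seeds with `n_s ≤ 10`,
`n_r ≤ 14`, `n_m ≤ 2`; block brute-force cross-checks over all `2^T`
vectors for `T ≤ 14`; enumeration at `n_r = 17`; assembly at
`n_r ∈ {35, 43}` with blocks up to `T = 21`; sensitivity at 1000 trials
on a 50 kb reference. These reproduce the published small-scale numbers
exactly while keeping the whole suite under a minute; the same code
paths scale to the published catalog bounds (`n_r ≤ 400`, blocks to
`T = 50`) given proportionally more CPU time, which is a cost statement,
not a correctness one.

Integer bitsets make all validation exact; there is no floating point
anywhere in the deciders. The only floating-point quantity is the
diagnostic candidate estimate `α (n_r − n_s + 1) / 4^w`. Packed values
use int64 when `w ≤ 31` and Python integers beyond.

## Known limitations

* Substitutions only; indel-tolerant and transition-aware seed designs
  are different objects.
* Single seeds only: multiple-seed sets with low overlap complexity are
  not optimised here, though sequential application of single seeds is
  straightforward.
* The enumeration route is exponential and intended for `n_r ≲ 40`; the
  block route covers longer reads but only over the block sizes actually
  catalogued, so reported maxima are maxima over the supplied `T` range.
* Block validity is necessary, not proven sufficient, for seed validity;
  the assembler therefore re-validates every emitted seed (no such
  re-validation has ever failed in testing, but the check is kept hard).
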