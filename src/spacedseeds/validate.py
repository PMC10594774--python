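"""Full-sensitivity (lossless) validation of spaced seeds.

A seed ``s`` of length ``n_s`` is *valid* for reads of length ``n_r``
with at most ``n_m`` substitutions when, for every choice of ``n_m``
mismatch positions inside the read, at least one placement of the seed
within the read avoids all of them with its 1-elements.  A valid seed
guarantees a seed-value hit for every alignable read (zero false
negatives), which is what makes seed-and-extend filtration lossless.

Two equivalent deciders are provided:

* the *row* method: enumerate mismatch combinations and test each of the
  ``n_r - n_s + 1`` zero-padded shift rows ``L_p`` directly;
* the *column* method: build per-position columns ``U_t`` (which shift
  rows cover position ``t``) and ask whether some combination of at most
  ``n_m`` columns ORs to the saturated all-ones vector.  Duplicate and
  subset columns can be dropped without changing the verdict, which
  shrinks the combination space dramatically.

Positions handed to callers (defeating combinations) are 0-based within
this module; the CLI and reports convert to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

from .seed import Seed

__all__ = [
    "ValidationSpec",
    "shift_rows",
    "build_columns",
    "reduce_columns",
    "is_full_sensitivity_rows",
    "is_full_sensitivity_columns",
    "is_full_sensitivity",
    "find_defeating_combo",
    "min_valid_read_length",
]


@dataclass(frozen=True)
class ValidationSpec:
    """Read length and mismatch budget a seed is validated against."""

    n_r: int
    n_m: int

    def __post_init__(self) -> None:
        if self.n_r < 1:
            raise ValueError("read length must be positive")
        if self.n_m < 0:
            raise ValueError("mismatch budget must be non-negative")


def _check_fits(s: Seed, spec: ValidationSpec) -> None:
    if s.n_s > spec.n_r:
        raise ValueError(
            f"seed length {s.n_s} exceeds read length {spec.n_r}"
        )


def shift_rows(s: Seed, n_r: int) -> list[int]:
    """The ``n_r - n_s + 1`` zero-padded placements of the seed in a read.

    Row ``p`` (0-based) is the seed shifted right by ``p`` elements; it is
    returned as an integer whose bit ``i`` is the row's element at read
    position ``i`` (0-based).
    """
    base = 0
    for i, b in enumerate(s.bits):
        if b:
            base |= 1 << i
    return [base << p for p in range(n_r - s.n_s + 1)]


def build_columns(s: Seed, n_r: int) -> list[int]:
    """Per-position columns ``U_t``: which shift rows put a 1 on position t.

    Column ``t`` is an integer whose bit ``p`` is 1 iff shift row ``p``
    has a 1-element at read position ``t``.
    """
    n_rows = n_r - s.n_s + 1
    cols = []
    for t in range(n_r):
        col = 0
        for p in range(n_rows):
            k = t - p
            if 0 <= k < s.n_s and s.bits[k]:
                col |= 1 << p
        cols.append(col)
    return cols


def reduce_columns(cols: list[int]) -> list[int]:
    """Drop duplicate columns and columns that are subsets of another.

    A column ``a`` is a subset of ``b`` when ``a | b == b``; any saturating
    combination using ``a`` still saturates with ``b`` in its place, so the
    validity verdict is unchanged by the reduction.
    """
    kept = sorted(set(cols))
    # a subset has numerically smaller value, so supersets can only follow
    return [
        a
        for i, a in enumerate(kept)
        if not any(a | b == b for b in kept[i + 1:])
    ]


def is_full_sensitivity_rows(s: Seed, spec: ValidationSpec) -> bool:
    """Row-method verdict: every mismatch combination is avoided by a row."""
    _check_fits(s, spec)
    return find_defeating_combo(s, spec) is None


def find_defeating_combo(
    s: Seed, spec: ValidationSpec
) -> Optional[tuple[int, ...]]:
    """First mismatch combination (0-based positions) no shift row avoids.

    Returns ``None`` when the seed is valid.  Enumeration is lexicographic
    over strictly increasing position tuples; the order only affects which
    witness is reported, never the verdict.
    """
    _check_fits(s, spec)
    rows = shift_rows(s, spec.n_r)
    # "at most n_m mismatches": a budget beyond the read length means every
    # position may mismatch, so the combination size caps at n_r
    for combo in combinations(range(spec.n_r), min(spec.n_m, spec.n_r)):
        mask = 0
        for i in combo:
            mask |= 1 << i
        if all(row & mask for row in rows):
            return combo
    return None


def is_full_sensitivity_columns(
    s: Seed, spec: ValidationSpec, reduce: bool = True
) -> bool:
    """Column-method verdict; agrees with the row method on every input.

    The seed fails exactly when some set of at most ``n_m`` (distinct,
    post-reduction) columns ORs to the saturated vector.  ``reduce=False``
    skips duplicate/subset removal and searches the raw columns.
    """
    _check_fits(s, spec)
    n_rows = spec.n_r - s.n_s + 1
    saturated = (1 << n_rows) - 1
    cols = build_columns(s, spec.n_r)
    if reduce:
        cols = reduce_columns(cols)
    cols = sorted(cols, reverse=True)  # try heavy columns first

    def saturates(acc: int, start: int, depth: int) -> bool:
        if acc == saturated:
            return True
        if depth == 0:
            return False
        for i in range(start, len(cols)):
            c = cols[i]
            if acc | c == acc:
                continue  # subset of the accumulator, adds nothing
            if saturates(acc | c, i + 1, depth - 1):
                return True
        return False

    return not saturates(0, 0, min(spec.n_m, spec.n_r))


def is_full_sensitivity(
    s: Seed, spec: ValidationSpec, method: str = "columns"
) -> bool:
    """Dispatch to a validation method: ``rows``, ``columns`` or ``both``.

    ``both`` runs the two deciders and raises if they ever disagree.
    """
    if method == "rows":
        return is_full_sensitivity_rows(s, spec)
    if method == "columns":
        return is_full_sensitivity_columns(s, spec)
    if method == "both":
        r = is_full_sensitivity_rows(s, spec)
        c = is_full_sensitivity_columns(s, spec)
        if r != c:  # pragma: no cover - would indicate an implementation bug
            raise AssertionError(f"row/column methods disagree on {s}")
        return r
    raise ValueError(f"unknown method {method!r}")


def min_valid_read_length(
    s: Seed, n_m: int, n_r_max: int
) -> Optional[int]:
    """Smallest read length in ``[n_s, n_r_max]`` for which ``s`` is valid.

    Validity is monotone in the read length (extra positions only add
    placements), so a linear scan returning the first valid length is
    exact.  Returns ``None`` if the seed is invalid up to ``n_r_max``.
    """
    if n_r_max < s.n_s:
        raise ValueError("n_r_max smaller than the seed length")
    for n_r in range(s.n_s, n_r_max + 1):
        if is_full_sensitivity_columns(s, ValidationSpec(n_r, n_m)):
            return n_r
    return None
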