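"""Spaced seeds and Hamming-style distance profiles.

A spaced seed is a binary mask over read positions: 1-elements are *match*
positions that contribute to the comparison, 0-elements are "don't care".
The number of 1-elements is the *weight* ``w`` and the total number of
elements is the *length* ``n_s``.  A well-formed seed starts and ends with
a 1-element.

Internally all positions are 0-based; anything reported to a user
(candidate positions, mismatch indices, witness shifts in messages) is
1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence, TextIO

__all__ = [
    "Seed",
    "SubsetWitness",
    "parse_seed",
    "reverse_seed",
    "is_subset",
    "distance_profile",
    "write_seed_catalog",
    "read_seed_catalog",
]

_BINARY = frozenset("01")
_HASHDASH = frozenset("#-")


@dataclass(frozen=True)
class Seed:
    """A spaced seed: an immutable binary mask starting and ending in 1."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.bits:
            raise ValueError("empty seed")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("seed bits must be 0 or 1")
        if self.bits[0] != 1 or self.bits[-1] != 1:
            raise ValueError("seed must start and end with a 1-element")

    @property
    def n_s(self) -> int:
        """Seed length (number of all elements)."""
        return len(self.bits)

    @property
    def w(self) -> int:
        """Seed weight (number of 1-elements)."""
        return sum(self.bits)

    @property
    def one_positions(self) -> tuple[int, ...]:
        """0-based indices of the 1-elements, in increasing order."""
        return tuple(i for i, b in enumerate(self.bits) if b)

    def __str__(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def __len__(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class SubsetWitness:
    """Offset placing a smaller seed inside a larger one.

    ``shift`` is the 0-based offset of the smaller seed's first element
    relative to the larger seed's first element such that every 1-element
    of the smaller seed lands on a 1-element of the larger.
    """

    shift: int


def parse_seed(text: str) -> Seed:
    """Parse a seed from 0/1 or #/- notation.

    ``#`` is a match symbol (1) and ``-`` a don't-care (0).  The two
    alphabets may not be mixed.  The canonical text form is 0/1; #/- is
    accepted on input only.
    """
    if not text:
        raise ValueError("empty seed string")
    chars = set(text)
    if chars <= _BINARY:
        bits = tuple(1 if c == "1" else 0 for c in text)
    elif chars <= _HASHDASH:
        bits = tuple(1 if c == "#" else 0 for c in text)
    else:
        raise ValueError(f"seed string mixes alphabets or has bad symbols: {text!r}")
    if bits[0] != 1 or bits[-1] != 1:
        raise ValueError(f"seed must start and end with a match symbol: {text!r}")
    return Seed(bits)


def reverse_seed(s: Seed) -> Seed:
    """Return the seed with the order of its elements reversed."""
    return Seed(s.bits[::-1])


def is_subset(s1: Seed, s2: Seed) -> Optional[SubsetWitness]:
    """Check whether ``s1`` is a subset of ``s2``.

    ``s1`` is a subset of ``s2`` if some alignment places every 1-element
    of ``s1`` on a 1-element of ``s2``.  Returns the witness with the
    smallest shift, or ``None`` if no alignment works.
    """
    if s1.n_s > s2.n_s:
        return None
    m1 = _as_int(s1.bits)
    m2 = _as_int(s2.bits)
    span = s2.n_s - s1.n_s
    for shift in range(span + 1):
        # align s1's first element with s2's element at `shift`
        placed = m1 << (span - shift)
        if placed | m2 == m2:
            return SubsetWitness(shift)
    return None


def _as_int(bits: Sequence[int]) -> int:
    v = 0
    for b in bits:
        v = (v << 1) | b
    return v


def distance_profile(
    x: str, y: str, mask: Optional[Seed] = None
) -> tuple[int, ...]:
    """Masked mismatch counts of ``y`` against every offset of ``x``.

    Entry ``j`` (0-based here; reports elsewhere use 1-based ``j+1``)
    counts the positions where ``x[j + k] != y[k]``, restricted to the
    positions ``k`` where ``mask`` has a 1-element.  ``mask=None`` means
    the all-ones mask of length ``len(y)``.
    """
    if len(y) > len(x):
        raise ValueError("second sequence longer than first")
    if mask is not None and mask.n_s != len(y):
        raise ValueError("mask length must equal the length of the second sequence")
    positions = range(len(y)) if mask is None else mask.one_positions
    m = len(x) - len(y) + 1
    return tuple(
        sum(1 for k in positions if x[j + k] != y[k]) for j in range(m)
    )


def write_seed_catalog(seeds: Iterable[Seed], handle: TextIO) -> None:
    """Write seeds as tab-separated ``<weight>\\t<length>\\t<bits>`` lines."""
    for s in seeds:
        handle.write(f"{s.w}\t{s.n_s}\t{s}\n")


def read_seed_catalog(handle: TextIO) -> Iterator[Seed]:
    """Read a seed catalog written by :func:`write_seed_catalog`.

    Lines starting with ``#`` are comments; blank lines are ignored.
    """
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        s = parse_seed(fields[-1])
        if len(fields) >= 3 and (int(fields[0]), int(fields[1])) != (s.w, s.n_s):
            raise ValueError(f"catalog line disagrees with its seed: {line!r}")
        yield s
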