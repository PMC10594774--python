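"""Periodic blocks: the building unit of long lossless seeds.

A *periodic block* is a length-``T`` binary vector whose ``T`` cyclic
rotations jointly satisfy the validation criterion for ``n_m``
mismatches: no choice of ``n_m`` rotations ORs to the saturated all-ones
vector.  A seed built by repeating a valid block ``n_b`` times plus a
prefix remainder is a candidate lossless seed for reads of length
``n_s + T - 1`` (re-verified seed by seed downstream).

Rotating a block or reversing it preserves validity, so blocks come in
equivalence classes of up to ``2T`` members; one canonical representative
per class is enough.  Every valid block must contain a cyclic run of at
least ``n_m`` zeros, so candidates are generated with the first ``n_m``
elements forced to 0 and the last element forced to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator, Sequence, TextIO

__all__ = [
    "PeriodicBlock",
    "BlockSearchSpec",
    "validate_block",
    "rotations",
    "equivalence_class",
    "canonical_representative",
    "canonical_form",
    "max_weight_blocks",
    "write_block_catalog",
    "read_block_catalog",
]


@dataclass(frozen=True)
class PeriodicBlock:
    """A length-``T`` binary vector intended to tile a periodic seed."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.bits:
            raise ValueError("empty block")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("block bits must be 0 or 1")

    @classmethod
    def from_text(cls, text: str) -> "PeriodicBlock":
        if not text or set(text) - set("01"):
            raise ValueError(f"bad block string {text!r}")
        return cls(tuple(int(c) for c in text))

    @property
    def T(self) -> int:
        return len(self.bits)

    @property
    def n_1(self) -> int:
        """Block weight (number of 1-elements)."""
        return sum(self.bits)

    @property
    def rho(self) -> float:
        """Density: weight per element."""
        return self.n_1 / self.T

    def __str__(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def reverse(self) -> "PeriodicBlock":
        return PeriodicBlock(self.bits[::-1])

    def rotate(self, n: int) -> "PeriodicBlock":
        """Cyclic rotation moving the last ``n`` elements to the front."""
        n %= self.T
        if n == 0:
            return self
        return PeriodicBlock(self.bits[-n:] + self.bits[:-n])


@dataclass(frozen=True)
class BlockSearchSpec:
    """Search space for maximum-weight blocks of size ``T`` at ``n_m``."""

    T: int
    n_m: int
    w_start: int | None = None

    def __post_init__(self) -> None:
        if self.n_m < 1:
            raise ValueError("mismatch budget must be at least 1")
        if self.T < self.n_m + 1:
            raise ValueError("block size must leave room for the zero run and a 1")
        if self.w_start is not None and self.w_start > self.T - self.n_m:
            raise ValueError("initial weight leaves no room for the n_m-zero run")


def _bits_to_int(bits: Sequence[int]) -> int:
    v = 0
    for i, b in enumerate(bits):
        if b:
            v |= 1 << i
    return v


def _rotations_int(mask: int, T: int) -> list[int]:
    full = (1 << T) - 1
    return [((mask << r) | (mask >> (T - r))) & full for r in range(T)]


def validate_block(b: PeriodicBlock, n_m: int, prune: bool = True) -> bool:
    """True iff no ``n_m`` rotations of the block OR to the saturated vector.

    With ``prune=True`` the first rotation index is fixed (any saturating
    combination can be cyclically shifted so its first member is rotation
    0) and rotations already contained in the running accumulator are
    skipped.  ``prune=False`` runs the plain combination loop; both paths
    return identical verdicts.
    """
    if b.T < n_m:
        raise ValueError("block shorter than the mismatch budget")
    T = b.T
    saturated = (1 << T) - 1
    rots = _rotations_int(_bits_to_int(b.bits), T)
    if not prune:
        for combo in combinations(rots, n_m):
            acc = 0
            for r in combo:
                acc |= r
            if acc == saturated:
                return False
        return True

    def saturates(acc: int, start: int, depth: int) -> bool:
        if acc == saturated:
            return True
        if depth == 0:
            return False
        for i in range(start, T):
            r = rots[i]
            if acc | r == acc:
                continue
            if saturates(acc | r, i + 1, depth - 1):
                return True
        return False

    # fixing the first rotation to index 0 loses no saturating combination
    return not saturates(rots[0], 1, n_m - 1)


def rotations(b: PeriodicBlock) -> list[PeriodicBlock]:
    """All ``T`` cyclic rotations of the block (may contain repeats)."""
    return [b.rotate(r) for r in range(b.T)]


def equivalence_class(b: PeriodicBlock) -> list[PeriodicBlock]:
    """Rotations of the block and of its reverse, deduplicated.

    All members are valid or invalid together, for any mismatch budget.
    """
    seen: set[tuple[int, ...]] = set()
    out: list[PeriodicBlock] = []
    for member in (*rotations(b), *rotations(b.reverse())):
        if member.bits not in seen:
            seen.add(member.bits)
            out.append(member)
    return out


def _leading_zero_run(bits: tuple[int, ...]) -> int:
    run = 0
    for x in bits:
        if x:
            break
        run += 1
    return run


def canonical_representative(members: Iterable[PeriodicBlock]) -> PeriodicBlock:
    """Deterministic class representative.

    Among members ending in a 1-element, pick the one with the longest
    leading run of 0-elements; remaining ties are broken by the
    lexicographically smallest bit string.  (The all-zero degenerate class
    has no member ending in 1 and is returned as-is.)  The chosen member
    may differ textually from other published representative conventions;
    class counts and weights do not depend on the choice.
    """
    pool = [m for m in members if m.bits[-1] == 1]
    if not pool:
        return next(iter(members))
    return min(pool, key=lambda m: (-_leading_zero_run(m.bits), m.bits))


def canonical_form(b: PeriodicBlock) -> PeriodicBlock:
    """Canonical representative of the block's own equivalence class."""
    return canonical_representative(equivalence_class(b))


def max_weight_blocks(spec: BlockSearchSpec, guard: int = 10**8) -> list[PeriodicBlock]:
    """All equivalence classes of valid blocks at the maximum weight.

    Candidates have their first ``n_m`` elements forced to 0 and the last
    element forced to 1 (every valid block has a rotation of this shape).
    The search starts at weight ``w_start`` (default ``T - n_m``) and
    decrements until some weight admits a valid block; one canonical
    representative per class is returned, sorted by bit string.
    """
    T, n_m = spec.T, spec.n_m
    free = range(n_m, T - 1)  # positions not forced to 0 (head) or 1 (tail)
    w = spec.w_start if spec.w_start is not None else T - n_m
    while w >= 1:
        n_choose = w - 1
        if n_choose <= len(free):
            if math.comb(len(free), n_choose) > guard:
                raise RuntimeError(
                    f"candidate count for T={T}, w={w} exceeds guard cap {guard}"
                )
            reps: set[tuple[int, ...]] = set()
            for ones in combinations(free, n_choose):
                bits = [0] * T
                for i in ones:
                    bits[i] = 1
                bits[-1] = 1
                cand = PeriodicBlock(tuple(bits))
                if validate_block(cand, n_m):
                    reps.add(canonical_form(cand).bits)
            if reps:
                return [PeriodicBlock(b) for b in sorted(reps)]
        w -= 1
    return []


def write_block_catalog(
    blocks: Sequence[PeriodicBlock], T: int, n_m: int, handle: TextIO
) -> None:
    """Write a per-(T, n_m) block catalog: a header plus one block per line."""
    w = blocks[0].n_1 if blocks else 0
    handle.write(f"# T={T} n_m={n_m} w={w}\n")
    for b in blocks:
        handle.write(f"{b}\n")


def read_block_catalog(handle: TextIO) -> Iterator[PeriodicBlock]:
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        yield PeriodicBlock.from_text(line)
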