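"""Exhaustive enumeration of valid seeds by rightward extension.

Every seed of length ``k + 1 + z`` arises from a valid seed of length
``<= k`` by appending ``z >= 0`` zeros and a final 1-element.  Because any
subset of a valid seed is itself valid, a candidate can be skipped unless
both the seed it extends and its maximal proper suffix-seed (the candidate
with its leading 1 and the following 0s stripped) are already known to be
valid.  This prunes the ``2^(n_r - 1)`` candidate space hard enough to
enumerate everything up to reads of length ~40.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seed import Seed, reverse_seed
from .validate import ValidationSpec, is_full_sensitivity_columns

__all__ = ["SeedCatalog", "CandidateBudgetExceeded", "enumerate_valid_seeds", "max_weight_seeds"]

DEFAULT_GUARD = 10**8


class CandidateBudgetExceeded(RuntimeError):
    """Raised when the projected number of validations exceeds the guard cap."""


@dataclass
class SeedCatalog:
    """All seeds valid for a fixed (n_r, n_m), up to some maximum length."""

    spec: ValidationSpec
    max_len: int
    entries: set[Seed] = field(default_factory=set)

    @property
    def max_w(self) -> int:
        return max(s.w for s in self.entries)

    def by_weight(self, w: int) -> list[Seed]:
        return sorted((s for s in self.entries if s.w == w), key=str)


def _suffix_seed(bits: tuple[int, ...]) -> Seed | None:
    """Strip the leading 1 and following 0s; None if nothing remains."""
    rest = bits[1:]
    while rest and rest[0] == 0:
        rest = rest[1:]
    return Seed(rest) if rest else None


def enumerate_valid_seeds(
    spec: ValidationSpec,
    max_len: int | None = None,
    guard: int = DEFAULT_GUARD,
) -> SeedCatalog:
    """Enumerate every seed of length ``<= max_len`` valid for ``spec``.

    ``max_len`` defaults to ``n_r``.  Raises
    :class:`CandidateBudgetExceeded` if the raw candidate count
    ``2^(max_len - 1)`` exceeds ``guard`` (the pruned search examines far
    fewer, but the cap bounds the worst case a caller signs up for).
    """
    if max_len is None:
        max_len = spec.n_r
    if max_len > spec.n_r:
        raise ValueError("max_len may not exceed the read length")
    if max_len >= 1 and 2 ** (max_len - 1) > guard:
        raise CandidateBudgetExceeded(
            f"up to 2^{max_len - 1} candidates exceeds the guard cap {guard}"
        )
    catalog = SeedCatalog(spec=spec, max_len=max_len)
    one = Seed((1,))
    if not (max_len >= 1 and is_full_sensitivity_columns(one, spec)):
        return catalog
    catalog.entries.add(one)
    # grow length by length so suffix lookups always hit a finished level
    by_len: dict[int, list[Seed]] = {1: [one]}
    for length in range(2, max_len + 1):
        found: list[Seed] = []
        for base_len in range(1, length):
            for base in by_len.get(base_len, ()):
                bits = base.bits + (0,) * (length - base_len - 1) + (1,)
                suffix = _suffix_seed(bits)
                if suffix is not None and suffix not in catalog.entries:
                    continue
                cand = Seed(bits)
                if is_full_sensitivity_columns(cand, spec):
                    found.append(cand)
        by_len[length] = found
        catalog.entries.update(found)
    return catalog


def max_weight_seeds(
    spec: ValidationSpec,
    max_len: int | None = None,
    pairs: bool = False,
    guard: int = DEFAULT_GUARD,
) -> list[Seed]:
    """All valid seeds attaining the maximum weight for ``spec``.

    With ``pairs=True`` the list is deduplicated up to reversal, keeping
    the lexicographically smaller member of each seed/reverse pair
    (palindromic seeds count once).
    """
    catalog = enumerate_valid_seeds(spec, max_len=max_len, guard=guard)
    if not catalog.entries:
        return []
    best = catalog.by_weight(catalog.max_w)
    if not pairs:
        return best
    out = []
    seen: set[Seed] = set()
    for s in best:
        r = reverse_seed(s)
        if r in seen:
            continue
        seen.add(s)
        out.append(s)
    return out
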