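"""Assemble maximum-weight periodic seeds from block catalogs.

A periodic seed for reads of length ``n_r`` is built from a block of size
``T`` as ``n_b`` whole copies followed by the first ``n_d`` elements of
the block, with

    n_s = n_b * T + n_d        and        n_r = n_s + T - 1,

which forces ``n_b >= 1``, ``1 <= n_d < T`` and hence ``T <= n_r / 2``.
For each catalogued block every rotation whose first element and
``n_d``-th element are both 1 (so the assembled seed starts and ends with
a 1-element) yields one candidate seed.  Candidates are re-checked with
the full validator before they are reported; the block criterion is
necessary but the per-seed re-verification is what the emitted table
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .blocks import BlockSearchSpec, PeriodicBlock, max_weight_blocks, read_block_catalog, rotations, write_block_catalog
from .seed import Seed
from .validate import ValidationSpec, is_full_sensitivity_columns

__all__ = [
    "PeriodicSeedRecipe",
    "SeedTable",
    "expand_recipe",
    "block_catalogs",
    "load_block_catalogs",
    "save_block_catalogs",
    "assemble_best_seeds",
    "min_read_for_weight",
]


@dataclass(frozen=True)
class PeriodicSeedRecipe:
    """(block, n_b, n_d) expansion defining a periodic seed."""

    block: PeriodicBlock
    n_b: int
    n_d: int

    def __post_init__(self) -> None:
        if self.n_b < 1:
            raise ValueError("need at least one whole block")
        if not 1 <= self.n_d < self.block.T:
            raise ValueError("remainder length must be in [1, T - 1]")
        if self.block.bits[0] != 1:
            raise ValueError("chosen block rotation must start with a 1-element")
        if self.block.bits[self.n_d - 1] != 1:
            raise ValueError("the n_d-th block element must be a 1-element")

    @property
    def n_s(self) -> int:
        return self.n_b * self.block.T + self.n_d

    @property
    def n_r(self) -> int:
        """The read length this recipe targets: ``n_s + T - 1``."""
        return self.n_s + self.block.T - 1


@dataclass
class SeedTable:
    """Max-weight seeds (with recipes) assembled for one (n_r, n_m)."""

    n_r: int
    n_m: int
    w: int
    entries: list[tuple[Seed, PeriodicSeedRecipe]]

    @property
    def block_sizes(self) -> set[int]:
        return {r.block.T for _, r in self.entries}


def expand_recipe(r: PeriodicSeedRecipe) -> Seed:
    """Materialize the seed: ``n_b`` block copies plus the n_d-prefix."""
    bits = r.block.bits * r.n_b + r.block.bits[: r.n_d]
    return Seed(bits)


def block_catalogs(
    n_m: int, T_min: int, T_max: int
) -> dict[int, list[PeriodicBlock]]:
    """Generate max-weight block catalogs for every T in [T_min, T_max]."""
    return {
        T: max_weight_blocks(BlockSearchSpec(T=T, n_m=n_m))
        for T in range(max(T_min, n_m + 1), T_max + 1)
    }


def save_block_catalogs(
    catalogs: Mapping[int, Sequence[PeriodicBlock]], n_m: int, directory: Path
) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    for T, blocks in catalogs.items():
        with open(directory / f"blocks_T{T}_m{n_m}.txt", "w") as fh:
            write_block_catalog(list(blocks), T, n_m, fh)


def load_block_catalogs(directory: Path) -> dict[int, list[PeriodicBlock]]:
    out: dict[int, list[PeriodicBlock]] = {}
    for path in sorted(Path(directory).glob("blocks_T*_m*.txt")):
        with open(path) as fh:
            blocks = list(read_block_catalog(fh))
        if blocks:
            out[blocks[0].T] = blocks
    return out


def _candidate_recipes(
    block: PeriodicBlock, n_r: int, include_reverse: bool
) -> list[PeriodicSeedRecipe]:
    T = block.T
    n_s = n_r - T + 1
    n_b, n_d = divmod(n_s, T)
    if n_b < 1 or n_d == 0:
        return []
    sources = [block, block.reverse()] if include_reverse else [block]
    out = []
    seen: set[tuple[int, ...]] = set()
    for src in sources:
        for rot in rotations(src):
            if rot.bits[0] == 1 and rot.bits[n_d - 1] == 1 and rot.bits not in seen:
                seen.add(rot.bits)
                out.append(PeriodicSeedRecipe(block=rot, n_b=n_b, n_d=n_d))
    return out


def assemble_best_seeds(
    n_r: int,
    n_m: int,
    catalogs: Mapping[int, Sequence[PeriodicBlock]],
    include_reverse: bool = False,
) -> SeedTable:
    """Max-weight periodic seeds for reads of length ``n_r`` at ``n_m``.

    ``catalogs`` maps block size T to its max-weight blocks; sizes above
    ``n_r // 2`` are ignored (the block relation cannot hold for them).
    Rotations of reversed blocks only produce the reverses of seeds built
    from the original block, so they are suppressed unless
    ``include_reverse`` is set.  Every candidate achieving the maximum
    weight is re-verified by the full validator; a failure raises, since
    it would mean the block criterion and the validator disagree.
    """
    if not catalogs:
        raise ValueError("no block catalogs supplied")
    spec = ValidationSpec(n_r, n_m)
    candidates: list[tuple[Seed, PeriodicSeedRecipe]] = []
    for T, blocks in catalogs.items():
        if T > n_r // 2:
            continue
        for block in blocks:
            for recipe in _candidate_recipes(block, n_r, include_reverse):
                candidates.append((expand_recipe(recipe), recipe))
    if not candidates:
        raise ValueError(
            f"no block of size <= {n_r // 2} in the catalogs fits n_r={n_r}"
        )
    best_w = max(s.w for s, _ in candidates)
    entries = []
    seen: set[tuple[int, ...]] = set()
    for s, recipe in candidates:
        if s.w != best_w or s.bits in seen:
            continue
        if not is_full_sensitivity_columns(s, spec):
            raise AssertionError(
                f"assembled seed {s} failed re-validation at (n_r={n_r}, n_m={n_m})"
            )
        seen.add(s.bits)
        entries.append((s, recipe))
    entries.sort(key=lambda e: (-e[0].n_s, str(e[0])))
    return SeedTable(n_r=n_r, n_m=n_m, w=best_w, entries=entries)


def min_read_for_weight(
    w: int,
    n_m: int,
    catalogs: Mapping[int, Sequence[PeriodicBlock]],
    n_r_max: int = 400,
) -> tuple[int, list[tuple[Seed, PeriodicSeedRecipe]]]:
    """Smallest read length whose assembled max weight reaches ``w``.

    Returns that ``n_r`` together with its weight-``w`` seeds of maximal
    length (the longest-seed rows of a per-weight seed table).  Only block
    sizes present in ``catalogs`` are considered.  Raises ``LookupError``
    if the weight is not reached by ``n_r_max``.
    """
    T_lo = min(catalogs)
    for n_r in range(2 * T_lo, n_r_max + 1):
        try:
            table = assemble_best_seeds(n_r, n_m, catalogs)
        except ValueError:
            continue
        if table.w >= w:
            at_w = [(s, r) for s, r in table.entries if s.w == w]
            if not at_w:  # max weight overshot w at the first feasible n_r
                at_w = table.entries
            longest = max(s.n_s for s, _ in at_w)
            return n_r, [(s, r) for s, r in at_w if s.n_s == longest]
    raise LookupError(f"weight {w} not reachable for reads up to {n_r_max}")
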