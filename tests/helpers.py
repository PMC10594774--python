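"""Shared test utilities: exhaustive seed generation and brute-force oracles."""

from __future__ import annotations

from itertools import combinations, product

from spacedseeds import Seed
from spacedseeds.blocks import PeriodicBlock, canonical_form, validate_block


def all_seeds(max_len: int):
    """Every well-formed seed (first/last element 1) of length <= max_len."""
    yield Seed((1,))
    for length in range(2, max_len + 1):
        for mid in product((0, 1), repeat=length - 2):
            yield Seed((1,) + mid + (1,))


def brute_max_weight_blocks(T: int, n_m: int) -> tuple[int, int]:
    """(max weight, class count) over ALL 2^T binary vectors, unpruned checks."""
    best_w, reps = -1, set()
    for v in range(1, 1 << T):
        bits = tuple((v >> i) & 1 for i in range(T))
        w = sum(bits)
        if w < best_w:
            continue
        b = PeriodicBlock(bits)
        if validate_block(b, n_m, prune=False):
            if w > best_w:
                best_w, reps = w, set()
            reps.add(canonical_form(b).bits)
    return best_w, len(reps)
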