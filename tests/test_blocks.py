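"""Periodic block validation, equivalence classes, and the max-weight search."""

import numpy as np
import pytest

from helpers import brute_max_weight_blocks
from spacedseeds import (
    BlockSearchSpec,
    PeriodicBlock,
    ValidationSpec,
    canonical_form,
    canonical_representative,
    equivalence_class,
    is_full_sensitivity_columns,
    max_weight_blocks,
    validate_block,
)
from spacedseeds.assemble import assemble_best_seeds
from spacedseeds.blocks import read_block_catalog, rotations, write_block_catalog

T11_M2_BLOCKS = [
    "00011011111",
    "00101011111",
    "00101110111",
    "00101111011",
    "00110101111",
]


def random_blocks(rng, n, t_range=(4, 14)):
    out = []
    for _ in range(n):
        T = int(rng.integers(*t_range))
        bits = tuple(int(b) for b in rng.integers(0, 2, size=T))
        out.append(PeriodicBlock(bits if any(bits) else bits[:-1] + (1,)))
    return out


@pytest.mark.parametrize("text", T11_M2_BLOCKS)
def test_known_valid_blocks_for_T11_m2(text):
    assert validate_block(PeriodicBlock.from_text(text), 2)


def test_block_behind_the_length35_seed_is_valid():
    assert validate_block(PeriodicBlock.from_text("1011100"), 2)


def test_all_ones_block_is_invalid():
    assert not validate_block(PeriodicBlock.from_text("1111"), 1)


def test_prune_and_noprune_verdicts_agree():
    rng = np.random.default_rng(23)
    for b in random_blocks(rng, 200):
        for n_m in (1, 2, 3):
            if b.T >= n_m:
                assert validate_block(b, n_m, prune=True) == validate_block(b, n_m, prune=False)


def test_equivalence_class_members_and_size():
    b = PeriodicBlock.from_text("1011101001000100111000011010100010101")
    members = equivalence_class(b)
    assert len(members) <= 2 * b.T
    assert all(m.n_1 == b.n_1 for m in members)
    # symmetric blocks collapse below the 2T bound
    small = equivalence_class(PeriodicBlock.from_text("00101101"))
    assert len(small) < 16


def test_validity_is_constant_across_equivalence_class():
    rng = np.random.default_rng(31)
    for b in random_blocks(rng, 100, t_range=(4, 11)):
        for n_m in (2, 3):
            if b.T < n_m:
                continue
            verdicts = {validate_block(m, n_m) for m in equivalence_class(b)}
            assert len(verdicts) == 1


def test_canonical_representative_is_deterministic_and_idempotent():
    b = PeriodicBlock.from_text("00011011111")
    rep = canonical_form(b)
    assert canonical_form(rep) == rep
    assert canonical_form(b.reverse()) == rep
    # representative exposes the longest leading zero run in the class
    lead = max(
        len(str(m)) - len(str(m).lstrip("0"))
        for m in equivalence_class(b)
        if m.bits[-1] == 1
    )
    assert str(rep).startswith("0" * lead)
    single = PeriodicBlock.from_text("1")
    assert canonical_representative([single]) == single


def test_rotation_moves_tail_to_front():
    b = PeriodicBlock.from_text("1011100")
    assert str(b.rotate(2)) == "0010111"
    assert {str(r) for r in rotations(b)} == {str(b.rotate(i)) for i in range(7)}


def test_max_weight_blocks_T11_m2():
    blocks = max_weight_blocks(BlockSearchSpec(T=11, n_m=2))
    assert [str(b) for b in blocks] == T11_M2_BLOCKS
    assert all(b.n_1 == 7 for b in blocks)


def test_max_weight_blocks_T25_m2_weight_19():
    blocks = max_weight_blocks(BlockSearchSpec(T=25, n_m=2))
    assert blocks and blocks[0].n_1 == 19


def test_minimal_block_size_gives_weight_one():
    for n_m in (1, 2, 3):
        blocks = max_weight_blocks(BlockSearchSpec(T=n_m + 1, n_m=n_m))
        assert [b.n_1 for b in blocks] == [1]


def test_search_agrees_with_brute_force_at_small_T():
    for T in (5, 7, 9, 11):
        for n_m in (2, 3):
            if T < n_m + 1:
                continue
            bw, nclasses = brute_max_weight_blocks(T, n_m)
            found = max_weight_blocks(BlockSearchSpec(T=T, n_m=n_m))
            assert (found[0].n_1, len(found)) == (bw, nclasses)


def test_no_valid_blocks_above_the_maximum_weight():
    # weight-monotone impossibility, checked directly above the found maximum
    blocks = max_weight_blocks(BlockSearchSpec(T=11, n_m=2))
    w_max = blocks[0].n_1
    assert max_weight_blocks(BlockSearchSpec(T=11, n_m=2, w_start=w_max)) == blocks
    from itertools import combinations

    free = range(2, 10)
    for ones in combinations(free, w_max):  # one more 1 than the maximum
        bits = [0] * 11
        for i in ones:
            bits[i] = 1
        bits[-1] = 1
        assert not validate_block(PeriodicBlock(tuple(bits)), 2)


def test_lower_weight_block_outside_the_clearing_closure():
    # 00010110111 (w=6) is valid yet cannot be reached from any w=7 block
    # by clearing a single 1-element
    b = PeriodicBlock.from_text("00010110111")
    assert validate_block(b, 2)
    reachable = set()
    for text in T11_M2_BLOCKS:
        top = PeriodicBlock.from_text(text)
        for member in equivalence_class(top):
            for i, bit in enumerate(member.bits):
                if bit:
                    cleared = list(member.bits)
                    cleared[i] = 0
                    reachable.add(canonical_form(PeriodicBlock(tuple(cleared))).bits)
    assert canonical_form(b).bits not in reachable


def test_seed_from_invalid_block_is_invalid():
    # block validity is necessary for the seed built from it
    rng = np.random.default_rng(41)
    checked = 0
    for b in random_blocks(rng, 300, t_range=(4, 9)):
        if validate_block(b, 2) or b.bits[0] != 1:
            continue
        n_b, n_d = 2, 1
        if b.bits[n_d - 1] != 1:
            continue
        from spacedseeds import Seed

        seed = Seed(b.bits * n_b + b.bits[:n_d])
        n_r = seed.n_s + b.T - 1
        assert not is_full_sensitivity_columns(seed, ValidationSpec(n_r, 2))
        checked += 1
    assert checked >= 20


def test_infeasible_spec_rejected():
    with pytest.raises(ValueError):
        BlockSearchSpec(T=2, n_m=2)
    with pytest.raises(ValueError):
        BlockSearchSpec(T=8, n_m=2, w_start=7)


def test_block_catalog_roundtrip(tmp_path):
    blocks = max_weight_blocks(BlockSearchSpec(T=11, n_m=2))
    path = tmp_path / "blocks_T11_m2.txt"
    with open(path, "w") as fh:
        write_block_catalog(blocks, 11, 2, fh)
    text = path.read_text()
    assert text.startswith("# T=11 n_m=2 w=7\n")
    with open(path) as fh:
        assert list(read_block_catalog(fh)) == blocks
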