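"""Record library construction, candidate search, and match counting."""

import numpy as np
import pytest

from spacedseeds import (
    EncodedReference,
    build_library,
    count_matches,
    distance_profile,
    encode_value,
    estimate_candidates,
    parse_seed,
    reverse_complement,
    search_candidates,
)
from spacedseeds.library import score_candidates
from spacedseeds.simulate import make_reference

X = "CTTGTCGTTGGAGATCGGAAGAGCA"
Y = "TAGGTGCTCG"


@pytest.mark.parametrize(
    "symbols, value", [("CTTG", 189), ("AAAA", 0), ("TAGG", 163)]
)
def test_encode_value(symbols, value):
    assert encode_value(symbols) == value


def test_encode_value_rejects_n():
    with pytest.raises(ValueError):
        encode_value("ACGN")


def test_reference_lanes_are_disjoint_and_cover_non_n():
    ref = EncodedReference("CATAGNCACGT")
    assert ref.lanes.sum(axis=0).max() == 1
    assert list(ref.lanes.any(axis=0)) == [c != "N" for c in ref.sequence]


def test_contiguous_seed_library_has_22_records():
    lib = build_library(EncodedReference(X), parse_seed("1111"))
    assert len(lib) == 22
    assert lib.positions(189) == [1]  # CTTG at position 1
    assert lib.records[0].value == min(r.value for r in lib.records)


def test_spaced_seed_library_has_20_records():
    lib = build_library(EncodedReference(X), parse_seed("101011"))
    assert len(lib) == 20
    assert lib.positions(187) == [5]
    assert lib.positions(104) == [19]
    assert lib.positions(122) == [11]


def test_windows_with_n_under_match_positions_are_excluded():
    lib = build_library(EncodedReference("ACNGTAC"), parse_seed("101"))
    # the N at 0-based index 2 kills the windows starting at positions 1 and
    # 3; at position 2 it sits under the seed's 0-element, so that window stays
    assert sorted(r.key for r in lib.records) == [2, 4, 5]


def test_library_size_bound():
    rng_ref = make_reference(200, 9)
    s = parse_seed("1011")
    lib = build_library(EncodedReference(rng_ref), s)
    assert len(lib) == 200 - s.n_s + 1  # equality: no N anywhere


def test_search_worked_example_spaced_seed():
    lib = build_library(EncodedReference(X), parse_seed("101011"))
    report = search_candidates(lib, Y)
    assert report.hit_values == [187, 104, 122]
    assert report.candidates == [5, 8]  # raw hits {5, 18, 8}; 18 out of range


def test_search_worked_example_contiguous_seed_finds_nothing():
    lib = build_library(EncodedReference(X), parse_seed("1111"))
    assert search_candidates(lib, Y).candidates == []


def test_exact_window_always_a_candidate():
    ref = make_reference(500, 21)
    s = parse_seed("1100110011")
    lib = build_library(EncodedReference(ref), s)
    for start in (1, 57, 471):
        read = ref[start - 1 : start - 1 + 30]
        assert start in search_candidates(lib, read).candidates


def test_count_matches_32mer_example():
    m1 = "CATAGNCACGTGATCCTAGNCATGTTACCTGT"
    m2 = "GCCTCAGTTTTCACTCTATCAATATGTAATAA"
    assert count_matches(EncodedReference(m1), m2, 1) == 9


def test_count_matches_identity_and_bounds():
    seq = "ACGT" * 8
    ref = EncodedReference(seq)
    assert count_matches(ref, seq, 1) == 32
    with pytest.raises(ValueError):
        count_matches(ref, seq, 2)


def test_count_matches_complements_distance_profile():
    ref = EncodedReference(X)
    for pos in (5, 8):
        d = distance_profile(X, Y)[pos - 1]
        assert count_matches(ref, Y, pos) == len(Y) - d


def test_score_candidates_best_positions():
    lib = build_library(EncodedReference(X), parse_seed("101011"))
    report = score_candidates(EncodedReference(X), Y, search_candidates(lib, Y))
    assert report.best_count == len(Y) - 3  # d_8 = 3 is the best alignment
    assert report.best_positions == [8]


@pytest.mark.parametrize(
    "read, rc", [("ATCCCAAAGTGCTTT", "AAAGCACTTTGGGAT"), ("A", "T"), ("NAC", "GTN")]
)
def test_reverse_complement(read, rc):
    assert reverse_complement(read) == rc


def test_reverse_complement_involution_and_errors():
    rng = np.random.default_rng(2)
    for _ in range(20):
        seq = make_reference(int(rng.integers(1, 60)), rng)
        assert reverse_complement(reverse_complement(seq)) == seq
    with pytest.raises(ValueError):
        reverse_complement("ACGU")


def test_multi_sequence_references_never_share_records():
    s = parse_seed("1111")
    ref = EncodedReference.concatenate([("a", "ACGTACGT"), ("b", "TTTTGGGG")], gap=s.n_s)
    lib = build_library(ref, s)
    for rec in lib.records:
        name, pos = ref.to_source(rec.key)
        assert 1 <= pos <= 8 - s.n_s + 1 + 4  # record lies inside one source
    assert ref.to_source(1) == ("a", 1)
    assert ref.to_source(8 + s.n_s + 1) == ("b", 1)


def test_estimate_candidates_scaling():
    assert estimate_candidates(4**5, 30, 30, 5) == 1.0
    base = estimate_candidates(1000.0, 50, 21, 8)
    assert estimate_candidates(1000.0, 50, 21, 9) == pytest.approx(base / 4)
    with pytest.raises(ValueError):
        estimate_candidates(-1.0, 30, 20, 4)


def test_estimate_tracks_empirical_candidate_counts():
    # random reads against a random reference: the mean candidate count
    # should track alpha * (n_r - n_s + 1) / 4^w within a small factor
    ref_seq = make_reference(100_000, 77)
    ref = EncodedReference(ref_seq)
    rng = np.random.default_rng(78)
    n_r = 36
    for text in ("111010111", "11011011011", "1101101101111"):
        s = parse_seed(text)
        lib = build_library(ref, s)
        alpha = len(lib)
        expect = estimate_candidates(alpha, n_r, s.n_s, s.w)
        n_reads = 400
        total = 0
        for _ in range(n_reads):
            read = make_reference(n_r, rng)
            total += len(search_candidates(lib, read).candidates)
        mean = total / n_reads
        assert mean <= 3 * expect + 0.05
        assert mean >= expect / 3 - 0.05
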