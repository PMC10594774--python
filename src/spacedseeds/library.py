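"""Seed-and-extend demonstrator: record library, candidate search, match counting.

The reference is held in a 2-bit-style encoding: one boolean lane per
base letter (A, C, G, T), with ``N`` setting no lane.  A *record* pairs a
1-based reference position ("key") with the packed base-4 integer
("value") of the ``w`` symbols under the seed's 1-elements; windows with
an ``N`` under a 1-element produce no record.  Looking up the values of a
read at every admissible seed offset, shift-correcting the hits to the
read's first element and deduplicating yields the candidate positions
that a downstream aligner would verify — for a seed valid at
``(n_r, n_m)`` this candidate list provably contains every placement with
at most ``n_m`` substitutions.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .seed import Seed

__all__ = [
    "ALPHABET",
    "EncodedReference",
    "Record",
    "RecordLibrary",
    "CandidateReport",
    "encode_value",
    "build_library",
    "search_candidates",
    "score_candidates",
    "count_matches",
    "reverse_complement",
    "estimate_candidates",
]

ALPHABET = "ACGTN"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_N = {**_CODE, "N": -1}


def encode_value(symbols: str) -> int:
    """Pack bases as a little-endian base-4 integer (first symbol least significant).

    ``A=0, C=1, G=2, T=3``; e.g. ``CTTG`` packs to ``1 + 4*3 + 16*3 + 64*2``.
    """
    value = 0
    for k, c in enumerate(reversed(symbols)):
        if c not in _CODE:
            raise ValueError(f"cannot encode symbol {c!r}")
        value = value * 4 + _CODE[c]
    return value


class EncodedReference:
    """A reference sequence with per-base boolean match lanes.

    Multiple source sequences are concatenated with runs of ``N`` (at
    least the seed length used downstream) so that no record can span two
    sources; :meth:`to_source` maps concatenated coordinates back.
    """

    def __init__(self, sequence: str, name: str = "ref"):
        self.sequence = sequence.upper()
        if set(self.sequence) - set(ALPHABET):
            bad = sorted(set(self.sequence) - set(ALPHABET))
            raise ValueError(f"reference contains non-ACGTN symbols: {bad}")
        self.names = [name]
        self.starts = [0]  # 0-based start of each source in the concatenation
        codes = np.frombuffer(self.sequence.encode(), dtype=np.uint8)
        self.codes = np.full(len(codes), -1, dtype=np.int8)
        for base, code in _CODE.items():
            self.codes[codes == ord(base)] = code
        # 4-channel lanes: lanes[c, i] == True iff base c at position i
        self.lanes = np.stack([self.codes == c for c in range(4)])

    @classmethod
    def concatenate(
        cls, records: Iterable[tuple[str, str]], gap: int
    ) -> "EncodedReference":
        """Join named sequences with ``gap`` N symbols between them."""
        names, seqs = zip(*records)
        ref = cls(("N" * gap).join(s.upper() for s in seqs), name=names[0])
        ref.names = list(names)
        starts, pos = [], 0
        for s in seqs:
            starts.append(pos)
            pos += len(s) + gap
        ref.starts = starts
        return ref

    def __len__(self) -> int:
        return len(self.sequence)

    def to_source(self, position: int) -> tuple[str, int]:
        """Map a 1-based concatenated position to (source name, 1-based position)."""
        i = max(0, bisect_right(self.starts, position - 1) - 1)
        return self.names[i], position - self.starts[i]


@dataclass(frozen=True)
class Record:
    """One library record: 1-based position and packed seed value."""

    key: int
    value: int


class RecordLibrary:
    """Sorted multimap from packed seed values to 1-based reference positions."""

    def __init__(self, ref: EncodedReference, seed: Seed):
        self.ref = ref
        self.seed = seed
        offsets = np.array(seed.one_positions)
        n = len(ref) - seed.n_s + 1
        self._by_value: dict[int, list[int]] = {}
        self.records: list[Record] = []
        if n <= 0:
            return
        window = ref.codes[np.arange(n)[:, None] + offsets[None, :]]
        valid = (window >= 0).all(axis=1)
        # 4**w fits int64 up to w == 31; fall back to Python ints beyond
        dtype = np.int64 if len(offsets) <= 31 else object
        powers = 4 ** np.arange(len(offsets), dtype=dtype)
        values = (window.astype(dtype) * powers).sum(axis=1)
        for i in np.flatnonzero(valid):
            v = int(values[i])
            self._by_value.setdefault(v, []).append(int(i) + 1)
        self.records = sorted(
            (Record(k, v) for v, keys in self._by_value.items() for k in keys),
            key=lambda r: (r.value, r.key),
        )

    def __len__(self) -> int:
        return len(self.records)

    def positions(self, value: int) -> list[int]:
        """1-based reference positions whose packed seed value is ``value``."""
        return self._by_value.get(value, [])


def build_library(ref: EncodedReference, seed: Seed) -> RecordLibrary:
    """One record per reference window whose seed-covered symbols are all ACGT."""
    return RecordLibrary(ref, seed)


@dataclass
class CandidateReport:
    """Candidate positions for one read, with optional match bookkeeping."""

    read_id: str
    candidates: list[int]
    hit_values: list[int] = field(default_factory=list)
    best_count: Optional[int] = None
    best_positions: list[int] = field(default_factory=list)


def search_candidates(
    lib: RecordLibrary,
    read: str,
    read_id: str = "read",
    skip_n: bool = True,
) -> CandidateReport:
    """Candidate start positions (1-based, deduplicated) for a read.

    For each of the ``n_r - n_s + 1`` read offsets the packed value is
    looked up in the library; hits are shift-corrected to the read's
    first element and starts that would push the read beyond the
    reference are discarded.  Offsets whose window contains ``N`` are
    skipped (with ``skip_n=False`` they are still skipped, as an N value
    cannot be packed; the flag exists to reject such reads outright).
    """
    read = read.upper()
    seed = lib.seed
    n_r = len(read)
    if seed.n_s > n_r:
        raise ValueError("seed longer than the read")
    if not skip_n and "N" in read:
        raise ValueError(f"read {read_id} contains N")
    max_start = len(lib.ref) - n_r + 1
    hits: set[int] = set()
    values: list[int] = []
    for delta in range(n_r - seed.n_s + 1):
        symbols = "".join(read[delta + k] for k in seed.one_positions)
        if "N" in symbols:
            continue
        value = encode_value(symbols)
        keys = lib.positions(value)
        if keys:
            values.append(value)
        for key in keys:
            start = key - delta  # 1-based start of the read
            if 1 <= start <= max_start:
                hits.add(start)
    return CandidateReport(
        read_id=read_id, candidates=sorted(hits), hit_values=values
    )


def count_matches(ref: EncodedReference, read: str, pos: int) -> int:
    """Matching symbols when the read is placed at 1-based position ``pos``.

    Computed the 4-channel way: AND each base lane of the reference slice
    with the read's lane, OR the four intersections, and count the set
    bits.  ``N`` on either side sets no lane, so it never matches.
    """
    read = read.upper()
    if pos < 1 or pos - 1 + len(read) > len(ref):
        raise ValueError(f"placement at {pos} is out of the reference range")
    codes = np.array([_CODE_N.get(c, -1) for c in read], dtype=np.int8)
    slice_lanes = ref.lanes[:, pos - 1 : pos - 1 + len(read)]
    agree = np.zeros(len(read), dtype=bool)
    for c in range(4):
        agree |= slice_lanes[c] & (codes == c)
    return int(agree.sum())


def score_candidates(
    ref: EncodedReference, read: str, report: CandidateReport
) -> CandidateReport:
    """Fill in the best match count and its positions for a candidate report."""
    best, best_pos = -1, []
    for pos in report.candidates:
        m = count_matches(ref, read, pos)
        if m > best:
            best, best_pos = m, [pos]
        elif m == best:
            best_pos.append(pos)
    report.best_count = None if best < 0 else best
    report.best_positions = best_pos
    return report


def reverse_complement(read: str) -> str:
    """Reverse-complement over {A, C, G, T, N} (N maps to N)."""
    read = read.upper()
    if set(read) - set(ALPHABET):
        raise ValueError("sequence contains non-ACGTN symbols")
    return str(Seq(read).reverse_complement())


def estimate_candidates(alpha: float, n_r: int, n_s: int, w: int) -> float:
    """Expected candidate count ``alpha * (n_r - n_s + 1) / 4**w``.

    ``alpha`` is the library-density constant of the reference (about its
    length for a random sequence).  Diagnostic only: each extra unit of
    seed weight divides the estimate by 4.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n_s > n_r:
        raise ValueError("seed longer than the read")
    return alpha * (n_r - n_s + 1) / 4**w
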