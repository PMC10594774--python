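"""Synthetic references, planted-mutation reads, and the sensitivity harness.

The generator emulates the setting the seed-design guarantees speak to:
a uniform i.i.d. reference over {A, C, G, T}, and reads copied from a
reference window with exactly ``k`` substitutions planted at distinct
positions (each substituted base differs from the original).  Random
planting measures sensitivity; *adversarial* planting puts the
substitutions at a defeating mismatch combination reported by the
validator, which is the only reliable way to exhibit a miss for an
invalid seed.

All randomness flows through explicit ``numpy.random.Generator`` seeds;
there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .library import EncodedReference, build_library, search_candidates
from .seed import Seed
from .validate import ValidationSpec, find_defeating_combo

__all__ = [
    "PlantedTrial",
    "SensitivitySummary",
    "make_reference",
    "plant_read",
    "sensitivity_experiment",
    "adversarial_trial",
    "is_lossless_by_search",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedTrial:
    """One read copied from a reference window with planted substitutions."""

    read: str
    position: int  # 1-based start of the source window
    mutated: tuple[int, ...]  # 0-based offsets within the read


@dataclass
class SensitivitySummary:
    tp: int
    fn: int
    misses: list[PlantedTrial]

    @property
    def sensitivity(self) -> float:
        """TP / (TP + FN); 1.0 exactly for a lossless seed."""
        if self.tp + self.fn == 0:
            return float("nan")
        return self.tp / (self.tp + self.fn)


def make_reference(length: int, rng: np.random.Generator | int) -> str:
    """Uniform i.i.d. reference sequence of the given length."""
    if length < 1:
        raise ValueError("reference length must be positive")
    rng = np.random.default_rng(rng)
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def plant_read(
    ref: str,
    n_r: int,
    k: int,
    rng: np.random.Generator | int,
    position: Optional[int] = None,
    mutated: Optional[Sequence[int]] = None,
) -> PlantedTrial:
    """Copy a window of ``ref`` and plant exactly ``k`` substitutions.

    ``position`` (1-based) and ``mutated`` (0-based offsets in the read)
    default to uniform random draws; each substituted base is drawn
    uniformly from the three bases differing from the original.
    """
    if not 0 <= k <= n_r:
        raise ValueError("cannot plant more substitutions than read positions")
    if n_r > len(ref):
        raise ValueError("read longer than the reference")
    rng = np.random.default_rng(rng)
    if position is None:
        position = int(rng.integers(1, len(ref) - n_r + 2))
    if mutated is None:
        mutated = rng.choice(n_r, size=k, replace=False)
    mutated = tuple(sorted(int(i) for i in mutated))
    if len(mutated) != k or any(not 0 <= i < n_r for i in mutated):
        raise ValueError("mutated offsets must be k distinct positions in the read")
    read = list(ref[position - 1 : position - 1 + n_r])
    for i in mutated:
        choices = [b for b in "ACGT" if b != read[i]]
        read[i] = choices[int(rng.integers(0, 3))]
    return PlantedTrial(read="".join(read), position=position, mutated=mutated)


def sensitivity_experiment(
    seed: Seed,
    spec: ValidationSpec,
    trials: int,
    rng: np.random.Generator | int,
    ref_length: int = 50_000,
    k: Optional[int] = None,
) -> SensitivitySummary:
    """Plant ``trials`` mutated reads and count recoveries of the true start.

    Each trial plants ``k`` substitutions (default: uniform in
    ``[0, n_m]``) and asks whether the planted window start appears among
    the candidate positions from the record library.  For a seed the
    validator approves, the summary must come back with ``fn == 0`` and
    sensitivity exactly 1.0.
    """
    rng = np.random.default_rng(rng)
    ref = EncodedReference(make_reference(ref_length, rng))
    lib = build_library(ref, seed)
    tp, fn, misses = 0, 0, []
    for _ in range(trials):
        kk = int(rng.integers(0, spec.n_m + 1)) if k is None else k
        trial = plant_read(ref.sequence, spec.n_r, kk, rng)
        report = search_candidates(lib, trial.read)
        if trial.position in report.candidates:
            tp += 1
        else:
            fn += 1
            misses.append(trial)
    return SensitivitySummary(tp=tp, fn=fn, misses=misses)


def adversarial_trial(
    seed: Seed,
    spec: ValidationSpec,
    rng: np.random.Generator | int,
    ref_length: int = 2_000,
) -> tuple[PlantedTrial, bool]:
    """Construct a worst-case trial for an invalid seed.

    The substitutions are planted at a defeating mismatch combination
    reported by the validator, so the planted position cannot produce a
    seed-value hit.  Returns the trial and whether the planted start was
    recovered (``False`` is the expected concrete miss).  Raises if the
    seed is actually valid for ``spec``.
    """
    combo = find_defeating_combo(seed, spec)
    if combo is None:
        raise ValueError(f"seed {seed} is valid for {spec}; no defeating combination")
    rng = np.random.default_rng(rng)
    ref = EncodedReference(make_reference(ref_length, rng))
    lib = build_library(ref, seed)
    trial = plant_read(ref.sequence, spec.n_r, len(combo), rng, mutated=combo)
    report = search_candidates(lib, trial.read)
    return trial, trial.position in report.candidates


def is_lossless_by_search(
    seed: Seed,
    spec: ValidationSpec,
    rng: np.random.Generator | int,
    ref_length: Optional[int] = None,
) -> bool:
    """Exhaustive planted-read decision of losslessness, via the library.

    Plants a read at a fixed position for *every* mismatch combination of
    exactly ``n_m`` positions and checks recovery through the record
    library.  Independent of the row/column bit logic, so it serves as an
    oracle for the validator at small sizes.  Agrees with
    :func:`~spacedseeds.validate.is_full_sensitivity_columns` by
    construction of the planted reads.
    """
    from itertools import combinations

    rng = np.random.default_rng(rng)
    if ref_length is None:
        ref_length = spec.n_r + 40
    ref = EncodedReference(make_reference(ref_length, rng))
    lib = build_library(ref, seed)
    position = int(rng.integers(1, len(ref.sequence) - spec.n_r + 2))
    k = min(spec.n_m, spec.n_r)
    for combo in combinations(range(spec.n_r), k):
        trial = plant_read(
            ref.sequence, spec.n_r, k, rng, position=position, mutated=combo
        )
        report = search_candidates(lib, trial.read)
        if trial.position not in report.candidates:
            return False
    return True
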