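"""Matched random-sequence null model.

Generates random sequences whose length distribution is copied one-to-one
from a reference set and whose GC content matches a pooled target exactly by
count: every sequence of length L receives round(L * gc_target) G/C bases at
uniformly random positions, G vs C and A vs U each split uniformly. This
removes composition and length as nuisance axes, so any structural contrast
against the reference set reflects sequence order alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio import Region, SequenceRecord, pooled_gc


@dataclass(frozen=True)
class NullSpec:
    """Recipe for one matched random set: per-sequence lengths (nt), the
    pooled GC fraction to hit, and the RNG seed."""

    lengths: tuple[int, ...]
    gc_target: float
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lengths", tuple(int(x) for x in self.lengths))
        if any(l < 1 for l in self.lengths):
            raise ValueError("all lengths must be >= 1")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError(f"gc_target {self.gc_target} outside [0, 1]")


def generate_matched(
    spec: NullSpec, per_sequence_gc: Sequence[float] | None = None
) -> list[SequenceRecord]:
    """Generate one random sequence per requested length.

    With ``per_sequence_gc`` given (same length as ``spec.lengths``), each
    sequence is matched to its own GC fraction instead of the pooled target.
    Fully reproducible from ``spec.seed``.
    """
    if per_sequence_gc is not None and len(per_sequence_gc) != len(spec.lengths):
        raise ValueError("per_sequence_gc must match lengths one-to-one")
    rng = np.random.default_rng(spec.seed)
    out = []
    for idx, length in enumerate(spec.lengths):
        gc = spec.gc_target if per_sequence_gc is None else per_sequence_gc[idx]
        if not 0.0 <= gc <= 1.0:
            raise ValueError(f"gc fraction {gc} outside [0, 1]")
        n_gc = round(length * gc)
        arr = np.empty(length, dtype="<U1")
        gc_pos = rng.choice(length, size=n_gc, replace=False)
        mask = np.zeros(length, dtype=bool)
        mask[gc_pos] = True
        arr[mask] = rng.choice(np.array(["G", "C"]), size=n_gc)
        arr[~mask] = rng.choice(np.array(["A", "U"]), size=length - n_gc)
        out.append(
            SequenceRecord(
                id=f"random_{idx + 1:03d}",
                residues="".join(arr),
                region=Region.RANDOM,
            )
        )
    return out


def match_from_reference(
    refs: Sequence[SequenceRecord], seed: int = 0
) -> NullSpec:
    """Build a NullSpec mirroring a reference set: lengths copied one-to-one,
    gc_target = pooled GC fraction of the references."""
    refs = list(refs)
    if not refs:
        raise ValueError("reference set is empty")
    return NullSpec(
        lengths=tuple(len(r) for r in refs),
        gc_target=pooled_gc(refs),
        seed=seed,
    )


def its_like_spec(
    n_its1: int = 50,
    n_its2: int = 50,
    gc_target: float = 0.549,
    seed: int = 0,
    its1_range: tuple[int, int] = (238, 286),
    its2_range: tuple[int, int] = (177, 220),
) -> NullSpec:
    """Null recipe mimicking observed ITS composition: half the lengths
    drawn uniformly from the ITS1 length range, half from the ITS2 range,
    pooled GC at the observed 54.9% default."""
    rng = np.random.default_rng(seed)
    lengths = tuple(rng.integers(its1_range[0], its1_range[1] + 1, n_its1)) + tuple(
        rng.integers(its2_range[0], its2_range[1] + 1, n_its2)
    )
    return NullSpec(lengths=lengths, gc_target=gc_target, seed=int(rng.integers(2**31)))


def gc_rounding_bound(spec: NullSpec) -> float:
    """Largest possible |pooled GC - gc_target| from per-sequence rounding."""
    total = sum(spec.lengths)
    return 0.5 * len(spec.lengths) / total
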