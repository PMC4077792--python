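"""Synthetic benchmark data with known structural ground truth.

Two sequence classes at desk scale:

* *structured*: ITS-like sequences built from k designed stem-loop units
  (stem, loop, reverse-complement stem) separated by A/U-rich spacers that
  are screened against pairing with the stems — so the intended fold, and
  in particular the intended hairpin count, is known by construction;
* *random*: unconstrained sequences generated by :mod:`itsfold.nullgen`,
  matched to the structured class in per-sequence length and pooled GC.

Spacers and loops are A/U-biased and G-free, so the GC budget concentrates
in the stems — mirroring how real conserved stems are more GC-rich than
unconstrained spacer runs — while the class total matches the target
exactly. What these data do NOT emulate:
phylogenetic correlation between sequences, indel length variation, or
compensatory substitution patterns — they probe the folding/census/testing
machinery, not evolution along a tree.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .nullgen import generate_matched, match_from_reference
from .seqio import Region, SecondaryStructure, SequenceRecord

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(s))


@dataclass(frozen=True)
class ScaffoldSpec:
    """Design of one structured sequence.

    k_hairpins stem-loop units of ``stem_len`` base pairs and ``loop_len``
    unpaired loop bases, separated (and flanked) by ``spacer_len`` spacer
    bases; ``gc_target`` is the overall GC fraction of the sequence.
    """

    k_hairpins: int
    stem_len: int = 8
    loop_len: int = 5
    spacer_len: int = 10
    gc_target: float = 0.549
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_hairpins < 0:
            raise ValueError("k_hairpins must be >= 0")
        if self.k_hairpins > 0 and self.stem_len < 1:
            raise ValueError("stem_len must be >= 1")
        if self.loop_len < 3:
            raise ValueError("loop_len must be >= 3 (minimum hairpin loop)")
        if self.spacer_len < 0:
            raise ValueError("spacer_len must be >= 0")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError("gc_target outside [0, 1]")

    @property
    def length(self) -> int:
        return (
            self.k_hairpins * (2 * self.stem_len + self.loop_len)
            + (self.k_hairpins + 1) * self.spacer_len
        )


def _unpaired_run(rng: np.random.Generator, n: int, n_c: int) -> str:
    """A/U-biased run carrying exactly ``n_c`` C residues; no G, so spacers
    and loops cannot seed G-C pairs with the C side of the stems."""
    arr = np.array(rng.choice(["A", "U"], size=n, p=[0.6, 0.4]), dtype="<U1")
    if n_c:
        arr[rng.choice(n, size=n_c, replace=False)] = "C"
    return "".join(arr)


def _spacer_clashes(spacer: str, stems: list[str], k: int = 4) -> bool:
    """Does any k-mer of the spacer have a reverse complement inside a stem
    (or its complement strand)?"""
    targets = set()
    for stem in stems:
        both = stem + "#" + _revcomp(stem)
        for i in range(len(both) - k + 1):
            targets.add(both[i : i + k])
    targets.discard(None)
    for i in range(len(spacer) - k + 1):
        if _revcomp(spacer[i : i + k]) in targets:
            return True
    return False


def make_structured(
    spec: ScaffoldSpec, seq_id: str = "synth_001"
) -> tuple[SequenceRecord, SecondaryStructure]:
    """Build one structured sequence and its intended structure.

    The G+C budget implied by ``gc_target`` is hit exactly: it is spent
    first on stem pairs (each G-C pair contributes two G/C bases and
    stabilizes the designed fold), and the remainder is placed into the
    unpaired runs as C residues at random positions.
    """
    rng = np.random.default_rng(spec.seed)
    k, s, lp = spec.k_hairpins, spec.stem_len, spec.loop_len
    if spec.length == 0:
        raise ValueError("scaffold of total length 0")

    # GC budget: stems carry it as G-C pairs (preferred, they stabilize the
    # designed fold); whatever stems cannot absorb goes into the unpaired
    # runs as C residues, so the overall count is hit exactly
    target_gc = round(spec.length * spec.gc_target)
    total_pairs = k * s
    run_lengths = [lp] * k + [spec.spacer_len] * (k + 1)
    unpaired_count = sum(run_lengths)
    baseline_unpaired_gc = round(0.25 * unpaired_count)
    gc_pairs = min(total_pairs, max(0, round((target_gc - baseline_unpaired_gc) / 2)))
    unpaired_gc = target_gc - 2 * gc_pairs
    if unpaired_gc < 0 or unpaired_gc > unpaired_count:
        raise ValueError(
            f"gc_target {spec.gc_target} unreachable: {total_pairs} stem pairs "
            f"and {unpaired_count} unpaired positions"
        )
    run_gc = (
        rng.multivariate_hypergeometric(run_lengths, unpaired_gc)
        if unpaired_count
        else np.zeros(len(run_lengths), dtype=int)
    )
    loops = [_unpaired_run(rng, lp, int(run_gc[i])) for i in range(k)]
    spacers = [
        _unpaired_run(rng, spec.spacer_len, int(run_gc[k + i])) for i in range(k + 1)
    ]

    # distribute GC pairs across stems as evenly as possible
    per_stem = [gc_pairs // k + (1 if i < gc_pairs % k else 0) for i in range(k)] if k else []
    stems = []
    for i in range(k):
        is_gc = np.zeros(s, dtype=bool)
        is_gc[rng.choice(s, size=per_stem[i], replace=False)] = True
        stem = "".join(
            rng.choice(["G", "C"]) if g else rng.choice(["A", "U"]) for g in is_gc
        )
        stems.append(stem)

    # re-draw spacers that could pair with stem sequence
    for idx in range(k + 1):
        tries = 0
        while spec.spacer_len >= 4 and _spacer_clashes(spacers[idx], stems) and tries < 50:
            spacers[idx] = _unpaired_run(rng, spec.spacer_len, int(run_gc[k + idx]))
            tries += 1

    parts = [spacers[0]]
    pairs = []
    offset = spec.spacer_len
    for i in range(k):
        parts.append(stems[i])
        parts.append(loops[i])
        parts.append(_revcomp(stems[i]))
        unit = 2 * s + lp
        for x in range(s):
            pairs.append((offset + x, offset + unit - 1 - x))
        offset += unit + spec.spacer_len
        parts.append(spacers[i + 1])

    record = SequenceRecord(id=seq_id, residues="".join(parts), region=Region.SYNTH)
    intended = SecondaryStructure(seq_id=seq_id, pairs=tuple(pairs), energy=0.0)
    return record, intended


def make_dataset(
    n_structured: int,
    n_random: int,
    spec: ScaffoldSpec,
    seed: int = 0,
    spacer_jitter: int = 3,
    spec2: ScaffoldSpec | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Labeled two-class dataset: structured scaffolds (with per-sequence
    spacer-length jitter) plus a nullgen random class matched to the
    structured class's lengths and pooled GC.

    Mirroring the two-region design of real spacer data, the structured
    class is split into two labeled halves: the first folds ``spec``, the
    second ``spec2`` (default: ``spec`` with one hairpin fewer, as the
    shorter spacer region carries fewer hairpins). Random sequences inherit
    the half label of the structured sequence whose length they match.
    Returns (records, truth table) with class, half, length, GC and the
    intended hairpin count per sequence.
    """
    if n_structured < 1 or n_random < 1:
        raise ValueError("need at least one sequence per class")
    if spec2 is None:
        spec2 = replace(spec, k_hairpins=max(1, spec.k_hairpins - 1))
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    rows = []
    n_half1 = (n_structured + 1) // 2
    halves: list[str] = []
    for i in range(n_structured):
        half = "HALF1" if i < n_half1 else "HALF2"
        base = spec if half == "HALF1" else spec2
        jitter = int(rng.integers(-spacer_jitter, spacer_jitter + 1)) if spacer_jitter else 0
        sp = replace(
            base,
            spacer_len=max(4, base.spacer_len + jitter),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec, _intended = make_structured(sp, seq_id=f"synth_{i + 1:03d}")
        records.append(rec)
        halves.append(half)
        rows.append(
            {
                "seq_id": rec.id,
                "seq_class": "STRUCTURED",
                "half": half,
                "length": len(rec),
                "gc": rec.gc_fraction,
                "intended_hairpins": sp.k_hairpins,
            }
        )
    null_spec = match_from_reference(records, seed=int(rng.integers(0, 2**31 - 1)))
    if n_random != n_structured:
        null_spec = replace(
            null_spec,
            lengths=tuple(null_spec.lengths[i % n_structured] for i in range(n_random)),
        )
    randoms = generate_matched(null_spec)
    for i, rec in enumerate(randoms):
        records.append(rec)
        rows.append(
            {
                "seq_id": rec.id,
                "seq_class": "RANDOM",
                "half": halves[i % n_structured],
                "length": len(rec),
                "gc": rec.gc_fraction,
                "intended_hairpins": pd.NA,
            }
        )
    return records, pd.DataFrame(rows)
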