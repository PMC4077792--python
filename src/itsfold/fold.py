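"""Minimum-free-energy RNA secondary structure prediction.

A nearest-neighbor thermodynamic model (Turner 2004 free energies at 37 °C,
shipped as plain-text tables under ``itsfold/data/``) drives a Zuker-style
dynamic program for the MFE structure, a loop-decomposition scorer for
arbitrary structures, an exhaustive enumerator usable as an oracle on short
sequences, and a Wuchty-style best-first enumerator for the suboptimal
ensemble within an energy band.

Model scope: pseudoknot-free structures; allowed pairs AU/UA/GC/CG/GU/UG;
minimum hairpin loop of 3 unpaired bases; helix stacking, hairpin and
interior terminal mismatches, loop-length initiation terms with logarithmic
extrapolation beyond 30, Ninio asymmetry for interior loops, affine
multiloops, and a terminal-AU/GU helix-end penalty. Dangling ends, coaxial
stacking and tabulated special loops (tetraloop bonuses, 1x1/2x1/2x2
interior tables) are deliberately omitted; absolute energies therefore carry
a small systematic offset relative to full folding programs while relative
contrasts between sequence classes are preserved.

All internal arithmetic is in integer tenths of kcal/mol; reported energies
are floats in kcal/mol with one decimal.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterator, Sequence

import numpy as np
from numba import njit

from .seqio import SecondaryStructure, SequenceRecord

INF = 1 << 28
HAIRPIN_MIN = 3  # minimum unpaired bases in a hairpin loop

#: base codes: ambiguity/N = 0, then A C G U (aligned with mismatch tables)
_BASE_CODE = {"A": 1, "C": 2, "G": 3, "U": 4}
_PAIR_NAMES = ("CG", "GC", "GU", "UG", "AU", "UA")
#: pair-type index by (code5', code3'); -1 = cannot pair
_PT = -np.ones((5, 5), dtype=np.int64)
for _idx, _name in enumerate(_PAIR_NAMES):
    _PT[_BASE_CODE[_name[0]], _BASE_CODE[_name[1]]] = _idx
#: pair types carrying the terminal AU/GU helix-end penalty
_AU_TYPES = frozenset((2, 3, 4, 5))


def encode(residues: str) -> np.ndarray:
    """Map residues to integer codes; ambiguity codes become 0 (unpairable)."""
    return np.array([_BASE_CODE.get(c, 0) for c in residues], dtype=np.int64)


def can_pair(a: str, b: str) -> bool:
    return _PT[_BASE_CODE.get(a, 0), _BASE_CODE.get(b, 0)] >= 0


# ---------------------------------------------------------------------------
# Energy model


def _read_table(name: str) -> list[list[str]]:
    text = resources.files("itsfold.data").joinpath(name).read_text()
    return [
        line.split("\t")
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def _deci(s: str) -> int:
    return INF if s == "INF" else round(float(s) * 10)


@dataclass(frozen=True)
class EnergyModel:
    """Integer (0.1 kcal/mol) nearest-neighbor parameter set.

    ``stack[p_outer][p_inner]`` stacks pair (i,j) on (i+1,j-1); mismatch
    tables are indexed ``[closing pair][code(i+1)][code(j-1)]`` with code 0
    reserved for unknown bases. Loop initiation tables cover sizes 0..30;
    longer loops use ``dG(30) + lxc·ln(n/30)``.
    """

    stack: tuple  # 6x6
    mm_hairpin: tuple  # 6x5x5
    mm_interior: tuple  # 6x5x5
    hairpin_init: tuple  # 31
    bulge_init: tuple
    interior_init: tuple
    ml_closing: int
    ml_branch: int
    ml_unpaired: int
    terminal_au: int
    ninio_m: int
    ninio_max: int
    lxc: float
    max_interior: int = 30

    def loop_tables(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Initiation tables extended to loop size ``n`` (numpy, for the DP)."""
        size = max(n, 30) + 1
        out = []
        for base in (self.hairpin_init, self.bulge_init, self.interior_init):
            arr = np.full(size, INF, dtype=np.int64)
            arr[:31] = base
            for m in range(31, size):
                arr[m] = base[30] + round(self.lxc * 10 * math.log(m / 30.0))
            out.append(arr)
        return tuple(out)

    def extrapolated(self, base: tuple, m: int) -> int:
        if m <= 30:
            return base[m]
        return base[30] + round(self.lxc * 10 * math.log(m / 30.0))


@lru_cache(maxsize=None)
def load_default_model() -> EnergyModel:
    """Load the Turner 2004 tables shipped with the package."""
    pair_idx = {p: i for i, p in enumerate(_PAIR_NAMES)}
    base_idx = {"N": 0, "A": 1, "C": 2, "G": 3, "U": 4}

    rows = _read_table("turner2004_stack.tsv")
    header = rows[0][1:]
    stack = [[0] * 6 for _ in range(6)]
    for row in rows[1:]:
        for col, val in zip(header, row[1:]):
            stack[pair_idx[row[0]]][pair_idx[col]] = _deci(val)

    def read_mismatch(name: str) -> list:
        table = [[[0] * 5 for _ in range(5)] for _ in range(6)]
        for pair, x, y, val in _read_table(name)[1:]:
            table[pair_idx[pair]][base_idx[x]][base_idx[y]] = _deci(val)
        return table

    loops = _read_table("turner2004_loops.tsv")[1:]
    hp, bu, it = [INF] * 31, [INF] * 31, [INF] * 31
    for n_s, h, b, i in loops:
        n = int(n_s)
        hp[n], bu[n], it[n] = _deci(h), _deci(b), _deci(i)

    misc = {row[0]: row[1] for row in _read_table("turner2004_misc.tsv")[1:]}
    to_tuple = lambda m: tuple(tuple(tuple(r) for r in p) for p in m)
    return EnergyModel(
        stack=tuple(tuple(r) for r in stack),
        mm_hairpin=to_tuple(read_mismatch("turner2004_mismatch_hairpin.tsv")),
        mm_interior=to_tuple(read_mismatch("turner2004_mismatch_interior.tsv")),
        hairpin_init=tuple(hp),
        bulge_init=tuple(bu),
        interior_init=tuple(it),
        ml_closing=_deci(misc["ml_closing"]),
        ml_branch=_deci(misc["ml_branch"]),
        ml_unpaired=_deci(misc["ml_unpaired"]),
        terminal_au=_deci(misc["terminal_au"]),
        ninio_m=_deci(misc["ninio_m"]),
        ninio_max=_deci(misc["ninio_max"]),
        lxc=float(misc["lxc"]),
        max_interior=int(misc["max_interior"]),
    )


# ---------------------------------------------------------------------------
# Integer loop energies (pure Python; mirrored inside the numba kernel)


class _Eval:
    """Per-sequence evaluator holding codes, pair types, and the model."""

    def __init__(self, seq: SequenceRecord | str, model: EnergyModel):
        residues = seq if isinstance(seq, str) else seq.residues
        self.codes = [_BASE_CODE.get(c, 0) for c in residues]
        self.n = len(self.codes)
        self.m = model
        self._pt = _PT

    def pt(self, i: int, j: int) -> int:
        return int(self._pt[self.codes[i], self.codes[j]])

    def tau(self, ptype: int) -> int:
        return self.m.terminal_au if ptype in _AU_TYPES else 0

    def hairpin_e(self, i: int, j: int) -> int:
        u = j - i - 1
        p = self.pt(i, j)
        e = self.m.extrapolated(self.m.hairpin_init, u)
        if e >= INF:
            return INF
        if u == HAIRPIN_MIN:
            return e + self.tau(p)
        return e + self.m.mm_hairpin[p][self.codes[i + 1]][self.codes[j - 1]]

    def interior_e(self, i: int, j: int, k: int, l: int) -> int:
        """Two-loop term: stack, bulge, or interior loop between (i,j)⊃(k,l)."""
        n1, n2 = k - i - 1, j - l - 1
        po, pi_ = self.pt(i, j), self.pt(k, l)
        if n1 == 0 and n2 == 0:
            return self.m.stack[po][pi_]
        u = n1 + n2
        if n1 == 0 or n2 == 0:
            e = self.m.extrapolated(self.m.bulge_init, u)
            if u == 1:
                return e + self.m.stack[po][pi_]
            return e + self.tau(po) + self.tau(pi_)
        e = self.m.extrapolated(self.m.interior_init, u)
        e += min(self.m.ninio_max, self.m.ninio_m * abs(n1 - n2))
        e += self.m.mm_interior[po][self.codes[i + 1]][self.codes[j - 1]]
        # enclosed pair seen from inside the loop: closing type reversed
        pr = int(self._pt[self.codes[l], self.codes[k]])
        e += self.m.mm_interior[pr][self.codes[l + 1]][self.codes[k - 1]]
        return e


def _int_energy_of(ev: _Eval, pairs: Sequence[tuple[int, int]]) -> int:
    """Loop-decomposition energy of an arbitrary valid structure, deci-kcal."""
    m = ev.m
    for i, j in pairs:
        if j >= ev.n:
            raise ValueError(f"pair ({i},{j}) outside sequence of length {ev.n}")
        if ev.pt(i, j) < 0:
            raise ValueError(
                f"pair ({i},{j}) is not an allowed base pair "
                f"({'ACGU'[ev.codes[i]-1] if ev.codes[i] else 'N'}-"
                f"{'ACGU'[ev.codes[j]-1] if ev.codes[j] else 'N'})"
            )
    ordered = sorted(pairs)
    # direct children of each pair (and of the exterior) via a nesting stack
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for p in ordered:
        while stack and p[0] > stack[-1][1]:
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append(p)
        children.setdefault(p, [])
        stack.append(p)
    e = 0
    for i, j in children[None]:  # exterior branches
        e += ev.tau(ev.pt(i, j))
    for parent, kids in children.items():
        if parent is None:
            continue
        i, j = parent
        if not kids:
            e += ev.hairpin_e(i, j)
        elif len(kids) == 1:
            e += ev.interior_e(i, j, *kids[0])
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            e += m.ml_closing + m.ml_branch * (len(kids) + 1)
            e += m.ml_unpaired * unpaired + ev.tau(ev.pt(i, j))
            for k, l in kids:
                e += ev.tau(ev.pt(k, l))
    return e


def energy_of(
    seq: SequenceRecord,
    structure: SecondaryStructure,
    model: EnergyModel | None = None,
) -> float:
    """Free energy (kcal/mol) of ``structure`` on ``seq`` under the model.

    The structure is decomposed into loops (stacks, hairpin, bulge, interior,
    multibranch, exterior) whose model terms are summed; the open chain
    scores 0.0. Invalid pairings raise ``ValueError``.
    """
    structure.pair_table(len(seq))  # bounds + involution check
    ev = _Eval(seq, model or load_default_model())
    return _int_energy_of(ev, structure.pairs) / 10.0


# ---------------------------------------------------------------------------
# Numba kernels: loop energies shared by the DP fill and the enumerator


@njit(cache=True)
def _tau_nb(p, t_au):
    return t_au if p >= 2 else 0


@njit(cache=True)
def _hairpin_nb(i, j, codes, pt, hp, mmh, t_au):
    p = pt[codes[i], codes[j]]
    if p < 0:
        return INF
    u = j - i - 1
    e = hp[u]
    if e >= INF:
        return INF
    if u == HAIRPIN_MIN:
        return e + _tau_nb(p, t_au)
    return e + mmh[p, codes[i + 1], codes[j - 1]]


@njit(cache=True)
def _interior_nb(i, j, k, l, codes, pt, stack, bu, itab, mmi,
                 ninio_m, ninio_max, t_au):
    p = pt[codes[i], codes[j]]
    q = pt[codes[k], codes[l]]
    n1 = k - i - 1
    n2 = j - l - 1
    if n1 == 0 and n2 == 0:
        return stack[p, q]
    u = n1 + n2
    if n1 == 0 or n2 == 0:
        e = bu[u]
        if u == 1:
            e += stack[p, q]
        else:
            e += _tau_nb(p, t_au) + _tau_nb(q, t_au)
        return e
    nin = ninio_m * (n1 - n2 if n1 > n2 else n2 - n1)
    if nin > ninio_max:
        nin = ninio_max
    qr = pt[codes[l], codes[k]]
    return (itab[u] + nin + mmi[p, codes[i + 1], codes[j - 1]]
            + mmi[qr, codes[l + 1], codes[k - 1]])


@njit(cache=True)
def _fill(codes, pt, stack, mmh, mmi, hp, bu, itab, ml_c, ml_b, ml_u,
          t_au, ninio_m, ninio_max, max_int):
    """Zuker-style fill. V: (i,j) paired; M: multiloop segment with >=1
    branch; M1: segment with exactly one branch starting at i; W: exterior
    prefix. Decompositions are unique (keyed on the status of the rightmost
    base), so the same recursions drive complete suboptimal enumeration."""
    n = codes.shape[0]
    V = np.full((n, n), INF, dtype=np.int64)
    M = np.full((n, n), INF, dtype=np.int64)
    M1 = np.full((n, n), INF, dtype=np.int64)
    W = np.zeros(n + 1, dtype=np.int64)

    for span in range(HAIRPIN_MIN + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            p = pt[codes[i], codes[j]]
            if p >= 0:
                tau_ij = _tau_nb(p, t_au)
                best = _hairpin_nb(i, j, codes, pt, hp, mmh, t_au)
                for k in range(i + 1, j - HAIRPIN_MIN):
                    n1 = k - i - 1
                    if n1 > max_int:
                        break
                    lmin = k + HAIRPIN_MIN + 1
                    l2 = j - 1 - (max_int - n1)
                    if l2 > lmin:
                        lmin = l2
                    for l in range(j - 1, lmin - 1, -1):
                        if pt[codes[k], codes[l]] < 0 or V[k, l] >= INF:
                            continue
                        cand = _interior_nb(i, j, k, l, codes, pt, stack, bu,
                                            itab, mmi, ninio_m, ninio_max,
                                            t_au) + V[k, l]
                        if cand < best:
                            best = cand
                # multiloop: k = start of the last branch
                for k in range(i + 2, j - HAIRPIN_MIN):
                    if M[i + 1, k - 1] < INF and M1[k, j - 1] < INF:
                        cand = (ml_c + ml_b + tau_ij
                                + M[i + 1, k - 1] + M1[k, j - 1])
                        if cand < best:
                            best = cand
                V[i, j] = best

            # M1: exactly one branch starting at i, trailing bases unpaired
            bestm1 = INF
            if j - 1 >= i and M1[i, j - 1] < INF:
                bestm1 = M1[i, j - 1] + ml_u
            if p >= 0 and V[i, j] < INF:
                cand = V[i, j] + ml_b + _tau_nb(p, t_au)
                if cand < bestm1:
                    bestm1 = cand
            M1[i, j] = bestm1

            # M: >=1 branch; keyed on the status of j
            bestm = INF
            if j - 1 >= i and M[i, j - 1] < INF:
                bestm = M[i, j - 1] + ml_u
            for k in range(i, j - HAIRPIN_MIN):
                q = pt[codes[k], codes[j]]
                if q < 0 or V[k, j] >= INF:
                    continue
                base = V[k, j] + ml_b + _tau_nb(q, t_au)
                cand = base + ml_u * (k - i)  # no branch before k
                if cand < bestm:
                    bestm = cand
                if k > i and M[i, k - 1] < INF:
                    cand = base + M[i, k - 1]
                    if cand < bestm:
                        bestm = cand
            M[i, j] = bestm

    for j in range(n):
        W[j + 1] = W[j]
        for k in range(0, j - HAIRPIN_MIN):
            q = pt[codes[k], codes[j]]
            if q >= 0 and V[k, j] < INF:
                cand = W[k] + V[k, j] + _tau_nb(q, t_au)
                if cand < W[j + 1]:
                    W[j + 1] = cand
    return V, M, M1, W


class _Matrices:
    """Filled DP matrices plus the numpy views the kernels need."""

    def __init__(self, seq: SequenceRecord | str, model: EnergyModel):
        self.ev = _Eval(seq, model)
        self.model = model
        self.codes = np.array(self.ev.codes, dtype=np.int64)
        n = self.ev.n
        self.hp, self.bu, self.itab = model.loop_tables(n)
        self.stack = np.array(model.stack, dtype=np.int64)
        self.mmh = np.array(model.mm_hairpin, dtype=np.int64)
        self.mmi = np.array(model.mm_interior, dtype=np.int64)
        self.V, self.M, self.M1, self.W = _fill(
            self.codes, _PT, self.stack, self.mmh, self.mmi,
            self.hp, self.bu, self.itab,
            model.ml_closing, model.ml_branch, model.ml_unpaired,
            model.terminal_au, model.ninio_m, model.ninio_max,
            model.max_interior,
        )


def _run_fill(seq: SequenceRecord | str, model: EnergyModel) -> _Matrices:
    return _Matrices(seq, model)


# ---------------------------------------------------------------------------
# Traceback (deterministic tie-breaking: hairpin first, then two-loop with
# 5' side innermost-first, then multiloop with smallest last-branch start;
# exterior prefers the smallest pairing partner for the rightmost base)


def _traceback(mat: _Matrices) -> list[tuple[int, int]]:
    ev, V, M, M1, W = mat.ev, mat.V, mat.M, mat.M1, mat.W
    m = ev.m
    n = ev.n
    pairs: list[tuple[int, int]] = []
    agenda: list[tuple[str, int, int]] = [("W", 0, n - 1)]
    while agenda:
        kind, i, j = agenda.pop()
        if kind == "W":
            if j < 0:
                continue
            target = W[j + 1]
            found = False
            for k in range(0, j - HAIRPIN_MIN):
                q = ev.pt(k, j)
                if q >= 0 and V[k, j] < INF:
                    if W[k] + V[k, j] + ev.tau(q) == target:
                        pairs.append((k, j))
                        agenda.append(("W", 0, k - 1))
                        agenda.append(("V", k, j))
                        found = True
                        break
            if not found:
                if W[j] != target:
                    raise RuntimeError("exterior traceback failed")
                agenda.append(("W", 0, j - 1))
        elif kind == "V":
            target = V[i, j]
            if ev.hairpin_e(i, j) == target:
                continue
            found = False
            for k in range(i + 1, j - HAIRPIN_MIN):
                if k - i - 1 > m.max_interior:
                    break
                lmin = max(k + HAIRPIN_MIN + 1,
                           j - 1 - (m.max_interior - (k - i - 1)))
                for l in range(j - 1, lmin - 1, -1):
                    if ev.pt(k, l) >= 0 and V[k, l] < INF:
                        if ev.interior_e(i, j, k, l) + V[k, l] == target:
                            pairs.append((k, l))
                            agenda.append(("V", k, l))
                            found = True
                            break
                if found:
                    break
            if found:
                continue
            tau_ij = ev.tau(ev.pt(i, j))
            for k in range(i + 2, j - HAIRPIN_MIN):
                if M[i + 1, k - 1] < INF and M1[k, j - 1] < INF:
                    if (m.ml_closing + m.ml_branch + tau_ij
                            + M[i + 1, k - 1] + M1[k, j - 1]) == target:
                        agenda.append(("M", i + 1, k - 1))
                        agenda.append(("M1", k, j - 1))
                        found = True
                        break
            if not found:
                raise RuntimeError(f"V traceback failed at ({i},{j})")
        elif kind == "M":
            target = M[i, j]
            found = False
            for k in range(i, j - HAIRPIN_MIN):
                q = ev.pt(k, j)
                if q < 0 or V[k, j] >= INF:
                    continue
                base = V[k, j] + m.ml_branch + ev.tau(q)
                if base + m.ml_unpaired * (k - i) == target:
                    pairs.append((k, j))
                    agenda.append(("V", k, j))
                    found = True
                    break
                if k > i and M[i, k - 1] < INF and base + M[i, k - 1] == target:
                    pairs.append((k, j))
                    agenda.append(("V", k, j))
                    agenda.append(("M", i, k - 1))
                    found = True
                    break
            if not found:
                if j - 1 >= i and M[i, j - 1] + m.ml_unpaired == target:
                    agenda.append(("M", i, j - 1))
                else:
                    raise RuntimeError(f"M traceback failed at ({i},{j})")
        else:  # M1
            target = M1[i, j]
            q = ev.pt(i, j)
            if (q >= 0 and V[i, j] < INF
                    and V[i, j] + m.ml_branch + ev.tau(q) == target):
                pairs.append((i, j))
                agenda.append(("V", i, j))
            elif j - 1 >= i and M1[i, j - 1] + m.ml_unpaired == target:
                agenda.append(("M1", i, j - 1))
            else:
                raise RuntimeError(f"M1 traceback failed at ({i},{j})")
    return sorted(pairs)


def fold_mfe(seq: SequenceRecord, model: EnergyModel | None = None) -> SecondaryStructure:
    """Predict the minimum-free-energy structure of ``seq``.

    Returns a valid pseudoknot-free structure minimizing the model energy
    (the search restricts interior loops to ``model.max_interior`` total
    unpaired bases, the standard Zuker restriction). Sequences shorter than
    5 nt, or with no allowed pair, return the open chain at 0.0 kcal/mol.
    """
    model = model or load_default_model()
    n = len(seq)
    if n < HAIRPIN_MIN + 2:  # too short for any pair
        return SecondaryStructure(seq_id=seq.id, pairs=(), energy=0.0)
    mat = _run_fill(seq, model)
    e = int(mat.W[n])
    pairs = _traceback(mat)
    return SecondaryStructure(seq_id=seq.id, pairs=tuple(pairs), energy=e / 10.0)


# ---------------------------------------------------------------------------
# Exhaustive enumeration (testing oracle)

MAX_BRUTE_LEN = 25


def _all_pairings(codes: list[int], i: int, j: int,
                  memo: dict) -> list[tuple[tuple[int, int], ...]]:
    """All pseudoknot-free pairings of [i..j]; unique by the status of i."""
    if j - i < HAIRPIN_MIN + 1:
        return [()]
    key = (i, j)
    if key in memo:
        return memo[key]
    out = list(_all_pairings(codes, i + 1, j, memo))
    for k in range(i + HAIRPIN_MIN + 1, j + 1):
        if _PT[codes[i], codes[k]] >= 0:
            inner = _all_pairings(codes, i + 1, k - 1, memo)
            outer = _all_pairings(codes, k + 1, j, memo)
            for a in inner:
                for b in outer:
                    out.append(((i, k),) + a + b)
    memo[key] = out
    return out


def brute_force_structures(
    seq: SequenceRecord, model: EnergyModel | None = None
) -> list[SecondaryStructure]:
    """Every valid structure of ``seq``, scored and sorted by energy.

    Exhaustive enumeration over all pseudoknot-free pairings obeying the
    allowed-pair set and the minimum hairpin loop; an independent oracle for
    the dynamic program on short sequences (guarded at 25 nt).
    """
    if len(seq) > MAX_BRUTE_LEN:
        raise ValueError(f"brute force limited to {MAX_BRUTE_LEN} nt, got {len(seq)}")
    model = model or load_default_model()
    ev = _Eval(seq, model)
    combos = _all_pairings(ev.codes, 0, ev.n - 1, {})
    scored = [(_int_energy_of(ev, pairs), tuple(sorted(pairs))) for pairs in combos]
    scored.sort()
    return [
        SecondaryStructure(seq_id=seq.id, pairs=p, energy=e / 10.0)
        for e, p in scored
    ]


# ---------------------------------------------------------------------------
# Suboptimal ensemble (Wuchty-style best-first enumeration)

# unresolved-interval kinds and refinement case codes
_K_W, _K_V, _K_M, _K_M1 = 0, 1, 2, 3
(_C_W_UNPAIRED, _C_W_PAIR, _C_V_HAIRPIN, _C_V_INTERIOR, _C_V_ML,
 _C_M_UNPAIRED, _C_M_BARE, _C_M_PREFIX, _C_M1_UNPAIRED, _C_M1_BRANCH) = range(10)


@njit(cache=True)
def _refine_nb(kind, i, j, rest_bound, e_max, codes, pt, V, M, M1, W,
               stack, mmh, mmi, hp, bu, itab,
               ml_c, ml_b, ml_u, t_au, ninio_m, ninio_max, max_int):
    """Expand one unresolved interval into all refinement candidates whose
    exact completion bound stays within ``e_max``.

    Returns rows (case, k, l, fixed_add, bound); the Python driver maps each
    case back onto new unresolved intervals. The candidate sets mirror the
    ``_fill`` recursions one-to-one, so each structure in the band is
    reachable exactly once.
    """
    n = codes.shape[0]
    cap = 2 * n + (max_int + 2) * (max_int + 2) + 8
    out = np.empty((cap, 5), dtype=np.int64)
    cnt = 0
    if kind == _K_W:
        b = rest_bound + (W[j] if j >= 1 else 0)
        if b <= e_max:
            out[cnt] = (_C_W_UNPAIRED, j - 1, -1, 0, b)
            cnt += 1
        for k in range(0, j - HAIRPIN_MIN):
            q = pt[codes[k], codes[j]]
            if q < 0 or V[k, j] >= INF:
                continue
            add = _tau_nb(q, t_au)
            b = rest_bound + add + V[k, j] + (W[k] if k >= 1 else 0)
            if b <= e_max:
                out[cnt] = (_C_W_PAIR, k, j, add, b)
                cnt += 1
    elif kind == _K_V:
        he = _hairpin_nb(i, j, codes, pt, hp, mmh, t_au)
        if he < INF and rest_bound + he <= e_max:
            out[cnt] = (_C_V_HAIRPIN, -1, -1, he, rest_bound + he)
            cnt += 1
        for k in range(i + 1, j - HAIRPIN_MIN):
            n1 = k - i - 1
            if n1 > max_int:
                break
            lmin = k + HAIRPIN_MIN + 1
            l2 = j - 1 - (max_int - n1)
            if l2 > lmin:
                lmin = l2
            for l in range(j - 1, lmin - 1, -1):
                if pt[codes[k], codes[l]] < 0 or V[k, l] >= INF:
                    continue
                e = _interior_nb(i, j, k, l, codes, pt, stack, bu, itab, mmi,
                                 ninio_m, ninio_max, t_au)
                b = rest_bound + e + V[k, l]
                if b <= e_max:
                    out[cnt] = (_C_V_INTERIOR, k, l, e, b)
                    cnt += 1
        p = pt[codes[i], codes[j]]
        base = ml_c + ml_b + _tau_nb(p, t_au)
        for k in range(i + 2, j - HAIRPIN_MIN):
            if M[i + 1, k - 1] < INF and M1[k, j - 1] < INF:
                b = rest_bound + base + M[i + 1, k - 1] + M1[k, j - 1]
                if b <= e_max:
                    out[cnt] = (_C_V_ML, k, -1, base, b)
                    cnt += 1
    elif kind == _K_M:
        if j - 1 >= i and M[i, j - 1] < INF:
            b = rest_bound + ml_u + M[i, j - 1]
            if b <= e_max:
                out[cnt] = (_C_M_UNPAIRED, j - 1, -1, ml_u, b)
                cnt += 1
        for k in range(i, j - HAIRPIN_MIN):
            q = pt[codes[k], codes[j]]
            if q < 0 or V[k, j] >= INF:
                continue
            add = ml_b + _tau_nb(q, t_au)
            e0 = add + ml_u * (k - i)
            b = rest_bound + e0 + V[k, j]
            if b <= e_max:
                out[cnt] = (_C_M_BARE, k, j, e0, b)
                cnt += 1
            if k > i and M[i, k - 1] < INF:
                b = rest_bound + add + M[i, k - 1] + V[k, j]
                if b <= e_max:
                    out[cnt] = (_C_M_PREFIX, k, j, add, b)
                    cnt += 1
    else:  # _K_M1
        if j - 1 >= i and M1[i, j - 1] < INF:
            b = rest_bound + ml_u + M1[i, j - 1]
            if b <= e_max:
                out[cnt] = (_C_M1_UNPAIRED, j - 1, -1, ml_u, b)
                cnt += 1
        q = pt[codes[i], codes[j]]
        if q >= 0 and V[i, j] < INF:
            add = ml_b + _tau_nb(q, t_au)
            b = rest_bound + add + V[i, j]
            if b <= e_max:
                out[cnt] = (_C_M1_BRANCH, i, j, add, b)
                cnt += 1
    return out[:cnt]


def _item_value(mat: _Matrices, item: tuple[int, int, int]) -> int:
    kind, i, j = item
    if kind == _K_W:
        return int(mat.W[j + 1])
    if kind == _K_V:
        return int(mat.V[i, j])
    if kind == _K_M:
        return int(mat.M[i, j])
    return int(mat.M1[i, j])


def _wuchty(mat: _Matrices, e_max: int, pop_limit: int | None,
            status: dict | None = None) -> Iterator[tuple[int, tuple]]:
    """Yield (energy, pairs) of every structure with energy <= e_max in
    non-decreasing energy order; each structure appears exactly once.

    States are partial structures: resolved energy, fixed pairs, and
    unresolved intervals whose DP entries give an exact completion bound,
    so the best-first pop order is globally optimal.
    """
    m = mat.model
    n = mat.ev.n
    heap: list = []
    counter = 0
    if int(mat.W[n]) > e_max:
        return
    heap.append((int(mat.W[n]), 0, 0, (), ((_K_W, 0, n - 1),)))
    pops = 0
    while heap:
        pops += 1
        if pop_limit is not None and pops > pop_limit:
            if status is not None:
                status["truncated"] = True
            return
        bound, _, fixed, pairs, items = heapq.heappop(heap)
        if not items:
            yield fixed, pairs
            continue
        last, rest = items[-1], items[:-1]
        kind, i, j = last
        rest_bound = bound - _item_value(mat, last)
        rows = _refine_nb(
            kind, i, j, rest_bound, e_max, mat.codes, _PT,
            mat.V, mat.M, mat.M1, mat.W, mat.stack, mat.mmh, mat.mmi,
            mat.hp, mat.bu, mat.itab,
            m.ml_closing, m.ml_branch, m.ml_unpaired, m.terminal_au,
            m.ninio_m, m.ninio_max, m.max_interior,
        )
        for row in rows.tolist():
            case, k, l, add, b = row
            new_pairs = pairs
            if case == _C_W_UNPAIRED:
                new_items = rest + ((_K_W, 0, k),) if k >= 0 else rest
            elif case == _C_W_PAIR:
                new_pairs = pairs + ((k, l),)
                new_items = rest + ((_K_V, k, l),)
                if k >= 1:
                    new_items = new_items + ((_K_W, 0, k - 1),)
            elif case == _C_V_HAIRPIN:
                new_items = rest
            elif case == _C_V_INTERIOR:
                new_pairs = pairs + ((k, l),)
                new_items = rest + ((_K_V, k, l),)
            elif case == _C_V_ML:
                new_items = rest + ((_K_M, i + 1, k - 1), (_K_M1, k, j - 1))
            elif case == _C_M_UNPAIRED:
                new_items = rest + ((_K_M, i, k),)
            elif case == _C_M_BARE:
                new_pairs = pairs + ((k, l),)
                new_items = rest + ((_K_V, k, l),)
            elif case == _C_M_PREFIX:
                new_pairs = pairs + ((k, l),)
                new_items = rest + ((_K_V, k, l), (_K_M, i, k - 1))
            elif case == _C_M1_UNPAIRED:
                new_items = rest + ((_K_M1, i, k),)
            else:  # _C_M1_BRANCH
                new_pairs = pairs + ((k, l),)
                new_items = rest + ((_K_V, k, l),)
            counter += 1
            heapq.heappush(heap, (b, counter, fixed + add, new_pairs, new_items))


@dataclass
class StructureEnsemble:
    """Ranked distinct suboptimal structures for one sequence."""

    seq_id: str
    structures: list[SecondaryStructure]
    count: int = 0
    complete: bool = True  # False if the exploration bound was hit

    def __post_init__(self) -> None:
        self.count = len(self.structures)

    @property
    def mfe(self) -> SecondaryStructure:
        return self.structures[0]


def default_window(n: int) -> int:
    """Length heuristic for the structure-distinctness window."""
    return 3 if n < 200 else 5


@njit(cache=True)
def _distinct_nb(cand, acc, window):
    """True if some candidate pair is >= window away from every accepted pair."""
    for a in range(cand.shape[0]):
        i, j = cand[a, 0], cand[a, 1]
        ok = True
        for b in range(acc.shape[0]):
            di = i - acc[b, 0]
            if di < 0:
                di = -di
            dj = j - acc[b, 1]
            if dj < 0:
                dj = -dj
            d = di if di > dj else dj
            if d < window:
                ok = False
                break
        if ok:
            return True
    return False


def _window_distinct(pairs: tuple, acc_arr: np.ndarray, window: int) -> bool:
    """True if some pair differs by >= window from every accepted pair."""
    if window <= 0 or acc_arr.shape[0] == 0:
        return True
    if not pairs:
        return False
    cand = np.array(pairs, dtype=np.int64)
    return bool(_distinct_nb(cand, acc_arr, window))


def enumerate_suboptimal(
    seq: SequenceRecord,
    model: EnergyModel | None = None,
    max_pct_diff: float = 10.0,
    max_count: int | None = 50,
    window: int | None = None,
    pop_limit: int | None = 100_000,
) -> StructureEnsemble:
    """Enumerate distinct suboptimal structures within an energy band.

    Structures are generated in non-decreasing energy order; all returned
    structures lie within ``max_pct_diff`` percent of the MFE (band relaxed
    toward 0, so a -80.0 MFE at 10% admits energies up to -72.0). With
    ``window > 0`` each accepted structure must contain at least one base
    pair whose coordinates differ by >= window positions from every pair of
    every previously accepted structure (the classical distinctness rule);
    ``window = None`` selects a length heuristic, and ``window == 0``
    disables the filter so every distinct structure in the band is returned.
    The list is capped at ``max_count``. For windowed enumeration an
    exploration bound (``pop_limit`` candidate states) guards against
    pathologically dense bands; because candidates are explored in energy
    order the returned list is always the energetically first window-distinct
    structures, and a hit bound is reported via ``ensemble.complete``.
    """
    if max_pct_diff < 0:
        raise ValueError("max_pct_diff must be >= 0")
    if max_count is not None and max_count < 1:
        raise ValueError("max_count must be >= 1")
    model = model or load_default_model()
    n = len(seq)
    if window is None:
        window = default_window(n)
    if n < HAIRPIN_MIN + 2:
        open_chain = SecondaryStructure(seq_id=seq.id, pairs=(), energy=0.0)
        return StructureEnsemble(seq_id=seq.id, structures=[open_chain])
    mat = _run_fill(seq, model)
    mfe_int = min(0, int(mat.W[n]))
    e_max = mfe_int + round(abs(mfe_int) * max_pct_diff / 100.0)

    accepted: list[SecondaryStructure] = []
    acc_arr = np.empty((0, 2), dtype=np.int64)
    status = {"truncated": False}
    limit = pop_limit if window > 0 else None
    for e, pairs in _wuchty(mat, e_max, limit, status):
        pairs = tuple(sorted(pairs))
        if not _window_distinct(pairs, acc_arr, window):
            continue
        accepted.append(
            SecondaryStructure(seq_id=seq.id, pairs=pairs, energy=e / 10.0)
        )
        if pairs:
            acc_arr = np.vstack([acc_arr, np.array(pairs, dtype=np.int64)])
        if max_count is not None and len(accepted) >= max_count:
            break
    if not accepted:
        accepted = [SecondaryStructure(seq_id=seq.id, pairs=(), energy=0.0)]
    return StructureEnsemble(
        seq_id=seq.id, structures=accepted, complete=not status["truncated"]
    )
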