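"""Partition functions, base-pair probabilities and ranked structures for the
non-crossing (secondary) ensemble of the effective one-strand system.

For every segment ``[a, b]`` the conformations are classified into six types
by the pairing status of the terminal nucleotides:

``coil``
    no base pairs at all; its partition function is exactly 1.0 — the empty
    structure is the reference state, so no initiation term ever appears.
``C``
    ``(a, b)`` themselves paired.
``L`` / ``R``
    only ``a`` (respectively only ``b``) paired, to some interior partner.
``LR``
    both termini paired, but not to each other.
``M``
    both termini unpaired and at least one base pair inside.

The total partition function of a segment is the sum over the six types.
Base-pair probabilities come from backtracking: the full chain starts with
probability 1.0 and partition-function ratios propagate outside weights down
the recursion (see :mod:`complexfold._grammar`).

All public indices (segments, pairs, matrices) are 1-based positions in the
effective sequence; the grammar works 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._grammar import Engine
from .energy_model import (
    EnergyModel,
    LoopDescriptor,
    coaxial_free_energy,
    loop_free_energy,
    stack_free_energy,
)
from .errors import StateError, ValidationError
from .sequence import EffectiveSequence

#: Partition function of the pair-free (coil) conformation of any segment.
COIL_PARTITION = 1.0

#: Initial probability assigned to the full chain when backtracking starts.
BACKTRACK_ROOT_PROBABILITY = 1.0

CONFORMATION_TYPES = ("coil", "C", "L", "R", "LR", "M")


@dataclass(frozen=True)
class Structure:
    """A set of base pairs (1-based, i < j) with its free energy in kcal/mol.

    ``crossing_pairs`` marks the pairs belonging to an intermolecular
    crossing helix; it is empty for purely secondary structures.
    """

    pairs: frozenset
    free_energy: float
    crossing_pairs: frozenset = frozenset()

    def sorted_pairs(self):
        return tuple(sorted(self.pairs))


class PairProbabilityMatrix:
    """Sparse upper-triangular matrix of pair probabilities (1-based)."""

    def __init__(self, n: int, probs: dict):
        self.n = n
        self._p = {k: float(v) for k, v in probs.items() if v > 0.0}

    def get(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        return self._p.get((i, j), 0.0)

    __call__ = get

    def items(self):
        return sorted(self._p.items())

    def row_sum(self, i: int) -> float:
        return sum(p for (a, b), p in self._p.items() if a == i or b == i)

    def to_dense(self) -> np.ndarray:
        m = np.zeros((self.n, self.n))
        for (i, j), p in self._p.items():
            m[i - 1, j - 1] = p
            m[j - 1, i - 1] = p
        return m


def _as_effective(seq) -> EffectiveSequence:
    if isinstance(seq, EffectiveSequence):
        return seq
    return EffectiveSequence.single(str(seq))


def _mask_to_internal(constraint_mask):
    if constraint_mask is None:
        return None
    return lambda i, j: constraint_mask(i + 1, j + 1)


class SegmentTables:
    """The six per-segment partition functions and their backtracking engine.

    Values are computed from constrained evaluations of the grammar and
    cached per segment; the full-chain tables are filled when the object is
    constructed so that backtracking can start immediately.
    """

    def __init__(self, seq, model: EnergyModel, constraint_mask=None):
        self.seq = _as_effective(seq)
        self.model = model
        self._allowed = _mask_to_internal(constraint_mask)
        self.n = self.seq.n
        self.engine = Engine(self.seq, model, allowed=self._allowed)
        self._z_cache = {}
        self._sub_engines = {}
        self._z_full = self.engine.z_total()
        self._complete = True

    @property
    def sequence_length(self) -> int:
        return self.n

    def linker_mask(self):
        return self.seq.linker_mask

    def _check_segment(self, a: int, b: int):
        if not (1 <= a <= b <= self.n):
            raise ValidationError(f"segment [{a}, {b}] outside 1..{self.n}")

    def _constrained_z(self, a0: int, b0: int, forced: frozenset) -> float:
        key = (a0, b0, forced)
        eng = self._sub_engines.get(key)
        if eng is None:
            eng = Engine(self.seq, self.model, allowed=self._allowed,
                         forced_unpaired=forced, region=(a0, b0))
            self._sub_engines[key] = eng
        return eng.z_total()

    def z(self, t: str, a: int, b: int) -> float:
        """Partition function of conformational type ``t`` on segment [a, b]."""
        if t not in CONFORMATION_TYPES:
            raise ValidationError(f"unknown conformational type {t!r}")
        self._check_segment(a, b)
        key = (t, a, b)
        if key in self._z_cache:
            return self._z_cache[key]
        a0, b0 = a - 1, b - 1
        if t == "coil":
            val = COIL_PARTITION
        elif t == "C":
            val = (self.engine.value(("B", a0, b0))
                   if self.engine.pairable(a0, b0) else 0.0)
        else:
            t00 = self._constrained_z(a0, b0, frozenset())
            tau = self._constrained_z(a0, b0, frozenset({a0}))
            tbu = self._constrained_z(a0, b0, frozenset({b0}))
            tab = self._constrained_z(a0, b0, frozenset({a0, b0}))
            if t == "L":
                val = tbu - tab
            elif t == "R":
                val = tau - tab
            elif t == "M":
                val = tab - COIL_PARTITION
            else:  # LR: both ends paired, but not with each other
                zc = self.z("C", a, b)
                val = t00 - tau - tbu + tab - zc
            val = max(val, 0.0)
        self._z_cache[key] = val
        return val

    def total(self, a: int, b: int) -> float:
        self._check_segment(a, b)
        return sum(self.z(t, a, b) for t in CONFORMATION_TYPES)

    @property
    def z_total_full(self) -> float:
        return self._z_full


def compute_partition_tables(seq, model: EnergyModel, constraint_mask=None) -> SegmentTables:
    """Fill the six-type partition function tables for ``seq``.

    ``seq`` may be an :class:`~complexfold.sequence.EffectiveSequence` or a
    plain RNA string (folded as a single strand).  ``constraint_mask`` is an
    optional predicate on 1-based pairs; returning False forbids the pair.
    The empty structure has weight 1, so the full-chain total equals 1.0
    exactly when no canonical pair fits.
    """
    return SegmentTables(seq, model, constraint_mask)


def total_partition(tables: SegmentTables, a: int, b: int) -> float:
    """Sum of the six conformational-type partition functions on [a, b]."""
    return tables.total(a, b)


def backtrack_pair_probabilities(tables: SegmentTables, model: EnergyModel = None) -> PairProbabilityMatrix:
    """Base-pair probabilities of the full chain by backtracking the tables."""
    if not getattr(tables, "_complete", False):
        raise StateError("partition tables are not complete")
    probs0 = tables.engine.pair_probabilities()
    return PairProbabilityMatrix(
        tables.n, {(i + 1, j + 1): p for (i, j), p in probs0.items()}
    )


def enumerate_probable_structures(tables: SegmentTables, model: EnergyModel = None, k: int = 10):
    """Up to ``k`` distinct structures in non-decreasing free energy.

    The first entry is the minimum-free-energy structure of the ensemble;
    ties are broken lexicographically on the sorted pair list.
    """
    if k < 1:
        raise ValidationError("k must be at least 1")
    model = model or tables.model
    out = []
    for dg, pairs0 in tables.engine.kbest(k):
        pairs = frozenset((i + 1, j + 1) for i, j in pairs0)
        out.append(Structure(pairs=pairs,
                             free_energy=structure_free_energy(tables.seq, pairs, model)))
    out.sort(key=lambda st: (st.free_energy, st.sorted_pairs()))
    return out


# ---------------------------------------------------------------------------
# Structure scoring
# ---------------------------------------------------------------------------

def _validate_pairs(seq: EffectiveSequence, pairs):
    seen = set()
    clean = []
    for i, j in pairs:
        if i > j:
            i, j = j, i
        if not (1 <= i < j <= seq.n):
            raise ValidationError(f"pair ({i}, {j}) outside the sequence")
        i0, j0 = i - 1, j - 1
        if seq.is_linker(i0) or seq.is_linker(j0):
            raise ValidationError(f"pair ({i}, {j}) involves a phantom-linker position")
        if i0 in seen or j0 in seen:
            raise ValidationError(f"position reused by pair ({i}, {j})")
        if not seq.can_pair(i0, j0):
            raise ValidationError(
                f"pair ({i}, {j}) is not allowed (non-canonical or below the "
                f"minimum hairpin span)"
            )
        seen.add(i0)
        seen.add(j0)
        clean.append((i0, j0))
    return sorted(clean)


def structure_free_energy(seq, structure, model: EnergyModel) -> float:
    """Additive free energy of a (non-crossing) structure on ``seq``.

    The sum of nearest-neighbor stack terms, loop terms (hairpin, bulge,
    internal, multiloop — all zero when the loop contains the phantom
    linker), and coaxial stacking terms at multiloop and exterior junctions
    where two helix ends are separated by fewer than two unpaired
    nucleotides.  The empty structure scores exactly 0.0: no initiation term
    is included, so complex free energies are relative to the two
    dissociated random coils.

    ``structure`` may be a :class:`Structure` or any iterable of 1-based
    pairs.  This scorer walks the loop decomposition of the pair set and is
    deliberately independent of the recursion engine; the test suite checks
    that both assign identical weights.
    """
    seq = _as_effective(seq)
    pairs_in = structure.pairs if isinstance(structure, Structure) else structure
    pairs = _validate_pairs(seq, pairs_in)
    if not pairs:
        return 0.0

    # nesting check + children map via a stack sweep
    children = {None: []}
    stack = [None]
    events = []
    for i, j in pairs:
        events.append((i, 0, (i, j)))
        events.append((j, 1, (i, j)))
    events.sort()
    for pos, kind, pr in events:
        if kind == 0:
            parent = stack[-1]
            children.setdefault(pr, [])
            children[parent].append(pr)
            stack.append(pr)
        else:
            if stack[-1] != pr:
                raise ValidationError(
                    f"pairs cross: {tuple(x + 1 for x in pr)} is not nested"
                )
            stack.pop()

    s = seq.bases
    total = 0.0

    def junction_coax(left_pair, right_pair, gap):
        # left_pair/right_pair already oriented adjacent-base-first
        if gap >= 2:
            return 0.0
        return coaxial_free_energy(model, left_pair, right_pair, gap)

    def loop_energy(closing, kids):
        nonlocal total
        if closing is None:
            # exterior region: no loop penalty, but flush/mismatch coaxial
            # stacking between consecutive top-level helices still applies
            for (k1, l1), (k2, l2) in zip(kids, kids[1:]):
                gap = k2 - l1 - 1
                total += junction_coax((s[l1], s[k1]), (s[k2], s[l2]), gap)
            return
        i, j = closing
        if not kids:
            if seq.linker_in(i + 1, j - 1):
                return
            total += loop_free_energy(
                model, LoopDescriptor("hairpin", (j - i - 1,), ((s[i], s[j]),))
            )
            return
        if len(kids) == 1:
            (k, l) = kids[0]
            if k == i + 1 and l == j - 1:
                total += stack_free_energy(model, (s[i], s[j]), (s[k], s[l]))
                return
            if seq.linker_in(i + 1, k - 1) or seq.linker_in(l + 1, j - 1):
                return
            s1, s2 = k - i - 1, j - l - 1
            if s1 == 0 or s2 == 0:
                total += loop_free_energy(
                    model, LoopDescriptor("bulge", (s1 + s2,),
                                          ((s[i], s[j]), (s[k], s[l])))
                )
            else:
                total += loop_free_energy(
                    model, LoopDescriptor("internal", (s1, s2),
                                          ((s[i], s[j]), (s[k], s[l])))
                )
            return
        # multiloop
        gaps = [kids[0][0] - i - 1]
        unpaired_regions = [(i + 1, kids[0][0] - 1)]
        for (k1, l1), (k2, l2) in zip(kids, kids[1:]):
            gaps.append(k2 - l1 - 1)
            unpaired_regions.append((l1 + 1, k2 - 1))
        gaps.append(j - kids[-1][1] - 1)
        unpaired_regions.append((kids[-1][1] + 1, j - 1))
        has_linker = any(seq.linker_in(lo, hi) for lo, hi in unpaired_regions)
        if not has_linker:
            closing_pairs = tuple([(s[i], s[j])] + [(s[k], s[l]) for k, l in kids])
            total += loop_free_energy(
                model, LoopDescriptor("multiloop", tuple(gaps), closing_pairs)
            )
        # junction coaxial terms (identical rule with or without the linker;
        # a gap containing the 3-nt linker is always >= 2 so never stacks)
        total += junction_coax((s[i], s[j]), (s[kids[0][0]], s[kids[0][1]]), gaps[0])
        for idx, ((k1, l1), (k2, l2)) in enumerate(zip(kids, kids[1:])):
            total += junction_coax((s[l1], s[k1]), (s[k2], s[l2]), gaps[idx + 1])
        k1, l1 = kids[-1]
        total += junction_coax((s[l1], s[k1]), (s[j], s[i]), gaps[-1])

    loop_energy(None, children[None])
    for pr in pairs:
        loop_energy(pr, children.get(pr, []))
    return total
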