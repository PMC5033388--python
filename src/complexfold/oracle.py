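"""Exhaustive-enumeration reference implementation and fixture generator.

The oracle lists every legal structure by direct recursion over pairing
choices — no dynamic programming, no sub-result sharing — and sums Boltzmann
weights explicitly.  Its independence from the recursion engine is what makes
the equivalence tests meaningful: the only component the two share is the
structure scorer (a single source of energetic truth) and the conformational
pairing rule itself.

Enumeration is guarded at 24 nt because the structure count grows
exponentially; the guard can be overridden explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .energy_model import EnergyModel
from .errors import CapabilityError, StateError, ValidationError
from .secondary_pf import Structure, structure_free_energy
from .sequence import EffectiveSequence

#: Default total-length guard for full enumeration.
LENGTH_GUARD = 24


@dataclass(frozen=True)
class EnumerationConstraints:
    """Constraints mirroring the engine's conformational definitions exactly."""

    min_hairpin: int = 3
    allow_crossing: str = "none"  # or "single_intermolecular_helix"
    required_helix: object = None  # a BindingMode, optional
    pair_predicate: object = None  # optional predicate on 1-based (i, j)

    def __post_init__(self):
        if self.allow_crossing not in ("none", "single_intermolecular_helix"):
            raise ValidationError(
                f"unknown crossing policy {self.allow_crossing!r}"
            )
        if self.min_hairpin != 3:
            raise ValidationError(
                "the engine folds with a fixed 3 nt minimum hairpin loop; the "
                "oracle mirrors it exactly"
            )
        if self.required_helix is not None and self.allow_crossing == "none":
            raise ValidationError("required_helix needs allow_crossing set")
        if self.allow_crossing != "none" and self.required_helix is None:
            raise ValidationError(
                "crossing enumeration is mode-conditional: pass the binding "
                "mode whose structures should be listed"
            )


def _as_effective(seq) -> EffectiveSequence:
    if isinstance(seq, EffectiveSequence):
        return seq
    return EffectiveSequence.single(str(seq))


def _candidate_pairs(seq: EffectiveSequence, constraints, excluded=frozenset()):
    out = []
    for i in range(seq.n):
        if i in excluded:
            continue
        for j in range(i + 1, seq.n):
            if j in excluded:
                continue
            if not seq.can_pair(i, j):
                continue
            if (constraints.pair_predicate is not None
                    and not constraints.pair_predicate(i + 1, j + 1)):
                continue
            out.append((i, j))
    return out


def _enumerate_noncrossing(candidates, lo, hi):
    """All mutually non-crossing subsets of ``candidates`` within [lo, hi].

    Plain interval recursion: position ``lo`` is either unpaired, or paired
    with some ``k``; the two sub-intervals are enumerated independently.
    Every structure is produced exactly once.
    """
    if lo > hi:
        return [frozenset()]
    result = []
    for rest in _enumerate_noncrossing(candidates, lo + 1, hi):
        result.append(rest)
    for (i, k) in candidates:
        if i != lo or k > hi:
            continue
        inner = _enumerate_noncrossing(candidates, lo + 1, k - 1)
        outer = _enumerate_noncrossing(candidates, k + 1, hi)
        for a in inner:
            for b in outer:
                result.append(a | b | {(i, k)})
    return result


def enumerate_structures(seq, constraints: EnumerationConstraints = None,
                         model: EnergyModel = None, override_guard: bool = False):
    """Complete, duplicate-free list of legal structures under ``constraints``.

    When ``model`` is given each structure carries its free energy (the
    shared scorer); otherwise free energies are NaN placeholders.  With
    ``required_helix`` set, every returned structure contains that helix and
    the remaining pairs avoid its positions.
    """
    seq = _as_effective(seq)
    constraints = constraints or EnumerationConstraints()
    if seq.l_tot > LENGTH_GUARD and not override_guard:
        raise CapabilityError(
            f"enumeration of {seq.l_tot} nt exceeds the {LENGTH_GUARD} nt guard; "
            f"pass override_guard=True to force it"
        )
    mode = constraints.required_helix
    excluded = frozenset()
    base_pairs = frozenset()
    if mode is not None:
        base_pairs = frozenset((i - 1, j - 1) for i, j in mode.helix_pairs)
        excluded = frozenset(p for ij in base_pairs for p in ij)
    candidates = _candidate_pairs(seq, constraints, excluded)
    out = []
    for rest in _enumerate_noncrossing(candidates, 0, seq.n - 1):
        pairs1 = frozenset((i + 1, j + 1) for i, j in rest | base_pairs)
        if model is not None:
            if mode is not None:
                from .complex_assembly import crossing_structure_free_energy

                rest1 = frozenset((i + 1, j + 1) for i, j in rest)
                dg = crossing_structure_free_energy(seq, rest1, mode, model)
            else:
                dg = structure_free_energy(seq, pairs1, model)
        else:
            dg = float("nan")
        out.append(Structure(
            pairs=pairs1,
            free_energy=dg,
            crossing_pairs=frozenset((i + 1, j + 1) for i, j in base_pairs),
        ))
    return out


def oracle_partition(structures, model: EnergyModel, temperature: float = None):
    """Boltzmann sum and exact pair fractions of an enumerated ensemble.

    Returns ``(Z, pair_fractions)`` with ``Z = sum(exp(-dG/RT))`` and
    ``pair_fractions[(i, j)]`` the weighted fraction of structures containing
    the (1-based) pair.
    """
    if not structures:
        raise StateError("cannot take the partition function of an empty list")
    rt = model.rt if temperature is None else 0.0019872 * temperature
    z = 0.0
    frac = {}
    for st in structures:
        if math.isinf(st.free_energy):
            continue
        w = math.exp(-st.free_energy / rt)
        z += w
        for pr in st.pairs:
            frac[pr] = frac.get(pr, 0.0) + w
    if z == 0.0:
        return 0.0, {}
    return z, {pr: w / z for pr, w in frac.items()}


def random_fixture(seed: int, length_a: int, length_b: int, gc_bias: float = 0.5):
    """Reproducible pair of random strands; identical seed, identical output.

    ``gc_bias`` is the probability of drawing from {G, C} (split evenly)
    versus {A, U}.
    """
    if length_a < 1 or length_b < 1:
        raise ValidationError("strand lengths must be at least 1")
    if not (0.0 <= gc_bias <= 1.0):
        raise ValidationError("gc_bias must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2, (1 - gc_bias) / 2]
    draw = lambda n: "".join(rng.choice(["G", "C", "A", "U"], size=n, p=probs))
    return draw(length_a), draw(length_b)
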