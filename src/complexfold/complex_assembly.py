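"""Two-strand assembly and the crossing-helix (binding mode) screen.

The two input strands are joined by the phantom linker into an effective
one-strand system whose total physical length L_tot gates three structural
ensembles:

* L_tot <= 300 nt: secondary (non-crossing) structures;
* L_tot <= 150 nt: additionally H-type pseudoknotted structures;
* L_tot <= 120 nt: additionally hairpin-hairpin kissing structures.

Crossing base pairs are restricted to a *single* contiguous intermolecular
helix — the binding mode B — optionally carrying one (1x1) internal loop or
one 1-nt bulge.  The screen is two-step: step 1 scores every candidate mode
by its partition function Z^B (the Boltzmann sum over all structures that
contain helix B, with every remaining intra- and inter-molecular pair
non-crossing and scored by the secondary engine, plus one motif-based
tertiary loop term for the whole pseudoknot/kissing motif).  The mode with
the largest Z^B is the most probable; step 2 computes conditional pair
probabilities p_ij^B = Z_ij^B / Z^B only for the retained top mode(s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from ._grammar import Engine
from .energy_model import (
    EnergyModel,
    INF,
    LoopDescriptor,
    TertiaryMotifDescriptor,
    load_energy_model,
    loop_free_energy,
    stack_free_energy,
    tertiary_loop_free_energy,
)
from .errors import OverLengthError, StateError, ValidationError
from .secondary_pf import (
    PairProbabilityMatrix,
    Structure,
    backtrack_pair_probabilities,
    compute_partition_tables,
    enumerate_probable_structures,
    structure_free_energy,
)
from .sequence import EffectiveSequence, concat_with_linker  # re-exported surface

#: Length gates (nt of L_tot) for the three structural ensembles.
SECONDARY_MAX_LTOT = 300
PSEUDOKNOT_MAX_LTOT = 150
KISSING_MAX_LTOT = 120

#: A binding-mode helix may carry at most one defect: a (1x1) internal loop
#: or a bulge of at most this many nucleotides.
MAX_DEFECT_BULGE_NT = 1

ENSEMBLE_SECONDARY = "secondary"
ENSEMBLE_PSEUDOKNOT = "h_pseudoknot"
ENSEMBLE_KISSING = "kissing"


@dataclass(frozen=True)
class EnsembleGate:
    ensembles: tuple
    status: str


def select_ensembles(l_tot: int) -> EnsembleGate:
    """Which structural ensembles the total length admits."""
    if l_tot < 2:
        raise ValidationError("a complex needs at least two nucleotides")
    if l_tot <= KISSING_MAX_LTOT:
        return EnsembleGate(
            (ENSEMBLE_SECONDARY, ENSEMBLE_PSEUDOKNOT, ENSEMBLE_KISSING),
            "all three ensembles admitted",
        )
    if l_tot <= PSEUDOKNOT_MAX_LTOT:
        return EnsembleGate(
            (ENSEMBLE_SECONDARY, ENSEMBLE_PSEUDOKNOT),
            "kissing ensemble skipped above "
            f"{KISSING_MAX_LTOT} nt",
        )
    if l_tot <= SECONDARY_MAX_LTOT:
        return EnsembleGate(
            (ENSEMBLE_SECONDARY,),
            f"crossing ensembles skipped above {PSEUDOKNOT_MAX_LTOT} nt",
        )
    return EnsembleGate(
        (),
        f"total length {l_tot} nt exceeds the {SECONDARY_MAX_LTOT} nt limit "
        f"of the secondary ensemble",
    )


@dataclass
class BindingMode:
    """One contiguous antiparallel intermolecular helix (1-based pairs).

    ``helix_pairs`` runs 5'->3' on strand A (ascending i) and therefore
    3'->5' on strand B (descending j).  ``defect`` is ``None`` or
    ``("internal_1x1", t)`` / ``("bulge_1nt", t, side)`` where the defect
    sits between helix pairs ``t-1`` and ``t`` (interior only) and ``side``
    is "A" or "B".  ``z_mode`` caches Z^B once scored.
    """

    helix_pairs: tuple
    defect: Optional[tuple] = None
    z_mode: Optional[float] = None

    def __post_init__(self):
        ps = tuple(tuple(p) for p in self.helix_pairs)
        object.__setattr__(self, "helix_pairs", ps)
        if len(ps) < 2:
            raise ValidationError("a binding-mode helix has at least 2 base pairs")
        is_ = [p[0] for p in ps]
        js = [p[1] for p in ps]
        if any(b <= a for a, b in zip(is_, is_[1:])) or any(
            b >= a for a, b in zip(js, js[1:])
        ):
            raise ValidationError("helix pairs must be strictly antiparallel")
        if self.defect is not None:
            t = self.defect[1]
            if not (1 <= t <= len(ps) - 1):
                raise ValidationError("a helix defect must be interior")

    @property
    def length(self) -> int:
        return len(self.helix_pairs)

    @property
    def positions(self) -> frozenset:
        return frozenset(p for ij in self.helix_pairs for p in ij)

    @property
    def a_window(self) -> tuple:
        return (self.helix_pairs[0][0], self.helix_pairs[-1][0])

    @property
    def b_window(self) -> tuple:
        return (self.helix_pairs[-1][1], self.helix_pairs[0][1])

    def sort_key(self) -> tuple:
        return (self.helix_pairs[0][0], self.b_window[0], self.length,
                self.defect or ())


@dataclass
class EnsembleResult:
    name: str
    partition_function: float
    structures: list
    pair_probabilities: Optional[PairProbabilityMatrix]
    modes: list = field(default_factory=list)  # (BindingMode, Z^B), ranked


@dataclass
class ComplexPrediction:
    """Per-ensemble results plus the free-energy-merged overall ranking."""

    seq: EffectiveSequence
    ensembles: dict
    merged: list  # (ensemble name, Structure), non-decreasing free energy
    gate: EnsembleGate
    options: dict


# ---------------------------------------------------------------------------
# Binding-mode enumeration
# ---------------------------------------------------------------------------

def _pairable_bases(seq: EffectiveSequence, i0: int, j0: int) -> bool:
    from .sequence import is_canonical

    return is_canonical(seq.bases[i0], seq.bases[j0])


def enumerate_binding_modes(seq: EffectiveSequence, min_helix_len: int = 3,
                            allow_defects: bool = False):
    """Every contiguous antiparallel intermolecular helix of canonical pairs.

    Modes are returned for all lengths >= ``min_helix_len`` (sub-helices of a
    longer complementary stretch are modes of their own).  With
    ``allow_defects`` the helix may contain exactly one (1x1) internal loop
    or one 1-nt bulge, interior only.  The list is duplicate-free.
    """
    if min_helix_len < 2:
        raise ValidationError("min_helix_len must be at least 2")
    lenA = seq.len_a
    sb = seq.strand_boundary  # 0-based first strand-B position
    n = seq.n
    seen = {}

    def emit(pairs0, defect):
        key = (tuple(pairs0), defect)
        if key in seen:
            return
        seen[key] = BindingMode(
            helix_pairs=tuple((i + 1, j + 1) for i, j in pairs0), defect=defect
        )

    def run(i0, j0, length):
        """Perfect block of `length` pairs starting (i0, j0), antiparallel."""
        return [(i0 + t, j0 - t) for t in range(length)]

    def block_ok(i0, j0, length):
        if i0 < 0 or i0 + length - 1 >= lenA:
            return False
        if j0 - length + 1 < sb or j0 >= n:
            return False
        return all(_pairable_bases(seq, i0 + t, j0 - t) for t in range(length))

    for i0 in range(lenA):
        for j0 in range(sb, n):
            # perfect helices
            length = min_helix_len
            while block_ok(i0, j0, length):
                emit(run(i0, j0, length), None)
                length += 1
            if not allow_defects:
                continue
            # one interior defect between blocks of l1 and l2 pairs
            for l1 in range(1, lenA):
                if not block_ok(i0, j0, l1):
                    break
                for kind in ("internal_1x1", "bulge_A", "bulge_B"):
                    if kind == "internal_1x1":
                        i2, j2 = i0 + l1 + 1, j0 - l1 - 1
                        defect_tag = ("internal_1x1", l1)
                    elif kind == "bulge_A":
                        i2, j2 = i0 + l1 + 1, j0 - l1
                        defect_tag = ("bulge_1nt", l1, "A")
                    else:
                        i2, j2 = i0 + l1, j0 - l1 - 1
                        defect_tag = ("bulge_1nt", l1, "B")
                    for l2 in range(1, lenA):
                        if l1 + l2 < min_helix_len:
                            continue
                        if not block_ok(i2, j2, l2):
                            break
                        emit(run(i0, j0, l1) + run(i2, j2, l2), defect_tag)
    return sorted(seen.values(), key=BindingMode.sort_key)


# ---------------------------------------------------------------------------
# Mode energetics
# ---------------------------------------------------------------------------

def _flanks(seq: EffectiveSequence, mode: BindingMode):
    """Unpaired flank lengths (nt) around the mode windows, strand-local."""
    lenA, lenB = seq.len_a, seq.len_b
    a_lo, a_hi = (x - 1 for x in mode.a_window)
    b_lo, b_hi = (x - 1 - seq.strand_boundary for x in mode.b_window)
    return (a_lo, lenA - 1 - a_hi, b_lo, lenB - 1 - b_hi)


def classify_mode(seq: EffectiveSequence, mode: BindingMode) -> str:
    """Kissing when both strands can close hairpins around the mode helix
    (at least one stem pair plus one loop nucleotide on each side of the
    helix window on each strand); H-type pseudoknot otherwise."""
    f5a, f3a, f5b, f3b = _flanks(seq, mode)
    if min(f5a, f3a, f5b, f3b) >= 2:
        return ENSEMBLE_KISSING
    return ENSEMBLE_PSEUDOKNOT


def mode_motif(seq: EffectiveSequence, mode: BindingMode) -> TertiaryMotifDescriptor:
    """Coarse, mode-level motif descriptor used for the tertiary loop term.

    Loop lengths are read off the strand geometry around the helix windows
    (not off any particular scaffold structure), so the motif term is a
    constant per mode and Z^B factorises over the secondary scaffold.
    """
    f5a, f3a, f5b, f3b = _flanks(seq, mode)
    cls = classify_mode(seq, mode)
    if cls == ENSEMBLE_KISSING:
        # reserve one stem nucleotide per side; the rest is kissing loop
        loops = (f5a + f3a - 2, f5b + f3b - 2)
    else:
        # spanning loops run from the helix to the strand junction
        loops = (f3a, f5b)
    return TertiaryMotifDescriptor(
        motif_class="kissing_hairpins" if cls == ENSEMBLE_KISSING else "h_pseudoknot",
        helix_lengths=(mode.length,),
        loop_lengths=loops,
    )


def mode_helix_free_energy(seq: EffectiveSequence, mode: BindingMode,
                           model: EnergyModel) -> float:
    """Stacking free energy of the mode helix plus its (optional) defect."""
    s = seq.bases
    dg = 0.0
    for (i1, j1), (i2, j2) in zip(mode.helix_pairs, mode.helix_pairs[1:]):
        a, b, c, d = i1 - 1, j1 - 1, i2 - 1, j2 - 1
        if i2 == i1 + 1 and j2 == j1 - 1:
            dg += stack_free_energy(model, (s[a], s[b]), (s[c], s[d]))
        else:  # the defect junction: no stack across it, a loop term instead
            if mode.defect and mode.defect[0] == "internal_1x1":
                dg += loop_free_energy(
                    model,
                    LoopDescriptor("internal", (1, 1),
                                   ((s[a], s[b]), (s[c], s[d]))),
                )
            else:
                dg += loop_free_energy(
                    model,
                    LoopDescriptor("bulge", (1,),
                                   ((s[a], s[b]), (s[c], s[d]))),
                )
    return dg


def crossing_structure_free_energy(seq: EffectiveSequence, rest_pairs, mode: BindingMode,
                                   model: EnergyModel) -> float:
    """Free energy of a crossing structure: secondary scaffold + mode helix.

    The scaffold (every pair except the crossing helix) is scored by the
    ordinary secondary decomposition with the helix positions treated as
    unpaired; the non-additive correction for the crossing motif enters once,
    through the motif-based tertiary loop term.
    """
    dg_rest = structure_free_energy(seq, rest_pairs, model)
    dg_helix = mode_helix_free_energy(seq, mode, model)
    dg_tert = tertiary_loop_free_energy(model, mode_motif(seq, mode))
    return dg_rest + dg_helix + dg_tert


def _mode_engine(seq: EffectiveSequence, mode: BindingMode, model: EnergyModel) -> Engine:
    blocked = frozenset(p - 1 for p in mode.positions)
    return Engine(seq, model,
                  allowed=lambda i, j: i not in blocked and j not in blocked)


def mode_partition_function(seq: EffectiveSequence, mode: BindingMode,
                            model: EnergyModel, ensemble: str = None) -> float:
    """Z^B: Boltzmann sum over all structures containing helix B.

    Zero when the motif is geometrically impossible (infinite-penalty
    sentinel) or when the mode's motif class does not match the requested
    ensemble.
    """
    cls = classify_mode(seq, mode)
    if ensemble is not None and ensemble != cls:
        return 0.0
    dg_mode = (mode_helix_free_energy(seq, mode, model)
               + tertiary_loop_free_energy(model, mode_motif(seq, mode)))
    if dg_mode == INF:
        return 0.0
    z_rest = _mode_engine(seq, mode, model).z_total()
    z = model.boltzmann(dg_mode) * z_rest
    mode.z_mode = z
    return z


def conditional_pair_probabilities(seq: EffectiveSequence, mode: BindingMode,
                                   model: EnergyModel) -> PairProbabilityMatrix:
    """p_ij^B = Z_ij^B / Z^B for all non-crossing pairs, given mode B.

    Pairs of helix B itself have probability exactly 1 (every structure of
    the mode contains them); linker and helix positions otherwise have 0.
    """
    if mode_partition_function(seq, mode, model) <= 0.0:
        raise StateError("Z^B is zero; conditional probabilities are undefined")
    eng = _mode_engine(seq, mode, model)
    eng.z_total()
    probs = {(i + 1, j + 1): p for (i, j), p in eng.pair_probabilities().items()}
    for pr in mode.helix_pairs:
        probs[pr] = 1.0
    return PairProbabilityMatrix(seq.n, probs)


def _mode_structures(seq, mode, model, k):
    eng = _mode_engine(seq, mode, model)
    dg_helix = mode_helix_free_energy(seq, mode, model)
    dg_tert = tertiary_loop_free_energy(model, mode_motif(seq, mode))
    out = []
    for dg0, rest0 in eng.kbest(k):
        rest = frozenset((i + 1, j + 1) for i, j in rest0)
        dg = structure_free_energy(seq, rest, model) + dg_helix + dg_tert
        out.append(Structure(
            pairs=rest | frozenset(mode.helix_pairs),
            free_energy=dg,
            crossing_pairs=frozenset(mode.helix_pairs),
        ))
    return out


# ---------------------------------------------------------------------------
# End-to-end prediction
# ---------------------------------------------------------------------------

def predict_complex(seq_a: str, seq_b: str, *, temperature: float = 37.0,
                    parameter_set: str = "turner04", top_k_structures: int = 10,
                    top_modes_retained: int = 1, min_helix_len: int = 3,
                    allow_defects: bool = True,
                    model: EnergyModel = None) -> ComplexPrediction:
    """Run the length gate, the secondary engine, and the two-step screen.

    Step 1 computes Z^B for every binding mode of each admitted crossing
    ensemble; step 2 backtracks conditional pair probabilities and ranked
    structures only for the ``top_modes_retained`` most probable modes.
    The merged ranking orders all ensembles' structures by free energy.
    """
    seq = concat_with_linker(seq_a, seq_b)
    gate = select_ensembles(seq.l_tot)
    if not gate.ensembles:
        raise OverLengthError(gate.status)
    if model is None:
        model = load_energy_model(parameter_set, temperature)

    ensembles = {}
    merged = []

    tables = compute_partition_tables(seq, model)
    sec_structs = enumerate_probable_structures(tables, model, top_k_structures)
    ensembles[ENSEMBLE_SECONDARY] = EnsembleResult(
        name=ENSEMBLE_SECONDARY,
        partition_function=tables.z_total_full,
        structures=sec_structs,
        pair_probabilities=backtrack_pair_probabilities(tables),
    )
    merged += [(ENSEMBLE_SECONDARY, st) for st in sec_structs]

    crossing = [e for e in gate.ensembles if e != ENSEMBLE_SECONDARY]
    if crossing:
        modes = enumerate_binding_modes(seq, min_helix_len, allow_defects)
        for ens in crossing:
            scored = []
            for mode in modes:
                z = mode_partition_function(seq, mode, model, ensemble=ens)
                if z > 0.0:
                    scored.append((mode, z))
            scored.sort(key=lambda mz: (-mz[1],) + mz[0].sort_key())
            retained = scored[:top_modes_retained]
            structs = []
            probs = None
            for mode, _z in retained:
                structs += _mode_structures(seq, mode, model, top_k_structures)
            structs.sort(key=lambda st: (st.free_energy, st.sorted_pairs()))
            structs = structs[:top_k_structures]
            if retained:
                probs = conditional_pair_probabilities(seq, retained[0][0], model)
            ensembles[ens] = EnsembleResult(
                name=ens,
                partition_function=sum(z for _m, z in scored),
                structures=structs,
                pair_probabilities=probs,
                modes=scored,
            )
            merged += [(ens, st) for st in structs]

    merged.sort(key=lambda e: (e[1].free_energy, e[1].sorted_pairs()))
    return ComplexPrediction(
        seq=seq,
        ensembles=ensembles,
        merged=merged[:top_k_structures],
        gate=gate,
        options=dict(temperature=temperature, parameter_set=parameter_set,
                     top_k_structures=top_k_structures,
                     top_modes_retained=top_modes_retained,
                     min_helix_len=min_helix_len, allow_defects=allow_defects),
    )
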