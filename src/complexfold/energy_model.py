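"""Thermodynamic model: stacks, loops, coaxial stacks, tertiary-loop motifs.

The model is additive nearest-neighbor: helix stability comes from stacked
base-pair doublets, loops carry length-dependent penalties, helix ends
separated by fewer than two unpaired nucleotides may stack coaxially, and
whole pseudoknot / kissing motifs receive a single motif-based tertiary loop
term supplied by a pluggable provider.

Two parameter sets ship as plain-text tables (``params/turner04.txt``,
``params/mfold23.txt``).  The turner04 set stores enthalpies and therefore
supports temperature extrapolation dG(T) = dH - T*dS; the mfold23 set is
dG37-only and refuses other temperatures.

A *forbidden* motif is signalled by the explicit infinite-penalty sentinel
:data:`INF` (its Boltzmann weight is exactly zero), never by a missing entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

from .errors import CapabilityError, ConfigurationError, ValidationError
from .sequence import CANONICAL_PAIRS

#: Gas constant in kcal/mol/K.
R_KCAL = 0.0019872

#: Reference temperature (37 C) in kelvin.
T37 = 310.15

#: Infinite-penalty sentinel for forbidden motifs.
INF = math.inf

#: Two helix ends stack coaxially only when separated by fewer than this
#: many unpaired nucleotides.
COAXIAL_GAP_LIMIT = 2

PARAMETER_SETS = ("turner04", "mfold23")

_PAIR_STR = {"".join(p) for p in CANONICAL_PAIRS}


def _as_pair(p) -> tuple:
    """Normalise a base pair given as 'GC' or ('G', 'C'); validate it."""
    if isinstance(p, str):
        t = tuple(p.upper())
    else:
        t = tuple(str(x).upper() for x in p)
    if len(t) != 2 or t not in CANONICAL_PAIRS:
        raise ValidationError(f"{p!r} is not a canonical base pair")
    return t


def _rev(p: tuple) -> tuple:
    return (p[1], p[0])


@dataclass(frozen=True)
class LoopDescriptor:
    """One secondary-structure loop.

    ``lengths`` holds the unpaired-nucleotide count of each loop segment
    (one for a hairpin, two for an internal loop, one per gap for a
    multiloop); ``closing_pairs`` the base pairs bounding the loop, as base
    tuples.  ``contains_linker`` marks loops threaded by the phantom linker,
    which are not physical loops and contribute zero free energy.
    """

    loop_class: str
    lengths: tuple
    closing_pairs: tuple = ()
    contains_linker: bool = False

    def __post_init__(self):
        if self.loop_class not in ("hairpin", "bulge", "internal", "multiloop", "exterior"):
            raise ValidationError(f"unknown loop class {self.loop_class!r}")
        if any(l < 0 for l in self.lengths):
            raise ValidationError("loop segment lengths must be non-negative")
        if self.loop_class == "hairpin" and len(self.lengths) != 1:
            raise ValidationError("a hairpin has exactly one loop segment")
        if self.loop_class == "internal" and len(self.lengths) != 2:
            raise ValidationError("an internal loop has exactly two segments")
        if self.loop_class == "multiloop" and self.closing_pairs and len(self.closing_pairs) < 3:
            raise ValidationError("a multiloop has at least three closing pairs")


@dataclass(frozen=True)
class TertiaryMotifDescriptor:
    """A whole crossing motif: H-type pseudoknot or kissing hairpins.

    ``helix_lengths`` are the base-pair counts of the participating helices
    (the intermolecular crossing helix first); ``loop_lengths`` the unpaired
    counts of the loops spanning them.  What makes the motif tertiary is that
    at least one loop spans a helix.
    """

    motif_class: str
    helix_lengths: tuple
    loop_lengths: tuple

    def __post_init__(self):
        if self.motif_class not in ("h_pseudoknot", "kissing_hairpins"):
            raise ValidationError(f"unknown motif class {self.motif_class!r}")
        if any(h < 1 for h in self.helix_lengths) or any(l < 0 for l in self.loop_lengths):
            raise ValidationError("motif lengths must be non-negative (helices >= 1 bp)")
        if not self.loop_lengths:
            raise ValidationError("a tertiary motif has at least one spanning loop")


def min_spanning_loop(helix_bp: int) -> int:
    """Smallest loop (nt) that can physically span a helix of ``helix_bp``.

    Coarse geometric rule: one loop nucleotide bridges roughly three stacked
    base pairs of A-form helix, with a one-nucleotide floor.
    """
    return max(1, math.ceil(helix_bp / 3))


@dataclass
class TertiaryLoopProvider:
    """Lookup table + fallback for motif-based tertiary loop free energies.

    ``entries`` maps discretised motif descriptors to dG37 values (kcal/mol);
    the table ships empty and exists as a seam for externally computed,
    structure-based loop parameters.  When ``fallback_enabled`` the provider
    is total: missing motifs are scored by a polymer-entropy closed form

        dG(T) = R * T * (offset + slope * ln(total loop nt)),

    a Jacobson-Stockmayer-style approximation whose coefficients are package
    defaults, not derived from any structure-based sampling.
    """

    entries: dict = field(default_factory=dict)
    fallback_enabled: bool = True
    fallback_coefficients: tuple = (4.5, 1.75)

    def free_energy(self, motif: TertiaryMotifDescriptor, temperature: float) -> float:
        h = motif.helix_lengths[0]
        if any(l < min_spanning_loop(h) for l in motif.loop_lengths):
            return INF  # geometrically impossible: a loop cannot span its helix
        key = (motif.motif_class, tuple(motif.helix_lengths), tuple(motif.loop_lengths))
        if key in self.entries:
            return self.entries[key] * temperature / T37
        if not self.fallback_enabled:
            raise CapabilityError(
                f"no tertiary loop entry for {key} and the fallback is disabled"
            )
        offset, slope = self.fallback_coefficients
        total = sum(motif.loop_lengths)
        return R_KCAL * temperature * (offset + slope * math.log(total))


@dataclass
class EnergyModel:
    """Temperature-resolved thermodynamic parameter bundle."""

    parameter_set_id: str
    temperature: float  # kelvin
    stack_table: dict  # (outer pair, inner pair) -> dG(T), fully expanded
    hairpin_init: dict
    bulge_init: dict
    internal_init: dict
    internal_asym_coef: float
    internal_asym_max: float
    multiloop_params: tuple  # (a, b, c) in kcal/mol at model temperature
    coax_mismatch_factor: float
    tertiary_provider: TertiaryLoopProvider = field(default_factory=TertiaryLoopProvider)
    #: Jacobson-Stockmayer extrapolation of loop tables beyond their largest
    #: tabulated length; disabled in zeroed models so every weight is exactly 1.
    long_loop_extension: bool = True

    @property
    def rt(self) -> float:
        """R*T in kcal/mol."""
        return R_KCAL * self.temperature

    def boltzmann(self, dg: float) -> float:
        return 0.0 if dg == INF else math.exp(-dg / self.rt)

    def zeroed(self) -> "EnergyModel":
        """A copy with every free-energy contribution forced to zero.

        The conformational rules (canonical pairs, minimum hairpin size) are
        untouched, so the partition function of the zeroed model counts legal
        structures.
        """
        return EnergyModel(
            parameter_set_id=self.parameter_set_id + "+zeroed",
            temperature=self.temperature,
            stack_table={k: 0.0 for k in self.stack_table},
            hairpin_init={k: 0.0 for k in self.hairpin_init},
            bulge_init={k: 0.0 for k in self.bulge_init},
            internal_init={k: 0.0 for k in self.internal_init},
            internal_asym_coef=0.0,
            internal_asym_max=0.0,
            multiloop_params=(0.0, 0.0, 0.0),
            coax_mismatch_factor=0.0,
            tertiary_provider=TertiaryLoopProvider(
                entries={}, fallback_enabled=True, fallback_coefficients=(0.0, 0.0)
            ),
            long_loop_extension=False,
        )


def _parse_table(text: str) -> dict:
    data = {"meta": {}, "stack": {}, "hairpin": {}, "bulge": {}, "internal": {}, "param": {}}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        kind = parts[0]
        if kind == "meta":
            data["meta"][parts[1]] = parts[2]
        elif kind == "stack":
            outer, inner = _as_pair(parts[1]), _as_pair(parts[2])
            dg37 = float(parts[3])
            dh = None if parts[4] == "NA" else float(parts[4])
            data["stack"][(outer, inner)] = (dg37, dh)
        elif kind in ("hairpin", "bulge", "internal"):
            data[kind][int(parts[1])] = float(parts[2])
        elif kind == "param":
            data["param"][parts[1]] = float(parts[2])
        else:
            raise ConfigurationError(f"parameter file line {lineno}: unknown record {kind!r}")
    return data


def _load_raw(parameter_set: str) -> dict:
    if parameter_set not in PARAMETER_SETS:
        raise ConfigurationError(
            f"unknown parameter set {parameter_set!r}; supported: {', '.join(PARAMETER_SETS)}"
        )
    text = resources.files("complexfold.params").joinpath(f"{parameter_set}.txt").read_text()
    return _parse_table(text)


def load_energy_model(parameter_set: str, temperature_celsius: float = 37.0) -> EnergyModel:
    """Load a parameter set at the requested temperature.

    Raises :class:`ConfigurationError` for an unknown set,
    :class:`ValidationError` for temperatures outside [0, 100] C, and
    :class:`CapabilityError` when a dG37-only table is asked for any
    temperature other than 37 C.
    """
    raw = _load_raw(parameter_set)
    if not (0.0 <= temperature_celsius <= 100.0):
        raise ValidationError(
            f"temperature {temperature_celsius} C outside the supported range [0, 100]"
        )
    temp_k = temperature_celsius + 273.15
    has_dh = raw["meta"].get("has_enthalpy", "false") == "true"
    if not has_dh and abs(temp_k - T37) > 1e-9:
        raise CapabilityError(
            f"parameter set {parameter_set!r} stores dG37 only and cannot be "
            f"extrapolated to {temperature_celsius} C"
        )

    # Expand the 21 stored symmetry classes to all 36 ordered doublets.
    stacks = {}
    for (outer, inner), (dg37, dh) in raw["stack"].items():
        if dh is not None:
            ds = (dh - dg37) / T37
            dg = dh - temp_k * ds
        else:
            dg = dg37
        stacks[(outer, inner)] = dg
        stacks[(_rev(inner), _rev(outer))] = dg
    for outer in CANONICAL_PAIRS:
        for inner in CANONICAL_PAIRS:
            if (outer, inner) not in stacks:
                raise ConfigurationError(
                    f"parameter set {parameter_set!r} is missing stack {outer}/{inner}"
                )

    scale = temp_k / T37  # entropic rescaling of dG37-parameterised loop terms
    p = raw["param"]
    return EnergyModel(
        parameter_set_id=parameter_set,
        temperature=temp_k,
        stack_table=stacks,
        hairpin_init={k: v * scale for k, v in raw["hairpin"].items()},
        bulge_init={k: v * scale for k, v in raw["bulge"].items()},
        internal_init={k: v * scale for k, v in raw["internal"].items()},
        internal_asym_coef=p["internal_asym_coef"] * scale,
        internal_asym_max=p["internal_asym_max"] * scale,
        multiloop_params=(p["ml_a"] * scale, p["ml_b"] * scale, p["ml_c"] * scale),
        coax_mismatch_factor=p["coax_mismatch_factor"],
    )


def stack_free_energy(model: EnergyModel, pair_outer, pair_inner) -> float:
    """Free energy of the doublet 5'-outer[0] inner[0]-3' / 3'-outer[1] inner[1]-5'.

    Both pairs must be canonical; the table obeys the reverse-orientation
    symmetry stack(o, i) == stack(rev(i), rev(o)).
    """
    outer = _as_pair(pair_outer)
    inner = _as_pair(pair_inner)
    return model.stack_table[(outer, inner)]


def _length_indexed(table: dict, length: int, rt: float, extend: bool = True) -> float:
    """Table lookup with Jacobson-Stockmayer extrapolation beyond the table."""
    if length in table:
        return table[length]
    lmax = max(table)
    if length < min(table):
        return INF
    if not extend:
        return table[lmax]
    return table[lmax] + 1.75 * rt * math.log(length / lmax)


def loop_free_energy(model: EnergyModel, loop: LoopDescriptor) -> float:
    """Free energy of one loop; linker-containing loops contribute exactly 0."""
    if loop.contains_linker:
        return 0.0
    if loop.loop_class == "exterior":
        return 0.0
    if loop.loop_class == "hairpin":
        (length,) = loop.lengths
        if length < 3:
            raise ValidationError(
                f"hairpin loop of {length} nt without a linker is below the 3 nt minimum"
            )
        return _length_indexed(model.hairpin_init, length, model.rt,
                               model.long_loop_extension)
    if loop.loop_class == "bulge":
        (length,) = loop.lengths
        if length < 1:
            raise ValidationError("a bulge loop has at least one unpaired nucleotide")
        return _length_indexed(model.bulge_init, length, model.rt,
                               model.long_loop_extension)
    if loop.loop_class == "internal":
        l1, l2 = loop.lengths
        if l1 < 1 or l2 < 1:
            raise ValidationError("both internal loop segments must be non-empty")
        init = _length_indexed(model.internal_init, l1 + l2, model.rt,
                               model.long_loop_extension)
        asym = min(model.internal_asym_max, model.internal_asym_coef * abs(l1 - l2))
        return init + asym
    # multiloop: linear model a + b * branches + c * unpaired
    a, b, c = model.multiloop_params
    branches = len(loop.closing_pairs)
    return a + b * branches + c * sum(loop.lengths)


def coaxial_free_energy(model: EnergyModel, helix_end_1, helix_end_2, gap_nt: int) -> float:
    """Coaxial stacking between two helix ends separated by ``gap_nt`` unpaired nt.

    Each end is given as (junction-adjacent base, partner base).  A flush
    junction (gap 0) is scored as the corresponding nearest-neighbor stack;
    a 1-nt gap as that value scaled by the mismatch factor; gaps of 2 or more
    do not stack (exactly 0).
    """
    if gap_nt < 0:
        raise ValidationError("gap between helix ends cannot be negative")
    e1 = _as_pair(helix_end_1)
    e2 = _as_pair(helix_end_2)
    if gap_nt >= COAXIAL_GAP_LIMIT:
        return 0.0
    flush = model.stack_table[(e1, e2)]
    if gap_nt == 0:
        return flush
    return model.coax_mismatch_factor * flush


def tertiary_loop_free_energy(model: EnergyModel, motif: TertiaryMotifDescriptor) -> float:
    """Motif-based free energy of a whole pseudoknot/kissing loop motif."""
    return model.tertiary_provider.free_energy(motif, model.temperature)
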