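# Methods

## The effective one-strand system

Two RNA strands are concatenated through a three-nucleotide phantom linker.
The linker positions are unpairable; a loop whose unpaired region contains a
linker position is not a physical loop and contributes zero enthalpy and
entropy, which makes such regions behave like exterior loop. Because the
linker is three nucleotides wide, a pair may close directly across it with no
minimum-loop restriction (that is how a blunt intermolecular duplex arises),
and no junction spanning the linker can ever satisfy the coaxial-stacking
distance. The strand-association initiation free energy is assumed
sequence-independent and is omitted entirely: the empty structure defines the
zero of free energy, and the ensemble partition function of an unpairable
chain is exactly 1.

## Energy model

Additive nearest-neighbor thermodynamics:

* **Stacks.** 21 symmetry-distinct doublets over the canonical pairs
  {AU, UA, GC, CG, GU, UG}, shipped as plain-text tables. `turner04` stores
  (ΔG37, ΔH) per doublet and extrapolates as ΔG(T) = ΔH − TΔS with
  ΔS = (ΔH − ΔG37)/310.15; `mfold23` is ΔG37-only and raises a capability
  error at any other temperature. The Watson–Crick entries of `turner04`
  follow the published 2004 values; a minority of GU-wobble entries in both
  sets are the package's own transcription choices (see the parameter file
  comments) — the tests assert consistency with the shipped files, not with
  any external source.
* **Loops.** Length-indexed hairpin/bulge/internal initiation tables
  (internal loops add an asymmetry penalty, 0.6 kcal/mol per nt capped at
  3.0 for `turner04`), extended beyond the largest tabulated length by the
  Jacobson–Stockmayer form ΔG(ℓ) = ΔG(ℓmax) + 1.75·RT·ln(ℓ/ℓmax). Loop
  terms are treated as purely entropic, so they scale as T/310.15.
  Multiloops use the linear model a + b·(closing pairs) + c·(unpaired nt).
* **Coaxial stacking.** Two helix ends separated by fewer than 2 unpaired
  nucleotides stack; a flush junction scores the corresponding
  nearest-neighbor doublet and a 1-nt-mediated junction scores half of it
  (configurable factor). Applied at multiloop and exterior junctions;
  dangling ends and terminal-AU penalties are deliberately omitted in this
  version so that the scorer and the exhaustive oracle stay tractable and
  bit-identical. 1-nt bulges score only the bulge initiation term (no
  flanking stack bonus).
* **Minimum hairpin loop** is 3 unpaired nt; lonely (isolated) pairs are
  permitted, so the engine's state space coincides with plain enumeration
  over pair sets.

A forbidden motif always carries an explicit infinite-penalty sentinel whose
Boltzmann weight is exactly zero; absence from a table is a configuration
error, never a silent zero.

## Partition function and backtracking

All quantities are evaluated over a single unambiguous derivation grammar:
every legal secondary structure corresponds to exactly one derivation. Pair
nodes choose the loop closed by the pair (hairpin, stack, bulge/internal, or
multiloop); fill nodes scan a region left-to-right placing helix branches,
carrying just enough state for the junction terms — the identity and distance
(1 or 2 nt) of the nearest helix end to the left, the minimum number of
branches still owed, and whether a multiloop spanning the linker still has to
bury it inside a branch (a physical multiloop whose loop would contain the
linker is instead scored as the zero-energy, exterior-like variant; the two
cases are disjoint derivations, so nothing is double counted).

One grammar, three evaluations:

* **sum-product** gives segment partition functions. The six conformational
  types of a segment (coil / C / L / R / LR / M, classified by the pairing
  status of the terminal bases) are obtained from constrained evaluations:
  forcing one or both termini unpaired and taking inclusion–exclusion
  differences. Type M is implemented as "both termini unpaired and at least
  one pair": with lonely pairs permitted this is the only reading under
  which the six types partition the ensemble and their sum reproduces the
  total; under a no-lonely-pair convention it coincides with requiring two
  pairs.
* **reverse (adjoint) pass** implements the backtracking: the root carries
  outside weight 1.0, each recursion term pushes outside weight down to its
  children, and the probability of pair (i, j) is its outside weight times
  its inside value over Z. This is the outside algorithm of the grammar and
  agrees with enumeration to ~1e-14 in practice (tested at 1e-9).
* **k-best** evaluates the same terms over sorted candidate lists, yielding
  the exact k lowest-free-energy structures with deterministic
  lexicographic tie-breaking on the sorted pair list. Because the grammar is
  unambiguous the list is duplicate-free and rank 1 is the exact MFE
  structure. This replaces stochastic backtracking with deduplication: a
  sampler cannot guarantee the rank-1 contract, and at the k values used
  here exact evaluation is cheaper than sampling deeply enough to be safe.

Numerics: plain double precision throughout. Partition functions grow as
e^(−ΔG/RT); beyond roughly 250–300 nt of strongly pairing sequence the sums
can exceed the double range, in which case the engine raises an overflow
rather than degrading silently. The tested and gated regime (≤ 300 nt
total, toy-scale oracle comparisons) stays far from that limit. All
equivalence tests use 1e-9 relative tolerance.

## The crossing-helix screen

Crossing base pairs are restricted to one contiguous antiparallel
intermolecular helix (the binding mode), optionally with one interior defect:
a 1×1 internal loop or a 1-nt bulge, scored with the ordinary internal/bulge
terms and no stack across the defect. Mode enumeration lists every canonical
helix of at least `min_helix_len` (default 3) base pairs, including
sub-helices of longer complementary stretches.

For a structure containing mode B, the free energy decomposes as

    ΔG = ΔG_secondary(scaffold) + ΔG_stack(B) + ΔG_defect(B) + ΔG_tertiary(motif)

where the scaffold (all non-B pairs) is scored by the secondary engine with
B's positions treated as unpaired, and the non-additivity of the crossing
motif is carried entirely by the single motif-based tertiary term. The motif
descriptor is **mode-geometric**: its loop lengths are read off the strand
flanks around the helix windows, not off the scaffold, so the tertiary term
is constant per mode and Z^B factorises into (mode weight) × (scaffold
partition function under the mode mask). A mode is classed *kissing* when
both strands retain at least 2 nt on both sides of their helix window
(room for one stem pair plus one loop nucleotide), *H-type pseudoknot*
otherwise; kissing loop lengths reserve one stem nucleotide per side, and
pseudoknot loops run from the helix to the strand junction. Z^B deliberately
includes scaffolds that happen not to cross B — the screen conditions on
"contains helix B", which is also what the restricted oracle enumerates.

Geometric feasibility: a loop of ℓ nt can span a helix of h bp only if
ℓ ≥ ⌈h/3⌉ (roughly one bridging nucleotide per three stacked pairs, with a
1-nt floor); infeasible motifs get the infinite sentinel and Z^B = 0.

**Tertiary loop free energies.** The structure-based loop-entropy tables the
motif term is designed for are external to this package; the provider is a
seam (`TertiaryLoopProvider.entries`, keyed by motif class, helix lengths
and discretised loop lengths) into which such tables can be dropped
verbatim. Until then a documented polymer-entropy fallback is used:
ΔG = RT·(A + B·ln ℓ_total) with package defaults (A, B) = (4.5, 1.75).
These are generic Jacobson–Stockmayer-style coefficients, not derived from
any conformational sampling; absolute kissing/pseudoknot stabilities are
therefore coarse, while everything upstream of the motif term (mode
enumeration, Z^B factorisation, conditional probabilities, ranking) is
exact with respect to the model and is what the oracle tests pin down.

The screen is two-step: step 1 scores every mode's Z^B with the full
secondary thermodynamics (no reduced model); step 2 computes conditional
pair probabilities and ranked structures only for the retained top mode(s)
(default 1). Ties in Z^B break lexicographically on (strand-A start,
strand-B start, length). Length gates: secondary ≤ 300 nt, + pseudoknot
≤ 150 nt, + kissing ≤ 120 nt of L_tot; above 300 nt the gate returns an
explanatory status and `predict_complex` raises an over-length error.

## Synthetic fixtures and what the tests show

`random_fixture(seed, len_a, len_b, gc_bias)` draws i.i.d. nucleotides with
a given GC probability (default 0.5, an unbiased composition). The
equivalence suites run ~200 such fixtures at 6–14 nt total plus toy
kissing/pseudoknot constructs at ≤ 24 nt — sizes at which *every* structure
can be enumerated, so agreement is checked against ground truth rather than
against another heuristic. These fixtures exercise the complete recursion
logic (every loop type, the linker rules, coaxial junctions, defects) but
they do not probe real-RNA features: no sequence conservation, no modified
bases, no tertiary interactions beyond the single crossing helix, and loop
thermodynamics only as accurate as the tables above. Passing tests therefore
establish that the implementation computes its stated model exactly, not
that the model's absolute free energies match experiment for long natural
sequences.

Problem sizes in the shipped tests and the acceptance script (200 fixtures
of 6–14 nt; 24-nt toy complexes; full mode screens of ~280 modes) were
chosen so every claim is verified against complete enumeration.

## Known limitations

* Lonely (isolated) base pairs are always permitted; there is no
  no-lonely-pairs mode in this version.
* Tertiary loop energies are surrogate (see above); ranking between the
  secondary and crossing ensembles shifts if real motif tables are plugged
  into the provider.
* No dangling ends, terminal-AU penalties, or special hairpin sequences;
  no salt/Mg2+ corrections; RNA only.
* One binding site only — complexes with two simultaneous intermolecular
  helices are out of scope.
* Double-precision partition functions; very long, strongly pairing inputs
  overflow loudly rather than switching to log space.
* The mode screen re-folds the scaffold per mode; cost grows with the mode
  count, so screening is intended for the gated (≤ 120–150 nt) regime.
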