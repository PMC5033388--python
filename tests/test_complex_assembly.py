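"""Crossing-helix screen: Z^B, conditional probabilities, end-to-end merge."""

import math

import pytest

from complexfold import (
    BindingMode,
    EnumerationConstraints,
    OverLengthError,
    StateError,
    concat_with_linker,
    conditional_pair_probabilities,
    enumerate_binding_modes,
    enumerate_structures,
    mode_partition_function,
    predict_complex,
)
from complexfold.complex_assembly import (
    ENSEMBLE_KISSING,
    ENSEMBLE_PSEUDOKNOT,
    classify_mode,
    crossing_structure_free_energy,
    mode_motif,
)


def restricted_oracle_z(seq, mode, model):
    cons = EnumerationConstraints(
        allow_crossing="single_intermolecular_helix", required_helix=mode)
    structs = enumerate_structures(seq, cons, model=model)
    z = sum(math.exp(-s.free_energy / model.rt)
            for s in structs if not math.isinf(s.free_energy))
    return z, structs


class TestModePartitionFunction:
    def test_matches_restricted_oracle(self, model, kissing_strands):
        seq = concat_with_linker(*kissing_strands)
        modes = enumerate_binding_modes(seq, min_helix_len=3, allow_defects=False)
        assert modes
        engine_rank, oracle_rank = [], []
        for mode in modes:
            zb = mode_partition_function(seq, mode, model)
            zo, _ = restricted_oracle_z(seq, mode, model)
            if zo > 0:
                assert zb == pytest.approx(zo, rel=1e-9)
            else:
                assert zb == 0.0
            engine_rank.append((mode.helix_pairs, zb))
            oracle_rank.append((mode.helix_pairs, zo))
        key = lambda t: (-t[1], t[0])
        assert ([h for h, _ in sorted(engine_rank, key=key)]
                == [h for h, _ in sorted(oracle_rank, key=key)])

    def test_saturated_mode_is_single_structure(self, model):
        """When the helix occupies every pairable position, Z^B is the
        weight of that one structure."""
        seq = concat_with_linker("GGG", "CCC")
        mode = BindingMode(helix_pairs=((1, 9), (2, 8), (3, 7)))
        zb = mode_partition_function(seq, mode, model)
        dg = crossing_structure_free_energy(seq, frozenset(), mode, model)
        assert zb == pytest.approx(math.exp(-dg / model.rt), rel=1e-12)

    def test_geometrically_impossible_kissing_is_zero(self, model):
        """Loops shorter than the helix span carry the infinite sentinel."""
        # 9-bp intermolecular helix leaves 1-2 nt flanks on each strand:
        # kissing-classed, but a 2-nt loop cannot span 9 bp.
        seq = concat_with_linker("AAGGGGGGGGGAA", "UUCCCCCCCCCUU")
        mode = BindingMode(helix_pairs=tuple((3 + t, 27 - t) for t in range(9)))
        assert classify_mode(seq, mode) == ENSEMBLE_KISSING
        assert mode_partition_function(seq, mode, model) == 0.0

    def test_ensemble_mismatch_is_zero_status(self, model, kissing_strands):
        seq = concat_with_linker(*kissing_strands)
        kissing_mode = BindingMode(tuple((5 + t, 23 - t) for t in range(4)))
        assert classify_mode(seq, kissing_mode) == ENSEMBLE_KISSING
        assert mode_partition_function(
            seq, kissing_mode, model, ensemble=ENSEMBLE_PSEUDOKNOT) == 0.0
        assert mode_partition_function(
            seq, kissing_mode, model, ensemble=ENSEMBLE_KISSING) > 0.0


class TestConditionalProbabilities:
    def test_matches_restricted_oracle(self, model, kissing_strands):
        seq = concat_with_linker(*kissing_strands)
        mode = BindingMode(tuple((5 + t, 23 - t) for t in range(4)))
        pm = conditional_pair_probabilities(seq, mode, model)
        zo, structs = restricted_oracle_z(seq, mode, model)
        frac = {}
        for s in structs:
            w = math.exp(-s.free_energy / model.rt)
            for pr in s.pairs:
                frac[pr] = frac.get(pr, 0.0) + w
        keys = set(frac) | {k for k, _ in pm.items()}
        for i, j in keys:
            assert pm.get(i, j) == pytest.approx(frac.get((i, j), 0.0) / zo, abs=1e-9)

    def test_mode_helix_pairs_are_certain(self, model, kissing_strands):
        seq = concat_with_linker(*kissing_strands)
        mode = BindingMode(tuple((5 + t, 23 - t) for t in range(4)))
        pm = conditional_pair_probabilities(seq, mode, model)
        for pr in mode.helix_pairs:
            assert pm.get(*pr) == 1.0
        # linker positions and the helix's own positions never pair otherwise
        for (i, j), p in pm.items():
            assert not seq.is_linker(i - 1) and not seq.is_linker(j - 1)

    def test_zero_mode_raises_state_error(self, model):
        seq = concat_with_linker("AAGGGGGGGGGAA", "UUCCCCCCCCCUU")
        mode = BindingMode(tuple((3 + t, 27 - t) for t in range(9)))
        with pytest.raises(StateError):
            conditional_pair_probabilities(seq, mode, model)


class TestPredictComplex:
    def test_three_blocks_under_every_gate(self, model, kissing_strands):
        pred = predict_complex(*kissing_strands, top_k_structures=3)
        assert set(pred.ensembles) == {"secondary", "h_pseudoknot", "kissing"}
        assert pred.gate.ensembles == ("secondary", "h_pseudoknot", "kissing")

    def test_over_length_error_names_limit(self):
        with pytest.raises(OverLengthError, match="300"):
            predict_complex("A" * 200, "A" * 102)

    def test_merged_top_equals_global_oracle_argmin(self, model, kissing_strands):
        pred = predict_complex(*kissing_strands, top_k_structures=5,
                               top_modes_retained=3)
        seq = pred.seq
        best_dg = min(s.free_energy
                      for s in enumerate_structures(seq, model=model))
        best = min(enumerate_structures(seq, model=model),
                   key=lambda s: (s.free_energy, s.sorted_pairs()))
        for mode in enumerate_binding_modes(seq, 3, allow_defects=True):
            cons = EnumerationConstraints(
                allow_crossing="single_intermolecular_helix", required_helix=mode)
            for s in enumerate_structures(seq, cons, model=model):
                if (s.free_energy, s.sorted_pairs()) < (best.free_energy,
                                                        best.sorted_pairs()):
                    best = s
        ens, top = pred.merged[0]
        assert top.pairs == best.pairs
        assert top.free_energy == pytest.approx(best.free_energy, abs=1e-9)

    def test_at_most_one_crossing_helix_anywhere(self, model, kissing_strands):
        """Every emitted structure has one contiguous crossing helix at most."""
        pred = predict_complex(*kissing_strands, top_k_structures=5,
                               top_modes_retained=2)
        for ens, st in pred.merged:
            if not st.crossing_pairs:
                continue
            ordered = sorted(st.crossing_pairs)
            gaps_a = [q[0] - p[0] for p, q in zip(ordered, ordered[1:])]
            gaps_b = [p[1] - q[1] for p, q in zip(ordered, ordered[1:])]
            # contiguous antiparallel run, allowing the single 1-nt defect
            assert all(1 <= g <= 2 for g in gaps_a + gaps_b)
            # and the scaffold pairs never cross each other
            rest = sorted(st.pairs - st.crossing_pairs)
            for i, j in rest:
                for k, l in rest:
                    assert not (i < k < j < l)

    def test_strand_order_symmetry(self, model):
        """The secondary partition function ignores which strand is 'A'."""
        z_ab = predict_complex("GGGAA", "UUCCC").ensembles["secondary"]
        z_ba = predict_complex("UUCCC", "GGGAA").ensembles["secondary"]
        assert z_ab.partition_function == pytest.approx(
            z_ba.partition_function, rel=1e-12)


def test_mode_motif_geometry(model, kissing_strands):
    seq = concat_with_linker(*kissing_strands)
    mode = BindingMode(tuple((5 + t, 23 - t) for t in range(4)))
    motif = mode_motif(seq, mode)
    assert motif.motif_class == "kissing_hairpins"
    assert motif.helix_lengths == (4,)
    assert all(l >= 1 for l in motif.loop_lengths)
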