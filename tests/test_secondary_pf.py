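"""Secondary-ensemble engine: tables, probabilities, ranking, scoring."""

import math

import pytest

from complexfold import (
    ValidationError,
    backtrack_pair_probabilities,
    compute_partition_tables,
    concat_with_linker,
    enumerate_probable_structures,
    enumerate_structures,
    oracle_partition,
    random_fixture,
    structure_free_energy,
    total_partition,
)
from complexfold.energy_model import _load_raw
from complexfold.secondary_pf import (
    BACKTRACK_ROOT_PROBABILITY,
    COIL_PARTITION,
    CONFORMATION_TYPES,
)


class TestPartitionTables:
    def test_unpairable_chain_is_pure_coil(self, model):
        t = compute_partition_tables("AAAA", model)
        assert t.z_total_full == 1.0
        assert total_partition(t, 1, 4) == 1.0

    def test_coil_partition_is_one_everywhere(self, model):
        t = compute_partition_tables("GGGAAACCC", model)
        for a in range(1, 10):
            for b in range(a, 10):
                assert t.z("coil", a, b) == COIL_PARTITION

    def test_single_nucleotide_segment(self, model):
        t = compute_partition_tables("GGGAAACCC", model)
        assert total_partition(t, 5, 5) == 1.0

    def test_sum_decomposition_is_exact(self, model):
        """The stored total is bit-for-bit the sum of the six types."""
        t = compute_partition_tables("GGGAAACCC", model)
        for a, b in [(1, 9), (2, 8), (1, 5), (3, 9)]:
            assert total_partition(t, a, b) == sum(
                t.z(ty, a, b) for ty in CONFORMATION_TYPES)

    def test_full_chain_matches_oracle(self, model):
        t = compute_partition_tables("GGGAAACCC", model)
        z, _ = oracle_partition(enumerate_structures("GGGAAACCC", model=model), model)
        assert t.z_total_full == pytest.approx(z, rel=1e-9)

    def test_short_span_c_type_is_zero(self, model):
        t = compute_partition_tables("GGGAAACCC", model)
        assert t.z("C", 4, 6) == 0.0  # span below the minimum hairpin loop
        assert t.z("C", 1, 2) == 0.0

    def test_segment_bounds_validated(self, model):
        t = compute_partition_tables("GGGAAACCC", model)
        with pytest.raises(ValidationError):
            total_partition(t, 0, 5)
        with pytest.raises(ValidationError):
            t.z("C", 3, 12)
        with pytest.raises(ValidationError):
            t.z("X", 1, 4)

    def test_invalid_alphabet_rejected(self, model):
        with pytest.raises(ValidationError):
            compute_partition_tables("GGXCC", model)

    def test_constraint_mask_monotonicity(self, model):
        """Allowing more pairs never decreases the partition function."""
        seq = concat_with_linker("GCGAAA", "UUUCGC")
        z_none = compute_partition_tables(
            seq, model, constraint_mask=lambda i, j: False).z_total_full
        z_some = compute_partition_tables(
            seq, model, constraint_mask=lambda i, j: i == 2).z_total_full
        z_all = compute_partition_tables(seq, model).z_total_full
        assert z_none == 1.0
        assert z_none <= z_some <= z_all
        # masked pairs really carry zero probability
        t = compute_partition_tables(seq, model, constraint_mask=lambda i, j: i != 2)
        pm = backtrack_pair_probabilities(t)
        assert all(i != 2 for (i, j), _ in pm.items())


class TestBacktracking:
    def test_root_initialisation(self):
        assert BACKTRACK_ROOT_PROBABILITY == 1.0

    def test_pairless_chain_gives_empty_matrix(self, model):
        t = compute_partition_tables("AAAA", model)
        pm = backtrack_pair_probabilities(t)
        assert pm.items() == []
        assert pm.get(1, 4) == 0.0

    def test_probabilities_match_oracle_fractions(self, model):
        for seed in range(8):
            a, b = random_fixture(seed, 6, 6, 0.6)
            seq = concat_with_linker(a, b)
            t = compute_partition_tables(seq, model)
            pm = backtrack_pair_probabilities(t)
            z, frac = oracle_partition(enumerate_structures(seq, model=model), model)
            keys = set(frac) | {k for k, _ in pm.items()}
            for i, j in keys:
                assert pm.get(i, j) == pytest.approx(frac.get((i, j), 0.0), abs=1e-9)

    def test_rows_are_subnormalised(self, model):
        seq = concat_with_linker("GGCGAAAACGCC", "GCGGUUUUCCGC")
        pm = backtrack_pair_probabilities(compute_partition_tables(seq, model))
        for i in range(1, seq.n + 1):
            assert pm.row_sum(i) <= 1.0 + 1e-9
        for (i, j), p in pm.items():
            assert 0.0 <= p <= 1.0
            assert not seq.is_linker(i - 1) and not seq.is_linker(j - 1)


class TestRanking:
    def test_trivial_chain_has_single_empty_structure(self, model):
        t = compute_partition_tables("AAAA", model)
        out = enumerate_probable_structures(t, model, k=5)
        assert len(out) == 1
        assert out[0].pairs == frozenset() and out[0].free_energy == 0.0

    def test_rank_one_is_oracle_argmin(self, model):
        for seed in range(6):
            a, b = random_fixture(50 + seed, 6, 6, 0.7)
            seq = concat_with_linker(a, b)
            t = compute_partition_tables(seq, model)
            out = enumerate_probable_structures(t, model, k=4)
            structs = enumerate_structures(seq, model=model)
            best = min(structs, key=lambda s: (s.free_energy, s.sorted_pairs()))
            assert out[0].pairs == best.pairs
            assert out[0].free_energy == pytest.approx(best.free_energy, abs=1e-9)
            dgs = [s.free_energy for s in out]
            assert dgs == sorted(dgs)

    def test_exhaustive_kbest_recovers_whole_ensemble(self, model):
        """Boltzmann weights of all ranked structures sum back to Z."""
        seq = concat_with_linker("GGCGAAA", "UUUCGCC")
        t = compute_partition_tables(seq, model)
        out = enumerate_probable_structures(t, model, k=10 ** 6)
        assert len(out) == len(enumerate_structures(seq))
        zsum = sum(math.exp(-s.free_energy / model.rt) for s in out)
        assert zsum == pytest.approx(t.z_total_full, rel=1e-9)

    def test_k_validated(self, model):
        t = compute_partition_tables("AAAA", model)
        with pytest.raises(ValidationError):
            enumerate_probable_structures(t, model, k=0)


class TestStructureFreeEnergy:
    def test_empty_structure_is_zero(self, model):
        assert structure_free_energy("GGGAAACCC", frozenset(), model) == 0.0

    def test_hairpin_helix_hand_sum(self, model):
        """3-bp helix + 3-nt hairpin loop == two stack entries + hairpin(3)."""
        raw = _load_raw("turner04")
        pairs = {(1, 9), (2, 8), (3, 7)}
        dg = structure_free_energy("GGGAAACCC", pairs, model)
        expected = 2 * raw["stack"][(("G", "C"), ("G", "C"))][0] + raw["hairpin"][3]
        assert dg == pytest.approx(expected)

    def test_linker_hairpin_is_free(self, model):
        """A duplex closing over the phantom linker costs no loop energy."""
        seq = concat_with_linker("GGG", "CCC")
        raw = _load_raw("turner04")
        dg = structure_free_energy(seq, {(1, 9), (2, 8), (3, 7)}, model)
        assert dg == pytest.approx(2 * raw["stack"][(("G", "C"), ("G", "C"))][0])

    def test_minimum_span_enforced(self, model):
        with pytest.raises(ValidationError):
            structure_free_energy("GGGAAACCC", {(4, 6)}, model)

    def test_linker_pair_rejected(self, model):
        seq = concat_with_linker("GGG", "CCC")
        with pytest.raises(ValidationError):
            structure_free_energy(seq, {(2, 5)}, model)

    def test_crossing_pairs_rejected(self, model):
        with pytest.raises(ValidationError):
            structure_free_energy("GCAGCAGCUGCUG", {(1, 8), (4, 12)}, model)

    def test_matches_engine_weights(self, model):
        """Scorer and recursion engine assign identical energies."""
        a, b = random_fixture(99, 7, 7, 0.6)
        seq = concat_with_linker(a, b)
        t = compute_partition_tables(seq, model)
        for st in enumerate_probable_structures(t, model, k=50):
            again = structure_free_energy(seq, st.pairs, model)
            assert again == pytest.approx(st.free_energy, abs=1e-9)
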