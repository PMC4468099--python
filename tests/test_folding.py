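"""Folding operations against hand examples and the enumeration oracle."""

import math

import numpy as np
import pytest

from multifind.folding import (
    boltzmann_probability,
    energy_of,
    ensemble_defect,
    enumerate_structures,
    max_expect_structure,
    mfe_fold,
    partition_function,
)
from multifind.rna import RnaSequence, SecondaryStructure


def _random_seq(rng, n):
    return RnaSequence("r", "".join(rng.choice(list("ACGU"), n)))


class TestEnumeration:
    def test_unpairable_sequence_has_only_open_chain(self):
        structs = enumerate_structures(RnaSequence("x", "AAAA"))
        assert len(structs) == 1
        assert structs[0].pairs == (-1, -1, -1, -1)

    def test_gaaac_has_open_chain_and_one_pair(self):
        structs = enumerate_structures(RnaSequence("x", "GAAAC"))
        assert len(structs) == 2
        assert {s.to_dotbracket() for s in structs} == {".....", "(...)"}

    def test_count_nondecreasing_under_extension(self, rng):
        for _ in range(10):
            base = "".join(rng.choice(list("ACGU"), 9))
            n0 = len(enumerate_structures(RnaSequence("x", base)))
            n1 = len(enumerate_structures(RnaSequence("x", base + rng.choice(list("ACGU")))))
            assert n1 >= n0

    def test_refuses_long_sequences(self):
        with pytest.raises(ValueError):
            enumerate_structures(RnaSequence("x", "A" * 21))

    def test_all_enumerated_structures_are_valid(self, rng):
        seq = _random_seq(rng, 12)
        structs = enumerate_structures(seq)
        assert len({s.pairs for s in structs}) == len(structs)  # duplicate-free
        for s in structs:
            s.validate(seq)


class TestMfe:
    def test_homopolymer_is_open_chain_at_zero(self):
        s, e = mfe_fold(RnaSequence("x", "AAAAAAA"))
        assert e == 0.0
        assert s.pairs == (-1,) * 7

    def test_hairpin_energy_matches_enumeration(self, model):
        seq = RnaSequence("x", "GGGAAACCC")
        structs = enumerate_structures(seq)
        emin = min(energy_of(s, seq, model) for s in structs)
        s, e = mfe_fold(seq, model)
        assert e == pytest.approx(emin, abs=1e-9)

    def test_energy_of_reproduces_mfe_energy(self, model, rng):
        for _ in range(10):
            seq = _random_seq(rng, 30)
            s, e = mfe_fold(seq, model)
            assert energy_of(s, seq, model) == pytest.approx(e, abs=1e-6)

    def test_deterministic_across_calls(self, model, rng):
        seq = _random_seq(rng, 40)
        s1, e1 = mfe_fold(seq, model)
        s2, e2 = mfe_fold(seq, model)
        assert s1.pairs == s2.pairs and e1 == e2


class TestEnergyOf:
    def test_open_chain_is_zero(self, model, rng):
        seq = _random_seq(rng, 15)
        assert energy_of(SecondaryStructure.open_chain(15), seq, model) == 0.0

    def test_single_hairpin_hand_sum(self, model):
        # GGGC AAAA GCCC: helix GGGC/GCCC (4 pairs, 3 stacks), loop of 4
        seq = RnaSequence("x", "GGGCAAAAGCCC")
        s = SecondaryStructure.from_pairs(12, [(0, 11), (1, 10), (2, 9), (3, 8)])
        from multifind.rna import PAIR_NAMES

        gc, cg = PAIR_NAMES.index("GC"), PAIR_NAMES.index("CG")
        expected = (
            model.stack[gc, gc] + model.stack[gc, gc] + model.stack[gc, cg]
            + model.hairpin_penalty(4)
        )  # all pairs GC/CG: no terminal penalty
        assert energy_of(s, seq, model) == pytest.approx(expected)

    def test_terminal_penalty_charged_on_au_helix_ends(self, model):
        # helix of 3 AU pairs closing a 4-loop; AU ends on hairpin and exterior
        seq = RnaSequence("x", "AAAGGGGUUU")
        s = SecondaryStructure.from_pairs(10, [(0, 9), (1, 8), (2, 7)])
        from multifind.rna import PAIR_NAMES

        au = PAIR_NAMES.index("AU")
        expected = (
            2 * model.stack[au, au] + model.hairpin_penalty(4) + 2 * model.terminal_au
        )
        assert energy_of(s, seq, model) == pytest.approx(expected)

    def test_incompatible_pair_rejected(self, model):
        seq = RnaSequence("x", "GAAAG")
        s = SecondaryStructure.from_pairs(5, [(0, 4)])
        with pytest.raises(ValueError):
            energy_of(s, seq, model)


class TestPartitionFunction:
    def test_unpairable_sequence_q_is_one(self, model):
        ens = partition_function(RnaSequence("x", "AAAA"), model)
        assert ens.q == pytest.approx(1.0)
        assert np.allclose(ens.unpaired_prob, 1.0)

    def test_normalization_identity(self, model, rng):
        for _ in range(5):
            seq = _random_seq(rng, 35)
            ens = partition_function(seq, model)
            total = ens.pair_prob.sum(axis=1) + ens.unpaired_prob
            assert np.allclose(total, 1.0, atol=1e-9)

    def test_mfe_structure_is_modal(self, model, rng):
        """Boltzmann consistency: no enumerated structure is more probable
        than the MFE structure."""
        for _ in range(10):
            seq = _random_seq(rng, 11)
            ens = partition_function(seq, model)
            smfe, _ = mfe_fold(seq, model)
            pmfe = boltzmann_probability(smfe, seq, ens, model)
            for s in enumerate_structures(seq):
                assert boltzmann_probability(s, seq, ens, model) <= pmfe + 1e-12

    def test_long_sequence_stays_finite(self, model, rng):
        seq = _random_seq(rng, 400)
        ens = partition_function(seq, model)
        assert math.isfinite(ens.log_q) and ens.log_q > 0
        assert np.isfinite(ens.pair_prob).all()


class TestEnsembleDefectAndMea:
    def test_single_structure_ensemble_has_zero_defect(self, model):
        seq = RnaSequence("x", "AAAA")
        ens = partition_function(seq, model)
        d, dn = ensemble_defect(SecondaryStructure.open_chain(4), ens)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert dn == pytest.approx(0.0, abs=1e-12)

    def test_normalized_defect_bounded(self, model, rng):
        for _ in range(25):
            seq = _random_seq(rng, int(rng.integers(8, 30)))
            ens = partition_function(seq, model)
            mea = max_expect_structure(ens)
            _, dn = ensemble_defect(mea, ens)
            assert 0.0 <= dn <= 1.0

    def test_mea_on_unpairable_sequence_is_open_chain(self, model):
        ens = partition_function(RnaSequence("x", "AAAA"), model)
        assert max_expect_structure(ens).pairs == (-1,) * 4

    def test_mea_defect_never_worse_than_mfe_defect(self, model, rng):
        for _ in range(30):
            seq = _random_seq(rng, int(rng.integers(10, 35)))
            ens = partition_function(seq, model)
            d_mea = ensemble_defect(max_expect_structure(ens), ens)[0]
            d_mfe = ensemble_defect(mfe_fold(seq, model)[0], ens)[0]
            assert d_mea <= d_mfe + 1e-9
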