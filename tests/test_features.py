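"""Feature computation: composition, shuffling nulls, Z scores, SCI, entropy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multifind.alignment import Alignment
from multifind.consensus import CommonStructureResult, consensus_fold
from multifind.features import (
    CompositionFeatures,
    NullDistribution,
    alignment_entropy,
    composition_features,
    feature_vector,
    sample_null,
    sci,
    shuffle_sequence,
    z_score,
)
from multifind.folding import mfe_fold
from multifind.rna import RnaSequence, SecondaryStructure


class TestComposition:
    @pytest.mark.parametrize(
        "residues,length,gc,g_of_gc,a_of_au",
        [
            ("GGCC", 4, 1.0, 0.5, 0.5),       # no A/U: ratio defaults to 0.5
            ("AUAU", 4, 0.0, 0.5, 0.5),       # no G/C: ratio defaults to 0.5
            ("GGGAAACCC", 9, 6 / 9, 0.5, 1.0),
        ],
    )
    def test_hand_counts_and_conventions(self, residues, length, gc, g_of_gc, a_of_au):
        f = composition_features(RnaSequence("x", residues))
        assert (f.length, f.gc, f.g_of_gc, f.a_of_au) == (length, pytest.approx(gc),
                                                          pytest.approx(g_of_gc),
                                                          pytest.approx(a_of_au))

    def test_n_residues_excluded_from_fractions(self):
        f = composition_features(RnaSequence("x", "GGNNCC"))
        assert f.length == 6 and f.gc == pytest.approx(1.0)


class TestShuffle:
    def test_homopolymer_shuffles_to_itself(self, rng):
        seq = RnaSequence("x", "AAAAAAA")
        assert shuffle_sequence(seq, rng).residues == seq.residues

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_composition_preserved(self, seed):
        rng = np.random.default_rng(seed)
        seq = RnaSequence("x", "".join(rng.choice(list("ACGU"), 40)))
        out = shuffle_sequence(seq, rng)
        assert sorted(out.residues) == sorted(seq.residues)

    def test_seeded_shuffle_reproducible(self):
        seq = RnaSequence("x", "GGGCCCAAAUUU")
        a = shuffle_sequence(seq, np.random.default_rng(5)).residues
        b = shuffle_sequence(seq, np.random.default_rng(5)).residues
        assert a == b


class TestNullAndZ:
    def test_homopolymer_null_is_degenerate(self, model, rng):
        null = sample_null(RnaSequence("x", "A" * 20), "energy", 10, model, rng)
        assert null.mu == 0.0 and null.sigma == 0.0
        assert z_score(-3.0, null) == 0.0  # sigma=0 convention

    def test_matches_independent_recomputation(self, model):
        seq = RnaSequence("x", "GGCGAAAGCUCCAUAG")
        null = sample_null(seq, "energy", 50, model, np.random.default_rng(9))
        # independent loop with the same seeded stream
        rng = np.random.default_rng(9)
        vals = []
        for _ in range(50):
            vals.append(mfe_fold(shuffle_sequence(seq, rng), model)[1])
        assert null.mu == pytest.approx(np.mean(vals))
        assert null.sigma == pytest.approx(np.std(vals))

    @pytest.mark.parametrize("value,mu,sigma,expected", [(5.0, 5.0, 2.0, 0.0), (1.0, 5.0, 2.0, -2.0)])
    def test_z_location_scale(self, value, mu, sigma, expected):
        null = NullDistribution(mu, sigma, 10, "energy")
        assert z_score(value, null) == expected

    def test_z_shift_invariance(self, rng):
        """Adding a constant to all null samples shifts Z exactly as
        (value - mu)/sigma predicts."""
        vals = rng.normal(-8, 2, size=100)
        for shift in (0.0, 3.7):
            null = NullDistribution(float(vals.mean()) + shift, float(vals.std()), 100, "energy")
            assert z_score(-12.0, null) == pytest.approx((-12.0 - vals.mean() - shift) / vals.std())

    def test_null_mean_stabilizes_with_more_shuffles(self, model):
        seq = RnaSequence("x", "GGCGCAAAGGCGCCAAUCCG")
        small = sample_null(seq, "energy", 50, model, np.random.default_rng(1))
        big = sample_null(seq, "energy", 300, model, np.random.default_rng(2))
        assert abs(small.mu - big.mu) < 4 * small.sigma / math.sqrt(50)


class TestSci:
    def test_ratio_arithmetic(self, model):
        common = CommonStructureResult(
            SecondaryStructure.open_chain(4), [], [], energies=[-10.0, -10.0]
        )
        seqs = [RnaSequence("a", "GGGCAAAAGCCC"), RnaSequence("b", "GGGCAAAAGCCC")]
        e_s = mfe_fold(seqs[0], model)[1]
        assert sci(common, seqs, model) == pytest.approx(-10.0 / e_s)

    def test_unfoldable_group_gives_zero(self, model):
        common = CommonStructureResult(SecondaryStructure.open_chain(4), [], [], energies=[0.0])
        seqs = [RnaSequence("a", "AAAA"), RnaSequence("b", "AAAA")]
        assert sci(common, seqs, model) == 0.0


class TestEntropy:
    def test_identical_rows_have_zero_entropy(self):
        aln = Alignment(("a", "b", "c"), ("GGAC",) * 3)
        assert alignment_entropy(aln) == 0.0

    def test_uniform_five_symbol_column_contributes_ln5(self):
        # first column holds each of {A,C,G,U,-} once; second is uniform
        aln = Alignment(tuple("abcde"), ("AA", "CA", "GA", "UA", "-A"))
        assert alignment_entropy(aln) == pytest.approx(math.log(5) / 2)

    def test_hand_summed_two_column_case(self):
        aln = Alignment(tuple("abcd"), ("AA", "AA", "UA", "UA"))
        assert alignment_entropy(aln) == pytest.approx((math.log(2) + 0.0) / 2)

    def test_invariant_under_row_reordering(self, rng):
        rows = tuple("".join(rng.choice(list("ACGU-"), 30)) for _ in range(5))
        rows = tuple(r if r.replace("-", "") else r[:-1] + "A" for r in rows)
        aln1 = Alignment(tuple("abcde"), rows)
        perm = rng.permutation(5)
        aln2 = Alignment(tuple(np.array(list("abcde"))[perm]), tuple(np.array(rows)[perm]))
        assert alignment_entropy(aln1) == pytest.approx(alignment_entropy(aln2))

    def test_bounded_by_ln5(self, rng):
        for _ in range(20):
            rows = []
            while len(rows) < 4:
                r = "".join(rng.choice(list("ACGU-"), 25))
                if r.replace("-", ""):
                    rows.append(r)
            s = alignment_entropy(Alignment(("a", "b", "c", "d"), tuple(rows)))
            assert 0.0 <= s <= math.log(5) + 1e-12


class TestFeatureVector:
    def test_identical_group_has_unit_sci_and_zero_entropy(self, model):
        aln = Alignment(("a", "b", "c"), ("GGGCAGGAACUUCGGUUCCUGCCC",) * 3)
        fv = feature_vector(aln, z_source="sampled", n_shuffles=20,
                            model=model, rng=np.random.default_rng(4))
        assert fv.sci == pytest.approx(1.0, abs=1e-6)
        assert fv.entropy == 0.0
        assert np.isfinite(fv.as_array()).all()

    def test_reproduces_scripted_recomputation(self, model):
        """End-to-end: the four numbers equal an independently scripted
        pipeline run with the same seeded stream."""
        aln = Alignment(
            ("a", "b", "c"),
            ("GGGCAGGAACUUCGGUUCCUGCCC",
             "GGGCAGCAACUUCGGUUGCUGCCC",
             "GGACAGGAACUUCGGUUCCUGUCC"),
        )
        fv = feature_vector(aln, z_source="sampled", n_shuffles=25,
                            model=model, rng=np.random.default_rng(21))

        rng = np.random.default_rng(21)
        seqs = aln.degapped()
        res = consensus_fold(aln, model)
        e_s = np.mean([mfe_fold(s, model)[1] for s in seqs])
        exp_sci = res.e_c / e_s
        from multifind.features import _statistic

        ez, dz = [], []
        for seq in seqs:
            e = _statistic(seq, "energy", model)
            d = _statistic(seq, "defect", model)
            ne = sample_null(seq, "energy", 25, model, rng)
            nd = sample_null(seq, "defect", 25, model, rng)
            ez.append(z_score(e, ne))
            dz.append(z_score(d, nd))
        assert fv.sci == pytest.approx(exp_sci)
        assert fv.energy_z == pytest.approx(np.mean(ez))
        assert fv.defect_z == pytest.approx(np.mean(dz))
        assert fv.entropy == pytest.approx(alignment_entropy(aln))
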