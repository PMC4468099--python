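"""Windowing, labeling, scanning and evaluation curves."""

import math

import numpy as np
import pytest

from multifind.alignment import Alignment
from multifind.genomescan import (
    AlignmentBlock,
    AnnotationInterval,
    GenomeWindow,
    RowCoords,
    cut_windows,
    filter_blocks,
    label_window,
    read_bed,
    read_gff3,
    read_maf,
    roc_curve,
    scan,
    sensitivity,
    specificity,
    stratify_by_entropy,
    tp_vs_candidates,
)


def _block(ncol, n_rows=2, block_id="b", rng=None, start=1000):
    rng = rng or np.random.default_rng(0)
    rows = tuple("".join(rng.choice(list("ACGU"), ncol)) for _ in range(n_rows))
    ids = tuple(f"g{i}.chr1" for i in range(n_rows))
    coords = tuple(RowCoords(ids[i], start, ncol) for i in range(n_rows))
    return AlignmentBlock(block_id, Alignment(ids, rows), coords)


class TestCutWindows:
    def test_250_columns_give_four_windows(self):
        ws = cut_windows(_block(250), width=100, step=50)
        assert [(w.col_start, w.col_end) for w in ws] == [
            (0, 100), (50, 150), (100, 200), (150, 250)]

    def test_exact_width_block_gives_one_window(self):
        assert len(cut_windows(_block(100))) == 1

    def test_short_block_gives_none(self):
        assert cut_windows(_block(80)) == []

    def test_end_anchored_final_window(self):
        ws = cut_windows(_block(230), width=100, step=50)
        assert [(w.col_start, w.col_end) for w in ws] == [
            (0, 100), (50, 150), (100, 200), (130, 230)]

    def test_gap_aware_genome_coordinates(self):
        # reference has gaps: coordinates must skip them
        rows = ("AC--GUACGU" + "A" * 90, "ACGUGUACGU" + "C" * 90)
        ids = ("ref.chr", "other.chr")
        block = AlignmentBlock(
            "b", Alignment(ids, rows),
            (RowCoords("ref.chr", 100, 98), RowCoords("other.chr", 0, 100)),
        )
        (w,) = cut_windows(block, width=100, step=50)
        assert w.coords[0].start == 100 and w.coords[0].size == 98
        sub = cut_windows(block, width=50, step=50)[0]
        assert sub.coords[0].start == 100 and sub.coords[0].size == 48

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            cut_windows(_block(100), width=0)
        with pytest.raises(ValueError):
            cut_windows(_block(100), width=50, step=60)


class TestLabeling:
    def _window(self, start=0, size=100):
        aln = Alignment(("ref.chr", "o"), ("A" * size, "C" * size))
        return GenomeWindow("b", 0, size, aln,
                            (RowCoords("ref.chr", start, size), RowCoords("o", 0, size)))

    def test_thirty_percent_window_rule(self):
        w = self._window(0, 100)
        ann = [AnnotationInterval("ref.chr", 69, 369)]  # 31 nt of a 300-nt ncRNA
        assert label_window(w, ann) == "ncRNA"

    def test_fifty_percent_annotation_rule(self):
        w = self._window(0, 100)
        ann = [AnnotationInterval("ref.chr", 79, 119)]  # 21 nt of a 40-nt ncRNA
        assert label_window(w, ann) == "ncRNA"

    def test_small_overlap_is_background(self):
        w = self._window(0, 100)
        ann = [AnnotationInterval("ref.chr", 90, 290)]  # 10 nt of a 200-nt ncRNA
        assert label_window(w, ann) == "background"

    def test_label_monotone_in_overlap(self):
        """Extending an annotation's overlap never flips ncRNA -> background."""
        w = self._window(0, 100)
        prev = "background"
        for end in range(5, 400, 15):
            lab = label_window(w, [AnnotationInterval("ref.chr", 0, end)])
            if prev == "ncRNA":
                assert lab == "ncRNA"
            prev = lab

    def test_wrong_chromosome_ignored(self):
        w = self._window(0, 100)
        assert label_window(w, [AnnotationInterval("elsewhere", 0, 100)]) == "background"


class TestFilterBlocks:
    def _annotations(self):
        return [AnnotationInterval("g0.chr1", 0, 5000, cls="intergenic")]

    def test_block_missing_required_genome_dropped(self):
        blocks = [_block(120, n_rows=2)]
        kept = filter_blocks(blocks, self._annotations(), ["g0.chr1", "g9.chr1"])
        assert kept == []

    def test_block_inside_gene_dropped(self):
        blocks = [_block(120, start=6000)]  # outside the intergenic interval
        kept = filter_blocks(blocks, self._annotations(), ["g0.chr1"])
        assert kept == []

    def test_straddling_block_trimmed_to_intergenic_part(self):
        block = _block(200, start=4900)  # reference spans 4900..5100
        kept = filter_blocks([block], self._annotations(), ["g0.chr1"])
        assert len(kept) == 1
        trimmed = kept[0]
        assert trimmed.reference.start == 4900
        assert trimmed.reference.end == 5000
        assert trimmed.alignment.ncol == 100

    def test_missing_intergenic_annotation_rejected(self):
        with pytest.raises(ValueError):
            filter_blocks([_block(100)], [AnnotationInterval("x", 0, 10, cls="ncRNA")], [])


class TestRates:
    def test_sensitivity_and_specificity_examples(self):
        assert sensitivity(8, 2) == pytest.approx(0.8)
        assert specificity(90, 10) == pytest.approx(0.9)

    def test_degenerate_counts_flagged_nan(self):
        assert math.isnan(sensitivity(0, 0))
        assert math.isnan(specificity(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sensitivity(-1, 2)


class TestCurves:
    def test_perfect_ranking_hits_corner(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        curve = roc_curve(scores, labels)
        assert curve.auc == pytest.approx(1.0)
        # passes through sensitivity 1 at specificity 1
        ideal = (curve.sensitivity == 1.0) & (curve.specificity == 1.0)
        assert ideal.any()

    def test_counts_conserved_along_curve(self):
        rng = np.random.default_rng(1)
        scores, labels = rng.random(50), rng.random(50) > 0.5
        curve = roc_curve(scores, labels)
        assert np.all(curve.tp + curve.fn == labels.sum())
        assert np.all(curve.tn + curve.fp == (~labels).sum())
        assert np.all(np.diff(curve.tp) >= 0)

    def test_random_scores_give_chance_auc(self):
        rng = np.random.default_rng(7)
        aucs = []
        for _ in range(20):
            scores = rng.random(200)
            labels = np.arange(200) < 100
            aucs.append(roc_curve(scores, labels).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.9], [1, 1])

    def test_tp_vs_candidates_hand_walk(self):
        cand, tps = tp_vs_candidates([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert list(cand) == [1, 2, 3, 4]
        assert list(tps) == [1, 1, 2, 2]

    def test_tp_curve_slope_one_until_exhausted(self):
        cand, tps = tp_vs_candidates([0.9, 0.8, 0.7, 0.2, 0.1], [1, 1, 1, 0, 0])
        assert list(tps) == [1, 2, 3, 3, 3]


class TestStratify:
    def test_partition_by_entropy(self):
        identical = GenomeWindow("b", 0, 4, Alignment(("a", "b"), ("ACGU", "ACGU")),
                                 (RowCoords("a", 0, 4), RowCoords("b", 0, 4)))
        diverse = GenomeWindow("b", 4, 8, Alignment(tuple("abcde"), ("AA", "CA", "GA", "UA", "-A")),
                               (RowCoords("a", 0, 2),) * 5)
        high, low = stratify_by_entropy([identical, diverse], threshold=0.3)
        assert low == [identical] and high == [diverse]

    def test_partition_sums_to_total_at_any_threshold(self, rng):
        wins = []
        for k in range(12):
            rows = tuple("".join(rng.choice(list("ACGU"), 20)) for _ in range(3))
            aln = Alignment(("a", "b", "c"), rows)
            wins.append(GenomeWindow("b", 0, 20, aln, (RowCoords("a", 0, 20),) * 3))
        for t in (0.0, 0.3, 0.8, 2.0):
            high, low = stratify_by_entropy(wins, t)
            assert len(high) + len(low) == len(wins)


MAF_TEXT = """##maf version=1
a score=0.0
s ref.chr1 1000 14 + 100000 GGGCAGGA--ACUUCG
s oth.chr2 2500 16 + 200000 GGGCAGGAUUACUUCG

a score=0.0
s ref.chr1 1100 16 + 100000 AAAACCCCGGGGUUUU
s oth.chr2 2600 16 + 200000 AAAACCCCGGGGUUUU
"""


class TestMafInput:
    def test_read_blocks_with_coordinates(self, tmp_path):
        p = tmp_path / "toy.maf"
        p.write_text(MAF_TEXT)
        blocks = read_maf(str(p))
        assert len(blocks) == 2
        b = blocks[0]
        assert b.reference.src == "ref.chr1"
        assert b.reference.start == 1000 and b.reference.size == 14
        assert b.alignment.rows[0] == "GGGCAGGA--ACUUCG"

    def test_coordinate_round_trip_through_windows(self, tmp_path):
        p = tmp_path / "toy.maf"
        p.write_text(MAF_TEXT)
        b = read_maf(str(p))[0]
        (w,) = cut_windows(b, width=16, step=16)
        assert w.coords[0].start == 1000 and w.coords[0].size == 14
        assert w.coords[1].start == 2500 and w.coords[1].size == 16
        # a half-width window sees only the residues left of the gap run
        first_half = cut_windows(b, width=8, step=8)[0]
        assert first_half.coords[0].size == 8
        second_half = cut_windows(b, width=8, step=8)[1]
        assert second_half.coords[0].start == 1008 and second_half.coords[0].size == 6


class TestAnnotationInput:
    def test_bed_is_zero_based_half_open(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t10\t20\tfoo\t0\t+\n")
        (a,) = read_bed(str(p))
        assert (a.start, a.end, a.name) == (10, 20, "foo")

    def test_gff3_converted_to_zero_based(self, tmp_path):
        p = tmp_path / "x.gff3"
        p.write_text("##gff-version 3\nchr1\tsrc\tncRNA\t11\t20\t.\t+\t.\tID=bar\n")
        (a,) = read_gff3(str(p))
        assert (a.start, a.end, a.name) == (10, 20, "bar")

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            AnnotationInterval("c", 5, 5)
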