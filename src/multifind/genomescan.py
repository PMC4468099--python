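"""Window scanning of multiple genome alignments.

Protocol: alignment blocks (MAF) are filtered to those containing every
required genome and lying in intergenic regions of the reference, cut into
fixed-width windows of alignment columns with a half-window step, labeled
against known ncRNA annotations (a window is an ncRNA window when more than
30% of its nucleotides overlap an annotation, or when it contains more than
50% of an annotation's nucleotides), scored with the trained classifier,
and evaluated with ROC and true-positives-versus-candidates curves,
optionally stratified by average column entropy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import AlignIO
from intervaltree import IntervalTree

from .alignment import GAP, Alignment
from .classifier import ClassifierModel
from .features import alignment_entropy, feature_vector

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentBlock", "GenomeWindow", "AnnotationInterval", "EvalCurve",
    "read_maf", "read_bed", "read_gff3", "cut_windows", "filter_blocks",
    "label_window", "scan", "sensitivity", "specificity",
    "roc_curve", "tp_vs_candidates", "stratify_by_entropy",
]


@dataclass(frozen=True)
class RowCoords:
    """MAF-style per-row coordinates: strand-relative 0-based start and the
    number of ungapped residues."""

    src: str
    start: int
    size: int
    strand: str = "+"
    src_size: int = 0

    @property
    def end(self) -> int:
        return self.start + self.size


@dataclass(frozen=True)
class AlignmentBlock:
    """One multiple-genome-alignment block: aligned rows plus coordinates."""

    block_id: str
    alignment: Alignment
    coords: tuple  # RowCoords per row

    @property
    def reference(self) -> RowCoords:
        return self.coords[0]


@dataclass
class GenomeWindow:
    """A fixed-width slice of a block's columns, with genome coordinates."""

    block_id: str
    col_start: int
    col_end: int
    alignment: Alignment
    coords: tuple           # RowCoords per row, for the window span
    label: str = "unknown"  # "ncRNA" | "background" | "unknown"
    entropy: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if math.isnan(self.entropy):
            self.entropy = alignment_entropy(self.alignment)


@dataclass(frozen=True)
class AnnotationInterval:
    """A genome annotation: 0-based half-open, with a feature class."""

    seqname: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""
    cls: str = "ncRNA"  # "ncRNA" | "gene" | "intergenic"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.name!r}: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# input formats

def read_maf(source) -> list:
    """Read alignment blocks from a MAF file."""
    blocks = []
    for k, msa in enumerate(AlignIO.parse(source, "maf")):
        ids, rows, coords = [], [], []
        for rec in msa:
            ann = rec.annotations
            ids.append(rec.id)
            rows.append(str(rec.seq))
            coords.append(RowCoords(
                src=rec.id,
                start=int(ann.get("start", 0)),
                size=int(ann.get("size", len(str(rec.seq).replace(GAP, "")))),
                strand="+" if ann.get("strand", 1) in (1, "+") else "-",
                src_size=int(ann.get("srcSize", 0)),
            ))
        blocks.append(AlignmentBlock(f"block{k}", Alignment(tuple(ids), tuple(rows)), tuple(coords)))
    return blocks


def read_bed(source, cls: str = "ncRNA") -> list:
    """BED intervals (0-based half-open, as the format defines)."""
    out = []
    with open(source) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(AnnotationInterval(
                seqname=f[0], start=int(f[1]), end=int(f[2]),
                name=f[3] if len(f) > 3 else "",
                strand=f[5] if len(f) > 5 else "+",
                cls=cls,
            ))
    return out


def read_gff3(source, cls: str = "ncRNA", feature_types: set | None = None) -> list:
    """GFF3 intervals (1-based inclusive on disk, converted to 0-based
    half-open internally)."""
    out = []
    with open(source) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                continue
            if feature_types and f[2] not in feature_types:
                continue
            attrs = f[8] if len(f) > 8 else ""
            name = ""
            for kv in attrs.split(";"):
                if kv.startswith(("ID=", "Name=")):
                    name = kv.split("=", 1)[1]
                    break
            out.append(AnnotationInterval(
                seqname=f[0], start=int(f[3]) - 1, end=int(f[4]),
                strand=f[6] if f[6] in "+-" else "+", name=name, cls=cls,
            ))
    return out


# ---------------------------------------------------------------------------
# windowing

def _row_coords_for_span(block: AlignmentBlock, start: int, stop: int) -> tuple:
    """Strand-relative genome coordinates of a column span, per row."""
    out = []
    for row, rc in zip(block.alignment.rows, block.coords):
        before = len(row[:start]) - row[:start].count(GAP)
        inside = len(row[start:stop]) - row[start:stop].count(GAP)
        out.append(replace(rc, start=rc.start + before, size=inside))
    return tuple(out)


def cut_windows(block: AlignmentBlock, width: int = 100, step: int = 50) -> list:
    """Cut a block into windows of ``width`` alignment columns every ``step``
    columns.  Only full-width windows are emitted; when the last one falls
    short of the block end, a final window anchored at the end is added.
    Blocks narrower than ``width`` yield nothing.
    """
    if width <= 0 or not (0 < step <= width):
        raise ValueError("need width > 0 and 0 < step <= width")
    ncol = block.alignment.ncol
    if ncol < width:
        return []
    starts = list(range(0, ncol - width + 1, step))
    if starts[-1] + width < ncol:
        starts.append(ncol - width)
    out = []
    for s in starts:
        sub = block.alignment.take_columns(s, s + width)
        out.append(GenomeWindow(
            block_id=block.block_id, col_start=s, col_end=s + width,
            alignment=sub, coords=_row_coords_for_span(block, s, s + width),
        ))
    return out


def _columns_for_ref_interval(block: AlignmentBlock, start: int, end: int) -> tuple:
    """Column span [c0, c1) covering reference genome positions [start, end)."""
    row = block.alignment.rows[0]
    pos = block.reference.start
    c0 = c1 = None
    for col, ch in enumerate(row):
        if ch != GAP:
            if c0 is None and pos >= start:
                c0 = col
            if pos < end:
                c1 = col + 1
            pos += 1
    if c0 is None or c1 is None or c1 <= c0:
        return (0, 0)
    return (c0, c1)


def filter_blocks(blocks: list, annotations: list, required_rows: list) -> list:
    """Keep blocks containing every required genome and lying in intergenic
    regions of the reference; blocks straddling a boundary are trimmed to
    their intergenic intersection (possibly into several sub-blocks)."""
    intergenic = [a for a in annotations if a.cls == "intergenic"]
    if not intergenic:
        raise ValueError("no intergenic intervals supplied for the reference")
    trees: dict = {}
    for a in intergenic:
        trees.setdefault(a.seqname, IntervalTree()).addi(a.start, a.end)

    out = []
    for block in blocks:
        srcs = {rc.src for rc in block.coords}
        if not set(required_rows) <= srcs:
            continue
        ref = block.reference
        tree = trees.get(ref.src)
        if tree is None:
            continue
        pieces = sorted(tree.overlap(ref.start, ref.end))
        for k, iv in enumerate(pieces):
            a, b = max(iv.begin, ref.start), min(iv.end, ref.end)
            if b <= a:
                continue
            if a == ref.start and b == ref.end:
                out.append(block)
                continue
            c0, c1 = _columns_for_ref_interval(block, a, b)
            if c1 - c0 <= 0:
                continue
            sub = block.alignment.take_columns(c0, c1)
            if any(not r.replace(GAP, "") for r in sub.rows):
                continue
            out.append(AlignmentBlock(
                f"{block.block_id}.{k}", sub, _row_coords_for_span(block, c0, c1)
            ))
    return out


def label_window(window: GenomeWindow, ncrnas: list) -> str:
    """ncRNA when >30% of the window's reference nucleotides overlap any
    annotation, or the window contains >50% of an annotation's nucleotides;
    otherwise background."""
    ref = window.coords[0]
    wlen = ref.size
    if wlen == 0:
        return "background"
    for a in ncrnas:
        if a.cls != "ncRNA" or a.seqname != ref.src:
            continue
        overlap = max(0, min(ref.end, a.end) - max(ref.start, a.start))
        if overlap == 0:
            continue
        if overlap / wlen > 0.30 or overlap / a.length > 0.50:
            return "ncRNA"
    return "background"


# ---------------------------------------------------------------------------
# scanning and evaluation

@dataclass(frozen=True)
class ScanHit:
    block_id: str
    col_start: int
    col_end: int
    ref_start: int
    ref_end: int
    probability: float
    entropy: float
    label: str


def scan(
    windows: list,
    model: ClassifierModel,
    min_row_length: int = 30,
    threshold: float = 0.5,
    **feature_kwargs,
) -> list:
    """Score every window with the classifier; returns ScanHits sorted by
    descending probability (ties broken by block id, then start column).

    Windows whose rows de-gap to fewer than ``min_row_length`` nt are
    skipped with a log entry.
    """
    hits = []
    for w in windows:
        if any(len(r.replace(GAP, "")) < min_row_length for r in w.alignment.rows):
            logger.info("skipping %s:%d (row below %d nt)", w.block_id, w.col_start, min_row_length)
            continue
        fv = feature_vector(w.alignment, **feature_kwargs)
        p, _ = model.classify(fv, threshold)
        ref = w.coords[0]
        hits.append(ScanHit(
            w.block_id, w.col_start, w.col_end, ref.start, ref.end,
            p, w.entropy, w.label,
        ))
    hits.sort(key=lambda h: (-h.probability, h.block_id, h.col_start))
    return hits


def hits_to_frame(hits: list) -> pd.DataFrame:
    return pd.DataFrame([h.__dict__ for h in hits])


def sensitivity(tp: int, fn: int) -> float:
    """TP / (TP + FN); NaN flags the undefined 0/0 case."""
    if tp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    return tp / (tp + fn) if tp + fn else float("nan")


def specificity(tn: int, fp: int) -> float:
    """TN / (TN + FP); NaN flags the undefined 0/0 case."""
    if tn < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    return tn / (tn + fp) if tn + fp else float("nan")


@dataclass
class EvalCurve:
    """Threshold sweep: counts and sensitivity/specificity per threshold."""

    threshold: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def sensitivity(self) -> np.ndarray:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> np.ndarray:
        return self.tn / (self.tn + self.fp)

    @property
    def auc(self) -> float:
        x = 1.0 - self.specificity
        return float(np.trapezoid(self.sensitivity, x))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.threshold, "tp": self.tp, "fp": self.fp,
            "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
        })


def roc_curve(scores, labels) -> EvalCurve:
    """ROC by sweeping a threshold over the unique scores (prediction:
    score >= threshold).  Requires at least one positive and one negative."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tp = np.array([(labels & (scores >= t)).sum() for t in thresholds])
    fp = np.array([(~labels & (scores >= t)).sum() for t in thresholds])
    return EvalCurve(thresholds, tp, fp, n_neg - fp, n_pos - tp)


def tp_vs_candidates(scores, labels):
    """Cumulative true positives down the ranked candidate list.

    Returns (candidates 1..n, tp_counts), both monotone nondecreasing.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(labels[order])
    return np.arange(1, len(scores) + 1), tps


def stratify_by_entropy(windows: list, threshold: float = 0.3) -> tuple:
    """Partition windows into (high_entropy, low_entropy) sets at the given
    average-column-entropy threshold.  High entropy (S > threshold) marks
    low-similarity alignments, where thermodynamic features carry the
    classification; S <= threshold marks high-similarity alignments."""
    high = [w for w in windows if w.entropy > threshold]
    low = [w for w in windows if w.entropy <= threshold]
    return high, low
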