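"""Multiple-sequence alignment container and I/O.

Thin wrapper over Biopython's AlignIO for CLUSTAL / Stockholm / FASTA input;
rows are gapped strings over {A,C,G,U,N,-} with T folded to U on load.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .rna import RnaSequence

GAP = "-"
_VALID = set("ACGUN-")


@dataclass(frozen=True)
class Alignment:
    """Aligned rows of equal length; de-gapping any row yields an RnaSequence."""

    ids: tuple
    rows: tuple

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        cleaned = tuple(r.upper().replace("T", "U").replace(".", "-") for r in self.rows)
        ncol = len(cleaned[0])
        for rid, row in zip(self.ids, cleaned):
            if len(row) != ncol:
                raise ValueError(f"row {rid!r} has length {len(row)} != {ncol}")
            bad = set(row) - _VALID
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)} in row {rid!r}")
            if not row.replace(GAP, ""):
                raise ValueError(f"row {rid!r} is all gaps")
        object.__setattr__(self, "rows", cleaned)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ncol(self) -> int:
        return len(self.rows[0])

    def degapped(self) -> list:
        """The underlying ungapped sequences, one per row."""
        return [RnaSequence(rid, row.replace(GAP, "")) for rid, row in zip(self.ids, self.rows)]

    def column(self, p: int) -> str:
        return "".join(row[p] for row in self.rows)

    def column_to_position(self) -> list:
        """Per row: array mapping alignment column -> 0-based ungapped position (or -1 at gaps)."""
        maps = []
        for row in self.rows:
            pos, m = 0, []
            for ch in row:
                if ch == GAP:
                    m.append(-1)
                else:
                    m.append(pos)
                    pos += 1
            maps.append(m)
        return maps

    def take_columns(self, start: int, stop: int) -> "Alignment":
        return Alignment(self.ids, tuple(r[start:stop] for r in self.rows))

    @classmethod
    def from_sequences(cls, seqs: Sequence[RnaSequence]) -> "Alignment":
        """Trivial positional alignment of equal-length sequences."""
        return cls(tuple(s.id for s in seqs), tuple(s.residues for s in seqs))

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def read(cls, source, fmt: str = "clustal") -> "Alignment":
        """Read an alignment (``fmt``: clustal, stockholm, fasta)."""
        msa = AlignIO.read(source, fmt)
        return cls(
            tuple(rec.id for rec in msa),
            tuple(str(rec.seq) for rec in msa),
        )

    def write(self, target, fmt: str = "clustal") -> None:
        msa = MultipleSeqAlignment(
            [SeqRecord(Seq(row), id=rid, description="") for rid, row in zip(self.ids, self.rows)]
        )
        AlignIO.write(msa, target, fmt)

    def to_clustal(self) -> str:
        buf = StringIO()
        self.write(buf, "clustal")
        return buf.getvalue()
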