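"""Core sequence and secondary-structure types.

An :class:`RnaSequence` is an ungapped nucleotide string over ``{A,C,G,U,N}``
(``T`` is folded to ``U`` on construction).  A :class:`SecondaryStructure` is
a pseudoknot-free pairing map: each position is either unpaired or paired
with exactly one partner, partners form canonical pairs, and hairpin loops
enclose at least three unpaired nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

ALPHABET = "ACGUN"
#: integer codes used throughout the folding kernels
A, C, G, U, N_CODE = 0, 1, 2, 3, 4

#: canonical pair codes, indexed by (code_i, code_j); -1 = cannot pair
PAIR_INDEX = -np.ones((5, 5), dtype=np.int64)
_CANONICAL = [("AU", 0), ("UA", 1), ("GC", 2), ("CG", 3), ("GU", 4), ("UG", 5)]
for _pair, _idx in _CANONICAL:
    PAIR_INDEX[ALPHABET.index(_pair[0]), ALPHABET.index(_pair[1])] = _idx

PAIR_NAMES = ["AU", "UA", "GC", "CG", "GU", "UG"]

#: minimum number of unpaired nucleotides in a hairpin loop
MIN_HAIRPIN = 3


def encode(residues: str) -> np.ndarray:
    """Translate a residue string into integer codes (A=0 C=1 G=2 U=3 N=4)."""
    table = str.maketrans(ALPHABET, "01234")
    return np.frombuffer(residues.translate(table).encode(), dtype=np.uint8).astype(np.int64) - ord("0")


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence: an id and residues over {A,C,G,U,N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        cleaned = self.residues.upper().replace("T", "U")
        bad = set(cleaned) - set(ALPHABET)
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in sequence {self.id!r}")
        if not cleaned:
            raise ValueError("empty sequence")
        object.__setattr__(self, "residues", cleaned)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n(self) -> int:
        return len(self.residues)

    def codes(self) -> np.ndarray:
        return encode(self.residues)

    def can_pair(self, i: int, j: int) -> bool:
        """True if positions i, j (0-based) form a canonical pair."""
        ci, cj = ALPHABET.index(self.residues[i]), ALPHABET.index(self.residues[j])
        return bool(PAIR_INDEX[ci, cj] >= 0)


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free pairing map over a sequence of length ``n``.

    ``pairs[i]`` is the 0-based partner of position ``i``, or -1 if unpaired.
    """

    pairs: tuple

    @classmethod
    def from_pairs(cls, n: int, pair_list: Iterable[tuple]) -> "SecondaryStructure":
        arr = [-1] * n
        for i, j in pair_list:
            arr[i], arr[j] = j, i
        return cls(tuple(arr))

    @classmethod
    def open_chain(cls, n: int) -> "SecondaryStructure":
        return cls(tuple([-1] * n))

    @classmethod
    def from_dotbracket(cls, db: str) -> "SecondaryStructure":
        stack: list = []
        arr = [-1] * len(db)
        for i, ch in enumerate(db):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                if not stack:
                    raise ValueError("unbalanced dot-bracket string")
                j = stack.pop()
                arr[i], arr[j] = j, i
            elif ch != ".":
                raise ValueError(f"unsupported dot-bracket character {ch!r}")
        if stack:
            raise ValueError("unbalanced dot-bracket string")
        return cls(tuple(arr))

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n(self) -> int:
        return len(self.pairs)

    def partner(self, i: int) -> int:
        return self.pairs[i]

    def base_pairs(self) -> Iterator[tuple]:
        """Yield (i, j) with i < j for every pair."""
        for i, j in enumerate(self.pairs):
            if j > i:
                yield (i, j)

    def to_dotbracket(self) -> str:
        out = []
        for i, j in enumerate(self.pairs):
            out.append("." if j < 0 else ("(" if j > i else ")"))
        return "".join(out)

    def validate(self, seq: RnaSequence | None = None) -> None:
        """Raise ValueError on any violated structural invariant."""
        n = len(self.pairs)
        if seq is not None and len(seq) != n:
            raise ValueError("structure/sequence length mismatch")
        plist = []
        for i, j in enumerate(self.pairs):
            if j < 0:
                continue
            if not (0 <= j < n) or self.pairs[j] != i or j == i:
                raise ValueError(f"pairing map is not an involution at {i}")
            if j > i:
                # a span of >= MIN_HAIRPIN enclosed positions per pair is
                # equivalent to every hairpin loop holding >= MIN_HAIRPIN nt
                if j - i - 1 < MIN_HAIRPIN:
                    raise ValueError(f"hairpin loop below {MIN_HAIRPIN} nt at pair ({i},{j})")
                plist.append((i, j))
                if seq is not None and not seq.can_pair(i, j):
                    raise ValueError(
                        f"non-canonical pair {seq.residues[i]}-{seq.residues[j]} at ({i},{j})"
                    )
        for a, b in plist:
            for c, d in plist:
                if a < c < b < d:
                    raise ValueError(f"pseudoknot: pairs ({a},{b}) and ({c},{d}) cross")


def structure_distance(s1: SecondaryStructure, s2: SecondaryStructure) -> int:
    """Number of positions whose conformation differs between two structures.

    A position agrees when it has the same partner in both structures or is
    unpaired in both; the distance is the count of disagreeing positions.
    It is 0 for identical structures and N when every position differs.
    """
    if len(s1) != len(s2):
        raise ValueError("structures have different lengths")
    return sum(1 for a, b in zip(s1.pairs, s2.pairs) if a != b)


# ---------------------------------------------------------------------------
# CT files (the standard per-nucleotide connectivity table)

def write_ct(path, seq: RnaSequence, struct: SecondaryStructure, energy: float | None = None) -> None:
    header = f"{len(seq)}  {seq.id}"
    if energy is not None:
        header = f"{len(seq)}  ENERGY = {energy:.2f}  {seq.id}"
    lines = [header]
    for i, res in enumerate(seq.residues, start=1):
        j = struct.pairs[i - 1] + 1
        lines.append(f"{i} {res} {i - 1} {i + 1 if i < len(seq) else 0} {j if j > 0 else 0} {i}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_ct(path) -> tuple:
    """Read one structure from a CT file; returns (RnaSequence, SecondaryStructure)."""
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    label = lines[0].split()[-1] if len(lines[0].split()) > 1 else "ct"
    residues, pairs = [], [-1] * n
    for ln in lines[1 : n + 1]:
        f = ln.split()
        i, res, j = int(f[0]), f[1], int(f[4])
        residues.append(res)
        if j > 0:
            pairs[i - 1] = j - 1
    return RnaSequence(label, "".join(residues)), SecondaryStructure(tuple(pairs))
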