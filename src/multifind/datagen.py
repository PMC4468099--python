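"""Synthetic data generation.

Everything the training and evaluation protocols need is generated here, so
no external database is required: composition-controlled random sequences
(for the Z-score surrogates), structured RNA families with compensatory
covariation at paired positions (positive groups), and column-shuffled
alignments (negative groups).  Column shuffling preserves each column's
vertical content — hence length, composition and average column entropy —
so any classifier signal separating positives from negatives must come from
structure, mirroring the control design of alignment-based ncRNA screens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .rna import PAIR_NAMES, RnaSequence, SecondaryStructure

CANONICAL_PAIRS = [tuple(p) for p in PAIR_NAMES]  # as residue tuples


def random_sequence(
    length: int,
    gc: float,
    g_of_gc: float,
    a_of_au: float,
    rng: np.random.Generator,
    id: str = "random",
) -> RnaSequence:
    """A random sequence hitting the requested composition targets.

    Residue counts are the rounded targets (realized composition within one
    residue of each target count), in uniformly random order.
    """
    n_gc = int(round(length * gc))
    n_g = int(round(n_gc * g_of_gc))
    n_au = length - n_gc
    n_a = int(round(n_au * a_of_au))
    residues = ["G"] * n_g + ["C"] * (n_gc - n_g) + ["A"] * n_a + ["U"] * (n_au - n_a)
    arr = np.array(residues)
    rng.shuffle(arr)
    return RnaSequence(id, "".join(arr))


@dataclass(frozen=True)
class FamilyTemplate:
    """A structured-family generator seed: a template sequence, its
    structure, and per-position mutation dynamics."""

    family_id: str
    sequence: str
    structure: SecondaryStructure
    mutation_rate: float = 0.15
    compensatory_prob: float = 0.9

    def __post_init__(self) -> None:
        if not (0 <= self.mutation_rate <= 1 and 0 <= self.compensatory_prob <= 1):
            raise ValueError("rates must lie in [0, 1]")
        self.structure.validate(RnaSequence(self.family_id, self.sequence))


def template_from_structure(
    db: str, family_id: str, rng: np.random.Generator,
    mutation_rate: float = 0.15, compensatory_prob: float = 0.9,
) -> FamilyTemplate:
    """Fill a dot-bracket layout with a random compatible sequence
    (random canonical pairs at paired positions, random bases elsewhere)."""
    struct = SecondaryStructure.from_dotbracket(db)
    residues = [""] * len(db)
    for i, j in enumerate(struct.pairs):
        if j < 0:
            residues[i] = str(rng.choice(list("ACGU")))
        elif j > i:
            a, b = CANONICAL_PAIRS[rng.integers(0, 6)]
            residues[i], residues[j] = a, b
    return FamilyTemplate(family_id, "".join(residues), struct, mutation_rate, compensatory_prob)


#: dot-bracket layouts for the shipped default templates
DEFAULT_LAYOUTS = {
    "hairpin": "...((((((((((....))))))))))...",
    "twostem": "..(((((((....)))))))..((((((((....))))))))..",
    "cloverleaf": (
        ".(((((((..((((........))))."
        "(((((.......)))))....(((((.......)))))))))))).."
    ),
}


def default_templates(rng: np.random.Generator) -> list:
    """The three shipped family layouts, filled with random sequences."""
    return [template_from_structure(db, name, rng) for name, db in DEFAULT_LAYOUTS.items()]


def random_family_template(
    rng: np.random.Generator, family_id: str = "family",
    mutation_rate: float = 0.15, compensatory_prob: float = 0.9,
) -> FamilyTemplate:
    """A random structured layout (randomized helix/loop lengths over the
    shipped shapes) with a random compatible sequence."""
    shape = rng.integers(0, 3)
    if shape == 0:  # single hairpin
        stem, loop = rng.integers(8, 13), rng.integers(4, 8)
        db = "." * 3 + "(" * stem + "." * loop + ")" * stem + "." * 3
    elif shape == 1:  # two stems
        s1, l1 = rng.integers(6, 10), rng.integers(4, 7)
        s2, l2 = rng.integers(6, 10), rng.integers(4, 7)
        sp = rng.integers(2, 5)
        db = ("." * 2 + "(" * s1 + "." * l1 + ")" * s1 + "." * sp
              + "(" * s2 + "." * l2 + ")" * s2 + "." * 2)
    else:  # cloverleaf: outer stem enclosing three arms
        outer = rng.integers(5, 8)
        arms = []
        for _ in range(3):
            s, l = rng.integers(4, 7), rng.integers(4, 8)
            arms.append("(" * s + "." * l + ")" * s + "." * rng.integers(1, 3))
        db = "." + "(" * outer + ".." + "".join(arms) + ")" * outer + "."
    return template_from_structure(db, family_id, rng, mutation_rate, compensatory_prob)


def sample_structured_family(
    template: FamilyTemplate, n_seqs: int, rng: np.random.Generator
) -> Alignment:
    """Mutate the template into a family of n_seqs sequences.

    Unpaired positions substitute independently at the mutation rate; paired
    positions mutate as a unit, compensatorily (a fresh random canonical
    pair) with the template's compensatory probability, otherwise one side
    only.  The returned alignment is the trivial positional alignment; the
    template's true structure applies column-wise.
    """
    if n_seqs < 2:
        raise ValueError("a family needs at least 2 sequences")
    bases = list("ACGU")
    rows, ids = [], []
    for k in range(n_seqs):
        residues = list(template.sequence)
        for i, j in enumerate(template.structure.pairs):
            if j < 0:
                if rng.random() < template.mutation_rate:
                    choices = [b for b in bases if b != residues[i]]
                    residues[i] = str(rng.choice(choices))
            elif j > i and rng.random() < template.mutation_rate:
                if rng.random() < template.compensatory_prob:
                    a, b = CANONICAL_PAIRS[rng.integers(0, 6)]
                    residues[i], residues[j] = a, b
                else:
                    side = i if rng.random() < 0.5 else j
                    choices = [b for b in bases if b != residues[side]]
                    residues[side] = str(rng.choice(choices))
        rows.append("".join(residues))
        ids.append(f"{template.family_id}_{k}")
    return Alignment(tuple(ids), tuple(rows))


def shuffle_alignment_columns(aln: Alignment, rng: np.random.Generator) -> Alignment:
    """Permute the column order uniformly, keeping each column's vertical
    content intact (the negative-control construction)."""
    perm = rng.permutation(aln.ncol)
    rows = tuple("".join(row[p] for p in perm) for row in aln.rows)
    return Alignment(aln.ids, rows)
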