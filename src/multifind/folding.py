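"""Single-sequence thermodynamic folding.

Operations: minimum-free-energy structure prediction, free energy of a given
structure, McCaskill partition function with base-pair probabilities,
maximum-expected-accuracy (minimum ensemble defect at gamma = 1) structure,
ensemble defect of a structure, and exhaustive structure enumeration for
small sequences (the brute-force oracle used in testing).

All operations share one energy decomposition (see :mod:`multifind._kernels`),
so the enumerated ensemble, the MFE search and the partition function agree
exactly on every structure's energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from ._kernels import mea_matrix, mfe_matrix, pf_matrix
from .energy import EnergyModel, default_model
from .rna import PAIR_INDEX, RnaSequence, SecondaryStructure

__all__ = [
    "EnsembleSummary",
    "mfe_fold",
    "energy_of",
    "partition_function",
    "ensemble_defect",
    "max_expect_structure",
    "enumerate_structures",
    "boltzmann_probability",
]

#: refuse exhaustive enumeration beyond this length
ENUMERATION_LIMIT = 20

#: sequences longer than this trigger partition-function rescaling
_SCALE_THRESHOLD = 200


@dataclass
class EnsembleSummary:
    """Partition function and pairing probabilities for one sequence.

    ``pair_prob[i, j]`` is the probability that i pairs j in the Boltzmann
    ensemble; ``unpaired_prob[i] = 1 - sum_j pair_prob[i, j]``.
    ``log_q`` is the natural log of the partition function Q (the open
    chain has energy zero, so Q >= 1 always).
    """

    log_q: float
    pair_prob: np.ndarray
    unpaired_prob: np.ndarray
    rt: float

    @property
    def q(self) -> float:
        return math.exp(self.log_q)

    @property
    def n(self) -> int:
        return len(self.unpaired_prob)


def _matrices(seq: RnaSequence, model: EnergyModel):
    """Pairability / terminal / stacking matrices for the DP kernels."""
    codes = seq.codes()
    n = len(codes)
    pidx = PAIR_INDEX[codes[:, None], codes[None, :]]
    span_ok = (np.arange(n)[None, :] - np.arange(n)[:, None] - 1) >= model.min_hairpin
    pairable = (pidx >= 0) & span_ok
    tau = np.where(pidx >= 0, model.pair_terminal[np.clip(pidx, 0, 5)], 0.0)
    stk = np.zeros((n, n))
    if n >= 2:
        inner = np.full((n, n), -1, dtype=np.int64)
        inner[:-1, 1:] = pidx[1:, :-1]  # pair index of (i+1, j-1)
        ok = (pidx >= 0) & (inner >= 0)
        stk[ok] = model.stack[pidx[ok], inner[ok]]
    return pairable, np.zeros((n, n)), tau, stk


def _loop_vectors(model: EnergyModel, n: int):
    return model.loop_tables(n)


def mfe_fold(seq: RnaSequence, model: EnergyModel | None = None):
    """Predict the minimum-free-energy structure.

    Returns ``(structure, energy_kcal_mol)``.  A sequence with no canonical
    pairing possibilities folds to the open chain at 0.0 kcal/mol.
    """
    model = model or default_model()
    n = len(seq)
    pairable, pen, tau, stk = _matrices(seq, model)
    hp, bl, il = _loop_vectors(model, n)
    energy, pairs = mfe_matrix(
        n, pairable, pen, tau, stk, hp, bl, il,
        model.ml_offset, model.ml_helix, model.ml_unpaired, model.max_internal,
    )
    return SecondaryStructure(tuple(int(x) for x in pairs)), float(energy)


def _loop_children(pairs, i: int, j: int):
    """Directly nested pairs within (i, j), exclusive bounds."""
    out = []
    k = i + 1
    while k < j:
        if pairs[k] > k:
            out.append((k, pairs[k]))
            k = pairs[k] + 1
        else:
            k += 1
    return out


def energy_of(
    structure: SecondaryStructure, seq: RnaSequence, model: EnergyModel | None = None
) -> float:
    """Free energy of a given structure on a given sequence (kcal/mol).

    Decomposes the structure into stacks, hairpin/bulge/internal loops,
    multibranch loops and the exterior loop and sums the model terms.  Every
    loop charges the helix-end penalty of each pair bordering it.  Raises
    ValueError if the structure is incompatible with the sequence
    (non-canonical pair, length mismatch, sub-minimal hairpin).
    """
    model = model or default_model()
    structure.validate(seq)
    pairs = structure.pairs
    codes = seq.codes()

    def pidx(i, j):
        return int(PAIR_INDEX[codes[i], codes[j]])

    def tau(i, j):
        return float(model.pair_terminal[pidx(i, j)])

    total = 0.0
    stack = [(-1, len(seq))]  # virtual exterior "pair"
    while stack:
        i, j = stack.pop()
        children = _loop_children(pairs, i, j)
        if i < 0:  # exterior loop
            total += sum(tau(k, l) for k, l in children)
        elif not children:
            total += model.hairpin_penalty(j - i - 1) + tau(i, j)
        elif len(children) == 1:
            (k, l) = children[0]
            sz1, sz2 = k - i - 1, j - l - 1
            if sz1 == 0 and sz2 == 0:
                total += float(model.stack[pidx(i, j), pidx(k, l)])
            elif sz1 == 0 or sz2 == 0:
                total += model.bulge_penalty(sz1 + sz2) + tau(i, j) + tau(k, l)
            else:
                total += model.internal_penalty(sz1 + sz2) + tau(i, j) + tau(k, l)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            total += (
                model.ml_offset
                + model.ml_helix * (1 + len(children))
                + model.ml_unpaired * unpaired
                + tau(i, j)
                + sum(tau(k, l) for k, l in children)
            )
        stack.extend(children)
    return total


def partition_function(seq: RnaSequence, model: EnergyModel | None = None) -> EnsembleSummary:
    """Boltzmann partition function and base-pair probabilities.

    Inside arrays are rescaled per nucleotide on long sequences, keeping the
    computation finite well past N = 2000; ``log_q`` is always exact in the
    log domain.
    """
    model = model or default_model()
    n = len(seq)
    pairable, pen, tau, stk = _matrices(seq, model)
    hp, bl, il = _loop_vectors(model, n)
    sf = 1.0
    if n > _SCALE_THRESHOLD:
        _, e_mfe = mfe_fold(seq, model)
        if e_mfe < 0:
            sf = math.exp(-1.07 * e_mfe / (model.rt * n))
    log_q, pr = pf_matrix(
        n, pairable, pen, tau, stk, hp, bl, il,
        model.ml_offset, model.ml_helix, model.ml_unpaired,
        model.max_internal, model.rt, sf,
    )
    unpaired = np.clip(1.0 - pr.sum(axis=1), 0.0, 1.0)
    return EnsembleSummary(float(log_q), pr, unpaired, model.rt)


def ensemble_defect(s: SecondaryStructure, ens: EnsembleSummary):
    """Ensemble defect of structure s: the expected number of nucleotides
    whose conformation differs from a Boltzmann-sampled structure.

    Returns ``(defect, normalized_defect)`` with the normalized value in
    [0, 1].  Per position the retained probability is the pairing
    probability with the partner assigned by s, or the unpaired probability
    where s leaves the position single-stranded.
    """
    if len(s) != ens.n:
        raise ValueError("structure/ensemble length mismatch")
    p_keep = 0.0
    for i, j in enumerate(s.pairs):
        p_keep += ens.pair_prob[i, j] if j >= 0 else ens.unpaired_prob[i]
    defect = ens.n - p_keep
    return defect, defect / ens.n


def max_expect_structure(ens: EnsembleSummary, gamma: float = 1.0) -> SecondaryStructure:
    """Maximum-expected-accuracy structure from pairing probabilities.

    Maximizes ``sum(2*gamma*p_ij) + sum(p_unpaired_i)`` over pseudoknot-free
    structures; with gamma = 1 this is the structure of minimum ensemble
    defect.
    """
    from .rna import MIN_HAIRPIN

    pairs = mea_matrix(ens.n, ens.pair_prob, ens.unpaired_prob, float(gamma), MIN_HAIRPIN)
    return SecondaryStructure(tuple(int(x) for x in pairs))


def enumerate_structures(seq: RnaSequence) -> list:
    """All pseudoknot-free canonical structures of a short sequence.

    The exhaustive oracle: every structure satisfying the pairing
    invariants, without duplicates.  Refuses sequences longer than
    ENUMERATION_LIMIT nucleotides.
    """
    from .rna import MIN_HAIRPIN

    n = len(seq)
    if n > ENUMERATION_LIMIT:
        raise ValueError(f"enumeration limited to N <= {ENUMERATION_LIMIT} (got {n})")
    codes = seq.codes()

    memo: dict = {}

    def enum(i: int, j: int):
        if i > j:
            return [[]]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = [rest for rest in enum(i + 1, j)]
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if PAIR_INDEX[codes[i], codes[k]] >= 0:
                for inner in enum(i + 1, k - 1):
                    for outer in enum(k + 1, j):
                        out.append([(i, k)] + inner + outer)
        memo[key] = out
        return out

    return [SecondaryStructure.from_pairs(n, plist) for plist in enum(0, n - 1)]


def boltzmann_probability(
    s: SecondaryStructure, seq: RnaSequence, ens: EnsembleSummary,
    model: EnergyModel | None = None,
) -> float:
    """Probability of one structure in the ensemble: exp(-E/RT) / Q."""
    model = model or default_model()
    return math.exp(-energy_of(s, seq, model) / model.rt - ens.log_q)
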