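"""The four classification features.

For a group of 3-6 homologous sequences with an alignment, the classifier
consumes:

* **SCI** — structure conservation index, ``E_c / E_s``: the mean free
  energy of the common structure mapped onto each sequence, over the mean
  single-sequence MFE.  Near 1 when the group shares one structure.
* **mean folding free-energy Z score** — per sequence, how many null
  standard deviations the MFE free energy sits below the mean of
  mononucleotide-shuffled versions of the same sequence; averaged over the
  group.  Stable structured RNAs score strongly negative.
* **mean normalized ensemble-defect Z score** — the same construction for
  the normalized ensemble defect of the minimum-defect (MEA, gamma = 1)
  structure: a measure of how concentrated the Boltzmann ensemble is.
* **average Shannon entropy** — per alignment column, the entropy of the
  symbol distribution over {A, C, G, U, -} in natural log units, averaged
  over columns; a proxy for sequence diversity that tells the classifier
  when SCI is informative.

Nulls are sampled by shuffling (exact) or predicted by trained regression
surrogates (fast); see :mod:`multifind.zsurrogate`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .consensus import CommonStructureResult, common_structure
from .energy import EnergyModel, default_model
from .folding import ensemble_defect, max_expect_structure, mfe_fold, partition_function
from .rna import RnaSequence

logger = logging.getLogger(__name__)

ENTROPY_ALPHABET = "ACGU-"

#: feature order consumed by the classifier
FEATURE_NAMES = ("sci", "energy_z", "defect_z", "entropy")


@dataclass(frozen=True)
class CompositionFeatures:
    """Length and composition ratios driving the Z-score surrogates."""

    length: int
    gc: float        # (G+C) / length
    g_of_gc: float   # G / (G+C), 0.5 when no G or C
    a_of_au: float   # A / (A+U), 0.5 when no A or U

    def as_array(self) -> np.ndarray:
        return np.array([self.length, self.gc, self.g_of_gc, self.a_of_au])


@dataclass(frozen=True)
class NullDistribution:
    """Mean and standard deviation of a statistic over sequence shuffles."""

    mu: float
    sigma: float
    n_shuffles: int
    statistic: str   # "energy" | "defect"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_shuffles < 2:
            raise ValueError("need at least 2 shuffles")


@dataclass(frozen=True)
class FeatureVector:
    """(SCI, mean dG Z, mean defect Z, average Shannon entropy)."""

    sci: float
    energy_z: float
    defect_z: float
    entropy: float

    def as_array(self, use_defect: bool = True) -> np.ndarray:
        if use_defect:
            return np.array([self.sci, self.energy_z, self.defect_z, self.entropy])
        return np.array([self.sci, self.energy_z, self.entropy])


# ---------------------------------------------------------------------------
# composition and shuffling

def composition_features(seq: RnaSequence) -> CompositionFeatures:
    """Length, GC fraction, G/(G+C) and A/(A+U); fractions ignore N residues,
    and ratios with an empty denominator default to the neutral value 0.5."""
    counts = {b: seq.residues.count(b) for b in "ACGU"}
    informative = sum(counts.values())
    gc = counts["G"] + counts["C"]
    au = counts["A"] + counts["U"]
    return CompositionFeatures(
        length=len(seq),
        gc=gc / informative if informative else 0.5,
        g_of_gc=counts["G"] / gc if gc else 0.5,
        a_of_au=counts["A"] / au if au else 0.5,
    )


def shuffle_sequence(seq: RnaSequence, rng: np.random.Generator) -> RnaSequence:
    """A uniform mononucleotide shuffle: a random permutation of the
    residues, preserving composition exactly."""
    residues = np.array(list(seq.residues))
    rng.shuffle(residues)
    return RnaSequence(seq.id, "".join(residues))


def _statistic(seq: RnaSequence, statistic: str, model: EnergyModel) -> float:
    if statistic == "energy":
        return mfe_fold(seq, model)[1]
    if statistic == "defect":
        ens = partition_function(seq, model)
        mea = max_expect_structure(ens, gamma=1.0)
        return ensemble_defect(mea, ens)[1]
    raise ValueError(f"unknown statistic {statistic!r}")


def sample_null(
    seq: RnaSequence,
    statistic: str,
    n_shuffles: int,
    model: EnergyModel | None = None,
    rng: np.random.Generator | None = None,
) -> NullDistribution:
    """Null mean/SD of a folding statistic over mononucleotide shuffles.

    ``statistic`` is ``"energy"`` (MFE free energy, kcal/mol) or
    ``"defect"`` (normalized ensemble defect of the MEA structure).
    """
    model = model or default_model()
    rng = rng if rng is not None else np.random.default_rng()
    vals = np.array(
        [_statistic(shuffle_sequence(seq, rng), statistic, model) for _ in range(n_shuffles)]
    )
    return NullDistribution(float(vals.mean()), float(vals.std(ddof=0)), n_shuffles, statistic)


def z_score(value: float, null: NullDistribution) -> float:
    """(value - mu) / sigma, with Z = 0 by convention when sigma = 0
    (degenerate nulls such as homopolymers)."""
    if null.sigma == 0:
        return 0.0
    return (value - null.mu) / null.sigma


# ---------------------------------------------------------------------------
# group-level features

def sci(common: CommonStructureResult, seqs: list, model: EnergyModel | None = None) -> float:
    """Structure conservation index E_c / E_s.

    E_s is the mean single-sequence MFE of the group.  When E_s is not
    negative (nothing folds), the ratio is undefined and 0 is returned.
    """
    model = model or default_model()
    e_s = float(np.mean([mfe_fold(s, model)[1] for s in seqs]))
    if e_s >= -1e-9:
        return 0.0
    return common.e_c / e_s


def alignment_entropy(aln: Alignment) -> float:
    """Average per-column Shannon entropy over {A, C, G, U, -}, natural log."""
    total = 0.0
    for p in range(aln.ncol):
        col = aln.column(p)
        n = len(col)
        for ch in ENTROPY_ALPHABET:
            k = col.count(ch)
            if k:
                pk = k / n
                total -= pk * math.log(pk)
    return total / aln.ncol


def feature_vector(
    aln: Alignment,
    z_source: str = "sampled",
    n_shuffles: int = 1000,
    model: EnergyModel | None = None,
    rng: np.random.Generator | None = None,
    engine: str = "consensus",
    surrogates: dict | None = None,
    engine_config: dict | None = None,
) -> FeatureVector:
    """Compute all four features for one aligned group of sequences.

    ``z_source`` selects shuffle-sampled nulls (``"sampled"``) or trained
    regression surrogates (``"surrogate"``, requires ``surrogates`` with
    keys ``"energy"`` and ``"defect"``).  Sequences whose composition falls
    outside a surrogate's trained range fall back to sampled nulls with a
    warning.
    """
    model = model or default_model()
    rng = rng if rng is not None else np.random.default_rng()
    seqs = aln.degapped()

    common = common_structure(aln, engine=engine, model=model, engine_config=engine_config)
    sci_val = sci(common, seqs, model)

    zs_energy, zs_defect = [], []
    for seq in seqs:
        e = _statistic(seq, "energy", model)
        d = _statistic(seq, "defect", model)
        for statistic, value, acc in (("energy", e, zs_energy), ("defect", d, zs_defect)):
            null = None
            if z_source == "surrogate":
                surr = (surrogates or {}).get(statistic)
                if surr is None:
                    raise ValueError(f"no surrogate model supplied for {statistic!r}")
                feats = composition_features(seq)
                if surr.in_range(feats):
                    mu, sigma = surr.predict_mu_sigma(feats)
                    null = NullDistribution(mu, sigma, surr.n_shuffles, statistic)
                else:
                    logger.warning(
                        "sequence %s outside surrogate training range; sampling null", seq.id
                    )
            if null is None:
                null = sample_null(seq, statistic, n_shuffles, model, rng)
            acc.append(z_score(value, null))

    return FeatureVector(
        sci=sci_val,
        energy_z=float(np.mean(zs_energy)),
        defect_z=float(np.mean(zs_defect)),
        entropy=alignment_entropy(aln),
    )
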