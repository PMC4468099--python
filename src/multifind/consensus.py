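"""Common secondary structure for a group of homologous sequences.

The default engine folds the alignment columns with the same
minimum-free-energy recursions as single-sequence folding, but every energy
term is averaged over the rows (an alignment-folding scheme in the spirit of
RNAalifold, without covariance bonuses).  Rows that cannot form a canonical
pair at a paired column pair — or are gapped there — contribute a fixed
penalty instead, so sparse exceptions do not veto strongly supported pairs.
The consensus is then mapped onto each row by deleting gap columns and
dropping pairs that become non-canonical, and each mapped structure is
scored with the single-sequence model; the mean of those energies is E_c,
the numerator of the structure conservation index.

An adapter for an external simultaneous-fold-and-align executable (e.g.
Multilign from RNAstructure) is provided for users who have one installed;
it fills the same result type, so the two engines are interchangeable
downstream.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._kernels import mfe_matrix
from .alignment import GAP, Alignment
from .energy import EnergyModel, default_model
from .folding import energy_of
from .rna import ALPHABET, PAIR_INDEX, RnaSequence, SecondaryStructure, read_ct

logger = logging.getLogger(__name__)

#: mean penalty per row that is gapped or non-canonical at a consensus pair
DEFAULT_GAP_PENALTY = 0.5


class EngineUnavailableError(RuntimeError):
    """Raised when the configured external structure engine cannot be run."""


@dataclass
class CommonStructureResult:
    """Consensus pairing over alignment columns plus its per-row projection.

    ``e_c`` is the arithmetic mean of the per-sequence free energies of the
    mapped structures.
    """

    consensus: SecondaryStructure            # over alignment columns
    structures: list                         # per-row SecondaryStructure (de-gapped)
    sequences: list                          # per-row RnaSequence (de-gapped)
    energies: list                           # per-row kcal/mol
    engine: str = "consensus"

    @property
    def e_c(self) -> float:
        return float(np.mean(self.energies))


def _consensus_matrices(aln: Alignment, model: EnergyModel, gap_penalty: float):
    """Row-averaged pairability / penalty / terminal / stacking matrices."""
    nrow, ncol = aln.n_rows, aln.ncol
    codes = np.full((nrow, ncol), -1, dtype=np.int64)
    for r, row in enumerate(aln.rows):
        for p, ch in enumerate(row):
            if ch != GAP:
                codes[r, p] = ALPHABET.index(ch)

    pidx = np.full((nrow, ncol, ncol), -1, dtype=np.int64)
    valid = codes >= 0
    for r in range(nrow):
        c = codes[r]
        pidx[r][np.ix_(valid[r], valid[r])] = PAIR_INDEX[np.ix_(c[valid[r]], c[valid[r]])]

    canonical = pidx >= 0                       # (nrow, ncol, ncol)
    n_can = canonical.sum(axis=0)
    span_ok = (np.arange(ncol)[None, :] - np.arange(ncol)[:, None] - 1) >= model.min_hairpin
    pairable = (n_can >= 1) & span_ok
    pairpen = gap_penalty * (nrow - n_can) / nrow

    term = np.zeros((ncol, ncol))
    for r in range(nrow):
        term += np.where(canonical[r], model.pair_terminal[np.clip(pidx[r], 0, 5)], 0.0)
    tau = term / nrow

    stk = np.zeros((ncol, ncol))
    if ncol >= 2:
        for r in range(nrow):
            outer = pidx[r]
            inner = np.full((ncol, ncol), -1, dtype=np.int64)
            inner[:-1, 1:] = outer[1:, :-1]
            ok = (outer >= 0) & (inner >= 0)
            stk[ok] += model.stack[outer[ok], inner[ok]]
    stk /= nrow
    return pairable, pairpen, tau, stk


def map_to_row(
    consensus: SecondaryStructure, aln: Alignment, row: int, model: EnergyModel
) -> SecondaryStructure:
    """Project a column-level consensus onto one row's ungapped sequence.

    Pairs whose columns are gapped in the row, are non-canonical for the
    row's residues, or whose projected hairpin span falls below the minimum
    are dropped.
    """
    colmap = aln.column_to_position()[row]
    seq = aln.degapped()[row]
    kept = []
    for p, q in consensus.base_pairs():
        i, j = colmap[p], colmap[q]
        if i < 0 or j < 0:
            continue
        if j - i - 1 < model.min_hairpin:
            continue
        if not seq.can_pair(i, j):
            continue
        kept.append((i, j))
    return SecondaryStructure.from_pairs(len(seq), kept)


def consensus_fold(
    aln: Alignment,
    model: EnergyModel | None = None,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> CommonStructureResult:
    """Predict a common structure by row-averaged energy minimization.

    Returns the consensus pairing over alignment columns, its projection
    onto every row, and the per-row free energies whose mean is E_c.
    """
    model = model or default_model()
    ncol = aln.ncol
    pairable, pairpen, tau, stk = _consensus_matrices(aln, model, gap_penalty)
    hp, bl, il = model.loop_tables(ncol)
    _, pairs = mfe_matrix(
        ncol, pairable, pairpen, tau, stk, hp, bl, il,
        model.ml_offset, model.ml_helix, model.ml_unpaired, model.max_internal,
    )
    consensus = SecondaryStructure(tuple(int(x) for x in pairs))
    seqs = aln.degapped()
    structures = [map_to_row(consensus, aln, r, model) for r in range(aln.n_rows)]
    energies = [energy_of(s, q, model) for s, q in zip(structures, seqs)]
    return CommonStructureResult(consensus, structures, seqs, energies, engine="consensus")


def external_engine_adapter(
    seqs: list,
    config: dict | None = None,
    model: EnergyModel | None = None,
) -> CommonStructureResult:
    """Run an external common-structure executable and collect its CT output.

    ``config`` keys: ``executable`` (default ``"multilign"``), ``args``
    (extra command-line tokens, passed through verbatim).  The executable is
    expected to accept a list of FASTA files and write one CT file per
    sequence next to them.  Raises EngineUnavailableError when the tool is
    not on PATH.
    """
    model = model or default_model()
    config = config or {}
    exe = config.get("executable", "multilign")
    if shutil.which(exe) is None:
        raise EngineUnavailableError(f"external engine {exe!r} not found on PATH")

    with tempfile.TemporaryDirectory() as tmp:
        tmpdir = Path(tmp)
        fasta_paths, ct_paths = [], []
        for k, seq in enumerate(seqs):
            fa = tmpdir / f"seq{k}.fasta"
            fa.write_text(f">{seq.id}\n{seq.residues}\n")
            fasta_paths.append(str(fa))
            ct_paths.append(str(tmpdir / f"seq{k}.ct"))
        cmd = [exe, *config.get("args", [])]
        for fa, ct in zip(fasta_paths, ct_paths):
            cmd.extend([fa, ct])
        try:
            subprocess.run(cmd, check=True, capture_output=True)
        except (subprocess.CalledProcessError, OSError) as exc:
            raise EngineUnavailableError(f"external engine {exe!r} failed: {exc}") from exc
        structures = []
        for ct in ct_paths:
            _, struct = read_ct(ct)
            structures.append(struct)
    energies = [energy_of(s, q, model) for s, q in zip(structures, seqs)]
    consensus = structures[0]  # index-sequence structure stands in for the consensus
    return CommonStructureResult(consensus, structures, list(seqs), energies, engine="external")


def common_structure(
    aln: Alignment,
    engine: str = "consensus",
    model: EnergyModel | None = None,
    engine_config: dict | None = None,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> CommonStructureResult:
    """Dispatch to the configured engine, falling back to consensus folding
    with a logged warning when the external tool is unavailable."""
    model = model or default_model()
    if engine == "external":
        try:
            return external_engine_adapter(aln.degapped(), engine_config, model)
        except EngineUnavailableError as exc:
            logger.warning("%s; falling back to consensus engine", exc)
    elif engine != "consensus":
        raise ValueError(f"unknown engine {engine!r}")
    return consensus_fold(aln, model, gap_penalty)
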