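"""Nearest-neighbor free-energy model ("Turner-lite").

The model covers helix stacking, hairpin/bulge/internal loop initiation with
logarithmic length extrapolation, a linear multibranch-loop model
(offset + per-helix + per-unpaired), and a terminal AU/GU helix-end penalty.
Dangling ends and coaxial stacking are deliberately out of the model so that
structure scoring, the minimum-free-energy search, the partition function
and exhaustive enumeration all agree exactly on every structure's energy.

The per-helix multibranch increment defaults to -0.6 kcal/mol, the value
supported by optical-melting estimates; temperature is 310.15 K and
RT = 0.6163 kcal/mol.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np

from .rna import PAIR_NAMES

#: coefficient of the logarithmic loop-size extrapolation, 1.75 * RT at 37 C
_LOG_EXTRAPOLATION = 1.75


@dataclass
class EnergyModel:
    """Parameter container used by every folding operation.

    Loop tables are dense per-size arrays in kcal/mol; indices beyond the
    shipped table are filled by ``dG(L) = dG(Lmax) + 1.75 RT ln(L / Lmax)``.
    """

    stack: np.ndarray            # (6, 6) pair-over-pair increments
    hairpin: np.ndarray          # penalty by loop size, index 0 unused
    bulge: np.ndarray
    internal: np.ndarray
    terminal_au: float = 0.5
    ml_offset: float = 9.3
    ml_helix: float = -0.6
    ml_unpaired: float = 0.0
    temperature: float = 310.15
    rt: float = 0.6163
    min_hairpin: int = 3
    max_internal: int = 30
    #: terminal penalty per pair code (AU, UA, GC, CG, GU, UG)
    pair_terminal: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.pair_terminal = np.array(
            [self.terminal_au, self.terminal_au, 0.0, 0.0, self.terminal_au, self.terminal_au]
        )

    # -- loop penalties ----------------------------------------------------
    def _loop(self, table: np.ndarray, size: int) -> float:
        lmax = len(table) - 1
        if size <= lmax:
            return float(table[size])
        return float(table[lmax]) + _LOG_EXTRAPOLATION * self.rt * math.log(size / lmax)

    def hairpin_penalty(self, size: int) -> float:
        if size < self.min_hairpin:
            raise ValueError(f"hairpin loop of {size} nt below minimum {self.min_hairpin}")
        return self._loop(self.hairpin, size)

    def bulge_penalty(self, size: int) -> float:
        return self._loop(self.bulge, size)

    def internal_penalty(self, size: int) -> float:
        return self._loop(self.internal, size)

    def loop_tables(self, n: int) -> tuple:
        """Dense (hairpin, bulge, internal) penalty vectors for sizes 0..n."""
        sizes = range(n + 1)
        hp = np.array([self._loop(self.hairpin, max(s, 1)) for s in sizes])
        hp[: self.min_hairpin] = np.inf
        bl = np.array([self._loop(self.bulge, max(s, 1)) for s in sizes])
        il = np.array([self._loop(self.internal, max(s, 2)) for s in sizes])
        return hp, bl, il


def _parse_table(path_text: str) -> dict:
    entries: dict = {"STACK": {}, "HAIRPIN": {}, "BULGE": {}, "INTERNAL": {}, "scalar": {}}
    for raw in path_text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        if tok[0] == "STACK":
            entries["STACK"][(tok[1], tok[2])] = float(tok[3])
        elif tok[0] in ("HAIRPIN", "BULGE", "INTERNAL"):
            entries[tok[0]][int(tok[1])] = float(tok[2])
        else:
            entries["scalar"][tok[0]] = float(tok[1])
    return entries


def load_energy_model(path=None) -> EnergyModel:
    """Load the shipped plain-text parameter file (or a user-supplied one)."""
    if path is None:
        text = (importlib.resources.files("multifind") / "data" / "turner_lite.dat").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    ent = _parse_table(text)
    sc = ent["scalar"]

    stack = np.full((6, 6), np.inf)
    for (p1, p2), e in ent["STACK"].items():
        stack[PAIR_NAMES.index(p1), PAIR_NAMES.index(p2)] = e
    if not np.isfinite(stack).all():
        raise ValueError("stacking table incomplete: all 6x6 canonical stacks required")

    def dense(d: dict) -> np.ndarray:
        lmax = max(d)
        arr = np.zeros(lmax + 1)
        for size in range(min(d), lmax + 1):
            if size not in d:
                raise ValueError(f"loop table has a gap at size {size}")
            arr[size] = d[size]
        return arr

    return EnergyModel(
        stack=stack,
        hairpin=dense(ent["HAIRPIN"]),
        bulge=dense(ent["BULGE"]),
        internal=dense(ent["INTERNAL"]),
        terminal_au=sc.get("TERMINAL_AU", 0.5),
        ml_offset=sc.get("MULTIBRANCH_OFFSET", 9.3),
        ml_helix=sc.get("MULTIBRANCH_HELIX", -0.6),
        ml_unpaired=sc.get("MULTIBRANCH_UNPAIRED", 0.0),
        temperature=sc.get("TEMPERATURE", 310.15),
        rt=sc.get("RT", 0.6163),
        min_hairpin=int(sc.get("MIN_HAIRPIN", 3)),
        max_internal=int(sc.get("MAX_INTERNAL_LOOP", 30)),
    )


_DEFAULT_MODEL: EnergyModel | None = None


def default_model() -> EnergyModel:
    """The shipped parameter set, loaded once per process."""
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = load_energy_model()
    return _DEFAULT_MODEL
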