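"""Loop-based nearest-neighbour free-energy model for DNA secondary structure.

The free energy of a structure is the sum over its loops:

    dG(s) = sum_{loop in s} dG(loop)

with sequence-dependent stacking for helical (stack) loops and size-dependent
penalties for hairpin, bulge and interior loops, an affine multiloop penalty,
and exterior faces at zero (the all-unpaired structure therefore has dG = 0
exactly). Stacking free energies are the unified DNA nearest-neighbour values
at 37 C (kcal/mol); loop penalty tables are extended beyond their tabulated
range with a Jacobson-Stockmayer logarithmic term. Coaxial stacking, dangles
and terminal AT penalties are deliberately omitted so that the dynamic
programmes and the exhaustive-enumeration oracle score exactly the same model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structures import Loop, SecondaryStructure, decompose_loops

__all__ = ["EnergyModel", "structure_free_energy", "GAS_CONSTANT_KCAL"]

#: Gas constant in kcal/(mol*K) — the "k" of the Boltzmann factor in molar units.
GAS_CONSTANT_KCAL = 0.0019872041

# Unified DNA nearest-neighbour stacks, dG37 in kcal/mol, keyed by the
# 5'->3' top-strand dinucleotide (bottom strand is the Watson-Crick
# complement). 16 entries collapsing to the 10 unique duplex steps.
_STACK_DG37 = {
    "AA": -1.00, "AC": -1.44, "AG": -1.28, "AT": -0.88,
    "CA": -1.45, "CC": -1.84, "CG": -2.17, "CT": -1.28,
    "GA": -1.30, "GC": -2.24, "GG": -1.84, "GT": -1.44,
    "TA": -0.58, "TC": -1.30, "TG": -1.45, "TT": -1.00,
}

# Size-dependent loop penalties (kcal/mol, 37 C); values beyond the largest
# tabulated size are extrapolated logarithmically.
_HAIRPIN_DG = {3: 3.5, 4: 3.6, 5: 3.8, 6: 4.0, 7: 4.2, 8: 4.3, 9: 4.5, 10: 4.6}
_BULGE_DG = {1: 4.0, 2: 2.9, 3: 3.1, 4: 3.2, 5: 3.3, 6: 3.5, 7: 3.7, 8: 3.9}
_INTERIOR_DG = {2: 3.2, 3: 3.6, 4: 4.0, 5: 4.4, 6: 4.6, 7: 4.8, 8: 5.0}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class EnergyModel:
    """Parameter set for the loop-sum free energy.

    Parameters
    ----------
    temperature:
        Kelvin; default 310.15 K (the assay runs at 37 C).
    k:
        Boltzmann/gas constant in kcal/(mol*K).
    multiloop_init, multiloop_branch, multiloop_unpaired:
        Affine multiloop penalty a + b * (#branches incl. closing pair)
        + c * (#unpaired in the loop).
    association_energy:
        Penalty per strand beyond the first in a complex (1 M standard
        state); applied at the complex level, not per loop.
    two_loop_max:
        Largest total unpaired size of a bulge/interior loop considered by
        the dynamic programmes (the usual MAXLOOP convention). Loops beyond
        it still receive a finite extrapolated energy when an explicitly
        given structure is scored.
    """

    temperature: float = 310.15
    k: float = GAS_CONSTANT_KCAL
    stack_dg: dict[str, float] = field(default_factory=lambda: dict(_STACK_DG37))
    hairpin_dg: dict[int, float] = field(default_factory=lambda: dict(_HAIRPIN_DG))
    bulge_dg: dict[int, float] = field(default_factory=lambda: dict(_BULGE_DG))
    interior_dg: dict[int, float] = field(default_factory=lambda: dict(_INTERIOR_DG))
    multiloop_init: float = 3.4
    multiloop_branch: float = 0.4
    multiloop_unpaired: float = 0.1
    association_energy: float = 1.96
    two_loop_max: int = 30

    @property
    def kT(self) -> float:
        return self.k * self.temperature

    # -- loop terms ---------------------------------------------------------

    def _sized(self, table: dict[int, float], n: int) -> float:
        if n in table:
            return table[n]
        nmax = max(table)
        if n < min(table):
            raise ValueError(f"loop size {n} below tabulated range")
        # Jacobson-Stockmayer entropic extrapolation
        return table[nmax] + 1.75 * self.kT * math.log(n / nmax)

    def hairpin_energy(self, n_unpaired: int) -> float:
        return self._sized(self.hairpin_dg, n_unpaired)

    def bulge_energy(self, n_unpaired: int) -> float:
        return self._sized(self.bulge_dg, n_unpaired)

    def interior_energy(self, n_unpaired: int) -> float:
        return self._sized(self.interior_dg, n_unpaired)

    def stack_energy(self, step: str) -> float:
        """dG of one helical step, keyed by the 5'->3' top dinucleotide."""
        return self.stack_dg[step]

    def multiloop_energy(self, n_branches: int, n_unpaired: int) -> float:
        """``n_branches`` counts the closing pair as well."""
        return (
            self.multiloop_init
            + self.multiloop_branch * n_branches
            + self.multiloop_unpaired * n_unpaired
        )

    def loop_energy(self, loop: Loop, sequence: str) -> float:
        if loop.kind == "exterior":
            return 0.0
        if loop.kind == "hairpin":
            return self.hairpin_energy(loop.size)
        if loop.kind == "stack":
            i, _ = loop.closing
            return self.stack_energy(sequence[i : i + 2])
        if loop.kind == "bulge":
            return self.bulge_energy(loop.size)
        if loop.kind == "interior":
            return self.interior_energy(loop.size)
        if loop.kind == "multiloop":
            return self.multiloop_energy(len(loop.branches) + 1, loop.size)
        raise ValueError(f"unknown loop kind {loop.kind!r}")

    # -- numeric views for the DP kernels -----------------------------------

    def tables(self, n: int) -> tuple[np.ndarray, ...]:
        """Dense arrays (stack 4x4, hairpin/bulge/interior up to size n)."""
        stack = np.zeros((4, 4))
        for step, dg in self.stack_dg.items():
            stack[_BASE_INDEX[step[0]], _BASE_INDEX[step[1]]] = dg
        size = max(n + 1, 4)
        hp = np.full(size, np.inf)
        bg = np.full(size, np.inf)
        il = np.full(size, np.inf)
        for m in range(3, size):
            hp[m] = self.hairpin_energy(m)
        for m in range(1, size):
            bg[m] = self.bulge_energy(m)
        for m in range(2, size):
            il[m] = self.interior_energy(m)
        return stack, hp, bg, il


def encode(sequence: str) -> np.ndarray:
    """Sequence as int8 codes A=0 C=1 G=2 T=3."""
    return np.array([_BASE_INDEX[b] for b in sequence], dtype=np.int8)


def structure_free_energy(
    structure: SecondaryStructure, model: EnergyModel
) -> float:
    """Loop-sum free energy dG(s) in kcal/mol; the empty structure scores 0."""
    seq = structure.sequence
    return sum(model.loop_energy(lp, seq) for lp in decompose_loops(structure))
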