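"""Structural ensembles: exhaustive enumeration, partition function, MFE.

Two independent routes compute ensemble quantities:

* :func:`enumerate_structures` — brute-force realization of the ensemble
  for short sequences (guarded at 22 nt), scoring every structure by the
  loop sum. This is the oracle against which the dynamic programmes are
  validated.
* :func:`partition_function` / :func:`mfe` — interval dynamic programmes
  over the same loop model (sum-product and min-plus respectively).

Probabilities follow the Boltzmann rule p(s) = exp(-dG(s)/kT) / Q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from .energy import EnergyModel, encode, structure_free_energy
from .pfdp import partition_function_dp
from .structures import SecondaryStructure

__all__ = [
    "ENUMERATION_GUARD",
    "EnsembleSummary",
    "enumerate_structures",
    "enumerate_pair_sets",
    "pair_set_energy",
    "partition_function",
    "structure_probability",
    "mfe",
    "ensemble_summary",
]

#: Longest total sequence the exhaustive enumerator will accept.
ENUMERATION_GUARD = 22

_WC_CODES = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def _wc(x: str, y: str) -> bool:
    return (x, y) in _WC_CODES


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_pair_sets(
    sequence: str, nicks: frozenset[int] = frozenset()
) -> list[tuple[tuple[int, int], ...]]:
    """All pseudoknot-free Watson-Crick pair sets of the concatenation.

    A childless pair needs >= 3 enclosed unpaired bases unless its loop
    contains a nick (then it is an exterior face with no size minimum).
    Connectivity is *not* filtered here.
    """
    n = len(sequence)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        if i > j:
            return ((),)
        out: list[tuple[tuple[int, int], ...]] = list(rec(i + 1, j))
        for k in range(i + 1, j + 1):
            if not _wc(sequence[i], sequence[k]):
                continue
            if k - i - 1 < 3 and not any(p in nicks for p in range(i, k)):
                continue
            for inner in rec(i + 1, k - 1):
                for right in rec(k + 1, j):
                    out.append(((i, k),) + inner + right)
        return tuple(out)

    result = list(rec(0, n - 1))
    rec.cache_clear()
    return result


def pair_set_energy(
    sequence: str,
    pairs: tuple[tuple[int, int], ...],
    nicks: frozenset[int],
    model: EnergyModel,
) -> float:
    """Loop-sum energy of one pair set, without building a structure object.

    Any loop exposing a nick scores 0 (exterior face). Assumes the pair set
    is valid (non-crossing, hairpin rule respected).
    """
    n = len(sequence)
    partner = [-1] * n
    for i, j in pairs:
        partner[i], partner[j] = j, i
    total = 0.0

    stack_faces = [(None, None)]
    while stack_faces:
        ci, cj = stack_faces.pop()
        lo = 0 if ci is None else ci + 1
        hi = n - 1 if cj is None else cj - 1
        unpaired = 0
        branches = []
        has_nick = ci is not None and ci in nicks
        p = lo
        while p <= hi:
            if partner[p] > p:
                branches.append((p, partner[p]))
                p = partner[p]
            else:
                unpaired += 1
            if p in nicks and p <= hi:
                has_nick = True
            p += 1
        for br in branches:
            stack_faces.append(br)
        if ci is None or has_nick:
            continue  # exterior face: 0
        if not branches:
            total += model.hairpin_energy(unpaired)
        elif len(branches) == 1:
            (k, l), = branches
            g1, g2 = k - ci - 1, cj - l - 1
            if g1 == 0 and g2 == 0:
                total += model.stack_energy(sequence[ci : ci + 2])
            elif g1 == 0 or g2 == 0:
                total += model.bulge_energy(g1 + g2)
            else:
                total += model.interior_energy(g1 + g2)
        else:
            total += model.multiloop_energy(len(branches) + 1, unpaired)
    return total


def enumerate_structures(
    sequence: str, model: EnergyModel
) -> list[tuple[SecondaryStructure, float]]:
    """Every pseudoknot-free structure of a single strand, with its energy.

    Includes the empty structure (energy 0). Guarded at
    ``ENUMERATION_GUARD`` nucleotides; longer inputs should use the dynamic
    programming route (:func:`partition_function`, :func:`mfe`).
    """
    if len(sequence) > ENUMERATION_GUARD:
        raise ValueError(
            f"sequence of length {len(sequence)} exceeds the enumeration "
            f"guard ({ENUMERATION_GUARD} nt); use the DP route instead"
        )
    out = []
    for pairs in enumerate_pair_sets(sequence):
        energy = pair_set_energy(sequence, pairs, frozenset(), model)
        struct = SecondaryStructure((sequence,), frozenset(pairs), validate=False)
        out.append((struct, energy))
    return out


# ---------------------------------------------------------------------------
# dynamic programmes
# ---------------------------------------------------------------------------

def partition_function(sequence: str, model: EnergyModel) -> float:
    """Q = sum_s exp(-dG(s)/kT) by interval dynamic programming."""
    return partition_function_dp(encode(sequence), [], model)


def structure_probability(
    structure: SecondaryStructure, sequence: str, model: EnergyModel
) -> float:
    """Equilibrium probability p(s) = exp(-dG(s)/kT) / Q."""
    if structure.sequence != sequence or len(structure.strands) != 1:
        raise ValueError("structure is not a single-strand structure of this sequence")
    dg = structure_free_energy(structure, model)
    q = partition_function(sequence, model)
    return math.exp(-dg / model.kT) / q


def _mfe_tables(sequence: str, model: EnergyModel):
    """Min-plus interval DP; returns value and choice tables for traceback."""
    n = len(sequence)
    INF = math.inf
    cap = model.two_loop_max
    a_ml, b_ml, c_ml = (
        model.multiloop_init,
        model.multiloop_branch,
        model.multiloop_unpaired,
    )
    Eb = [[INF] * n for _ in range(n)]
    Cb: dict[tuple[int, int], tuple] = {}
    # series tables indexed [a][b+1]
    S = [[0.0] * (n + 1) for _ in range(n + 1)]
    Cs: dict[tuple[int, int], tuple] = {}
    M = [[INF] * (n + 1) for _ in range(n + 1)]
    Cm: dict[tuple[int, int], tuple] = {}
    M2 = [[INF] * (n + 1) for _ in range(n + 1)]
    Cm2: dict[tuple[int, int], tuple] = {}

    for b in range(n):
        for a in range(b, -1, -1):
            if b > a and _wc(sequence[a], sequence[b]):
                best, choice = INF, None
                h = b - a - 1
                if h >= 3:
                    best, choice = model.hairpin_energy(h), ("hairpin",)
                for k in range(a + 1, b - 1):
                    g1 = k - a - 1
                    if g1 > cap:
                        break
                    for l in range(b - 1, k, -1):
                        g2 = b - l - 1
                        if g1 + g2 > cap:
                            break
                        if Eb[k][l] == INF:
                            continue
                        if g1 == 0 and g2 == 0:
                            e = model.stack_energy(sequence[a : a + 2])
                        elif g1 == 0 or g2 == 0:
                            e = model.bulge_energy(g1 + g2)
                        else:
                            e = model.interior_energy(g1 + g2)
                        if e + Eb[k][l] < best:
                            best, choice = e + Eb[k][l], ("two", k, l)
                if b - a >= 2 and a_ml + b_ml + M2[a + 1][b] < best:
                    best, choice = a_ml + b_ml + M2[a + 1][b], ("multi",)
                if choice is not None:
                    Eb[a][b] = best
                    Cb[(a, b)] = choice
            # series S (exterior), M (>=1 branch), M2 (>=2 branches)
            sbest, schoice = S[a + 1][b + 1], ("unpaired",)
            mbest, mchoice = (
                (c_ml + M[a + 1][b + 1], ("unpaired",))
                if M[a + 1][b + 1] < INF
                else (INF, None)
            )
            m2best, m2choice = (
                (c_ml + M2[a + 1][b + 1], ("unpaired",))
                if M2[a + 1][b + 1] < INF
                else (INF, None)
            )
            for l in range(a + 1, b + 1):
                if Eb[a][l] == INF:
                    continue
                cand = Eb[a][l] + S[l + 1][b + 1]
                if cand < sbest:
                    sbest, schoice = cand, ("branch", l)
                tail = Eb[a][l] + b_ml + c_ml * (b - l)
                if tail < mbest:
                    mbest, mchoice = tail, ("branch_tail", l)
                if M[l + 1][b + 1] < INF:
                    cont = Eb[a][l] + b_ml + M[l + 1][b + 1]
                    if cont < mbest:
                        mbest, mchoice = cont, ("branch_more", l)
                    if cont < m2best:
                        m2best, m2choice = cont, ("branch_more", l)
            S[a][b + 1], Cs[(a, b)] = sbest, schoice
            M[a][b + 1], Cm[(a, b)] = mbest, mchoice
            M2[a][b + 1], Cm2[(a, b)] = m2best, m2choice

    return S, Cb, Cs, Cm, Cm2


def mfe(
    sequence: str, model: EnergyModel
) -> tuple[SecondaryStructure, float]:
    """Minimum free energy structure and energy of a single strand.

    The empty structure (0 kcal/mol) is always admissible, so the MFE is
    never positive. Ties are broken deterministically by the DP scan order
    (earlier options win only on strict improvement, so the first optimal
    candidate encountered is kept).
    """
    n = len(sequence)
    S, Cb, Cs, Cm, Cm2 = _mfe_tables(sequence, model)
    pairs: set[tuple[int, int]] = set()

    def trace_pair(i: int, j: int) -> None:
        pairs.add((i, j))
        choice = Cb[(i, j)]
        if choice[0] == "two":
            trace_pair(choice[1], choice[2])
        elif choice[0] == "multi":
            trace_m(i + 1, j - 1, Cm2)

    def trace_m(a: int, b: int, table) -> None:
        if a > b:
            return
        choice = table[(a, b)]
        if choice[0] == "unpaired":
            trace_m(a + 1, b, table)
        elif choice[0] == "branch_tail":
            trace_pair(a, choice[1])
        else:  # branch_more
            trace_pair(a, choice[1])
            trace_m(choice[1] + 1, b, Cm)

    def trace_ext(a: int, b: int) -> None:
        if a > b:
            return
        choice = Cs[(a, b)]
        if choice[0] == "unpaired":
            trace_ext(a + 1, b)
        else:
            trace_pair(a, choice[1])
            trace_ext(choice[1] + 1, b)

    trace_ext(0, n - 1)
    energy = S[0][n]
    structure = SecondaryStructure((sequence,), frozenset(pairs))
    return structure, energy


@dataclass(frozen=True)
class EnsembleSummary:
    """Partition function and MFE of one strand's structural ensemble."""

    sequence: str
    Q: float
    mfe_energy: float
    mfe_structure: SecondaryStructure


def ensemble_summary(sequence: str, model: EnergyModel) -> EnsembleSummary:
    """Convenience wrapper computing Q and the MFE in one call."""
    q = partition_function(sequence, model)
    structure, energy = mfe(sequence, model)
    return EnsembleSummary(sequence, q, energy, structure)
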