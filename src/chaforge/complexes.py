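"""Test-tube equilibrium: complex enumeration and concentration solving.

A *tube* holds a set of strand species with total concentrations; the strands
interact to form complexes up to a maximum number of strands L. For each
complex ordering (a necklace of strand names, distinct up to circular
rotation) the multi-strand partition function Q_j is computed; the
equilibrium concentrations x then minimise the free energy of the dilute
solution

    min_x  sum_j x_j (log x_j - log Q_j - 1)   s.t.  A x = x0,  x >= 0,

where A is the strand/complex stoichiometry matrix and x0 the strand totals
(molar, 1 M standard state). The solver works on the concave dual: strand
potentials lambda with x_j = Q_j exp(sum_i A_ij lambda_i) (the KKT
certificate), iterated by a damped Newton method on the mass balances. A
complex's Q_j includes an association penalty per strand beyond the first
and is divided by the rotational symmetry order of its necklace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyModel, encode
from .ensemble import ENUMERATION_GUARD, enumerate_pair_sets, pair_set_energy
from .pfdp import partition_function_dp
from .strands import NucleotideStrand, OligoPanel

__all__ = [
    "ComplexSpecies",
    "Tube",
    "EquilibriumState",
    "enumerate_complexes",
    "complex_partition_function",
    "solve_equilibrium",
    "solve_tube",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Equilibrium solver failed to reach the requested residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


def _canonical_rotation(names: tuple[str, ...]) -> tuple[str, ...]:
    rotations = [names[i:] + names[:i] for i in range(len(names))]
    return min(rotations)


def _symmetry_order(names: tuple[str, ...]) -> int:
    return sum(
        1
        for i in range(len(names))
        if names[i:] + names[:i] == names
    )


@dataclass(frozen=True)
class ComplexSpecies:
    """An ordered multiset of strands, canonical under circular rotation."""

    strands: tuple[str, ...]
    Q: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "strands", _canonical_rotation(tuple(self.strands)))

    @property
    def name(self) -> str:
        return "·".join(self.strands)  # middle dot, e.g. H1·H2

    @property
    def size(self) -> int:
        return len(self.strands)

    @property
    def symmetry(self) -> int:
        """Order of the rotational symmetry group of the ordering."""
        return _symmetry_order(self.strands)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.strands:
            out[s] = out.get(s, 0) + 1
        return out

    def with_Q(self, q: float) -> "ComplexSpecies":
        return ComplexSpecies(self.strands, q)


@dataclass
class Tube:
    """Strand totals (entered in nM, stored as given) and tube settings."""

    concentrations_nM: dict[str, float]
    max_complex_size: int = 4
    temperature: float = 310.15

    def __post_init__(self) -> None:
        if self.max_complex_size < 1:
            raise ValueError("max complex size must be >= 1")
        for name, conc in self.concentrations_nM.items():
            if conc < 0:
                raise ValueError(f"negative total for strand {name!r}")

    @property
    def totals_molar(self) -> dict[str, float]:
        return {k: v * 1e-9 for k, v in self.concentrations_nM.items()}


def enumerate_complexes(
    strand_names: list[str], max_size: int
) -> list[ComplexSpecies]:
    """All rotation-distinct strand orderings up to ``max_size`` strands.

    Deterministic order: by size, then lexicographically by canonical
    ordering. Includes every monomer.
    """
    if max_size < 1:
        raise ValueError("max complex size must be >= 1")
    seen: set[tuple[str, ...]] = set()
    out: list[ComplexSpecies] = []
    for size in range(1, max_size + 1):
        bucket = set()
        stack: list[tuple[str, ...]] = [()]
        while stack:
            cur = stack.pop()
            if len(cur) == size:
                bucket.add(_canonical_rotation(cur))
                continue
            for name in strand_names:
                stack.append(cur + (name,))
        for names in sorted(bucket):
            if names not in seen:
                seen.add(names)
                out.append(ComplexSpecies(names))
    return out


def complex_partition_function(
    complex_: ComplexSpecies,
    panel: OligoPanel | dict[str, NucleotideStrand],
    model: EnergyModel,
    method: str = "dp",
) -> float:
    """Partition function Q_j over connected structures of one ordering.

    Includes the association penalty exp(-(L-1) * dG_assoc / kT) and the
    1/R rotational symmetry factor. ``method="enumerate"`` uses the
    exhaustive oracle (guarded at {guard} nt total).
    """
    strands = [panel[name].bases for name in complex_.strands]
    seq = "".join(strands)
    nicks: list[int] = []
    pos = 0
    for s in strands[:-1]:
        pos += len(s)
        nicks.append(pos - 1)
    if method == "dp":
        nick_flags = [False] * len(seq)
        for p in nicks:
            nick_flags[p] = True
        q_struct = partition_function_dp(encode(seq), nick_flags, model)
    elif method == "enumerate":
        if len(seq) > ENUMERATION_GUARD:
            raise ValueError(
                f"total length {len(seq)} exceeds the enumeration guard "
                f"({ENUMERATION_GUARD} nt) in oracle mode"
            )
        nfro = frozenset(nicks)
        strand_of: list[int] = []
        for si, s in enumerate(strands):
            strand_of += [si] * len(s)
        q_struct = 0.0
        for pairs in enumerate_pair_sets(seq, nfro):
            if len(strands) > 1 and not _connected(pairs, strand_of, len(strands)):
                continue
            q_struct += math.exp(
                -pair_set_energy(seq, pairs, nfro, model) / model.kT
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    n_strands = len(strands)
    assoc = math.exp(-(n_strands - 1) * model.association_energy / model.kT)
    return q_struct * assoc / complex_.symmetry


complex_partition_function.__doc__ = complex_partition_function.__doc__.format(
    guard=ENUMERATION_GUARD
)


def _connected(pairs, strand_of, n_strands) -> bool:
    parent = list(range(n_strands))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in pairs:
        a, b = find(strand_of[i]), find(strand_of[j])
        if a != b:
            parent[a] = b
    return len({find(k) for k in range(n_strands)}) == 1


@dataclass
class EquilibriumState:
    """Solved tube: complex concentrations and solver diagnostics."""

    complexes: list[ComplexSpecies]
    concentrations_molar: np.ndarray
    strand_names: list[str]
    stoichiometry: np.ndarray  # A_ij, strands x complexes
    potentials: np.ndarray  # dual variables lambda_i
    mass_balance_residual: float  # max relative
    kkt_residual: float
    iterations: int
    converged: bool
    objective_history: list[float] = field(default_factory=list)

    def concentration_nM(self, complex_name: str) -> float:
        for c, x in zip(self.complexes, self.concentrations_molar):
            if c.name == complex_name or "·".join(c.strands) == complex_name:
                return x * 1e9
        raise KeyError(complex_name)

    def as_dict_nM(self) -> dict[str, float]:
        return {
            c.name: x * 1e9
            for c, x in zip(self.complexes, self.concentrations_molar)
        }


def solve_equilibrium(
    tube: Tube,
    complexes: list[ComplexSpecies],
    rel_tol: float = 1e-10,
    max_iter: int = 200,
) -> EquilibriumState:
    """Solve the constrained free-energy minimisation for a tube.

    Every complex must carry its partition function ``Q``; complexes with
    Q = 0 (no connected structure possible) are held at zero concentration.
    Deterministic initialisation distributes each strand total over its
    monomer, i.e. the ideal no-complex state.
    """
    names = [n for n, c in tube.totals_molar.items() if c > 0]
    x0 = np.array([tube.totals_molar[n] for n in names])
    live = [
        c
        for c in complexes
        if c.Q is not None
        and c.Q > 0.0
        and all(s in names for s in c.strands)
    ]
    monomers = {c.strands[0] for c in live if c.size == 1}
    missing = [n for n in names if n not in monomers]
    if missing:
        raise ValueError(f"no monomer complex with Q > 0 for strands {missing}")
    A = np.zeros((len(names), len(live)))
    for j, c in enumerate(live):
        for s, k in c.counts().items():
            A[names.index(s), j] = k
    logQ = np.log(np.array([c.Q for c in live]))

    # ideal initialisation: x_monomer = x0  =>  lambda_i = log x0_i - log Q_i
    lam = np.zeros(len(names))
    for i, n in enumerate(names):
        j = next(
            j for j, c in enumerate(live) if c.size == 1 and c.strands[0] == n
        )
        lam[i] = math.log(x0[i]) - logQ[j]

    def conc(lam_vec: np.ndarray) -> np.ndarray:
        logx = logQ + A.T @ lam_vec
        return np.exp(np.minimum(logx, 500.0))

    def dual(lam_vec: np.ndarray) -> float:
        # g(lambda) = lambda . x0 - sum_j x_j ; maximised at the solution
        logx = logQ + A.T @ lam_vec
        if np.any(logx > 500.0):
            return -np.inf
        return float(lam_vec @ x0 - np.exp(logx).sum())

    history: list[float] = []
    g = dual(lam)
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        x = conc(lam)
        grad = x0 - A @ x
        residual = float(np.max(np.abs(grad) / x0))
        history.append(-g)
        if residual <= rel_tol:
            break
        J = (A * x) @ A.T  # Hessian of -g: A diag(x) A^T, SPD
        try:
            step = np.linalg.solve(J + 1e-300 * np.eye(len(names)), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, grad, rcond=None)[0]
        # Backtracking line search on the concave dual. Near the optimum the
        # dual improvement falls below floating-point resolution while Newton
        # still contracts quadratically, so a step that shrinks the mass
        # balance residual is also accepted (the dual is then flat to within
        # rounding, preserving monotonicity of the logged objective).
        t = 1.0
        accepted = False
        for _ in range(60):
            cand = lam + t * step
            g_cand = dual(cand)
            if g_cand > g:
                lam, g = cand, g_cand
                accepted = True
                break
            if g_cand >= g - 1e-9 * max(1.0, abs(g)):
                r_cand = float(np.max(np.abs(x0 - A @ conc(cand)) / x0))
                if r_cand < residual:
                    lam, g = cand, max(g, g_cand)
                    accepted = True
                    break
            t *= 0.5
        if not accepted:
            break  # no progress possible: numerical floor reached
    x = conc(lam)
    grad = x0 - A @ x
    residual = float(np.max(np.abs(grad) / x0))
    history.append(-dual(lam))
    converged = residual <= rel_tol
    if not converged and residual > 1e-6:
        raise ConvergenceError(
            f"equilibrium solve stalled at relative residual {residual:.3e} "
            f"after {it} iterations",
            residual,
        )
    with np.errstate(divide="ignore"):
        kkt = float(
            np.max(np.abs(np.log(x) - logQ - A.T @ lam)) if len(x) else 0.0
        )
    xfull = np.zeros(len(complexes))
    for j, c in enumerate(complexes):
        if c in live:
            xfull[j] = x[live.index(c)]
    return EquilibriumState(
        complexes=list(complexes),
        concentrations_molar=xfull,
        strand_names=names,
        stoichiometry=A,
        potentials=lam,
        mass_balance_residual=residual,
        kkt_residual=kkt,
        iterations=it,
        converged=converged,
        objective_history=history,
    )


def solve_tube(
    tube: Tube,
    panel: OligoPanel | dict[str, NucleotideStrand],
    model: EnergyModel | None = None,
) -> EquilibriumState:
    """Enumerate complexes, compute every Q_j by DP and solve the tube."""
    if model is None:
        model = EnergyModel(temperature=tube.temperature)
    names = [n for n in tube.concentrations_nM]
    cxs = enumerate_complexes(names, tube.max_complex_size)
    cxs = [
        c.with_Q(complex_partition_function(c, panel, model)) for c in cxs
    ]
    return solve_equilibrium(tube, cxs)
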