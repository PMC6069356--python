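"""Deterministic mass-action kinetics of the thrombin-triggered CHA circuit.

The circuit is modelled at the domain level with thrombin represented as a
single strand fully complementary to the aptamer (the same abstraction the
sensor's own strand-displacement simulation uses; protein-aptamer binding
biophysics is out of scope). Species and elementary reactions:

    R1  Thrombin + Aptamer.S   -> Aptamer.Thrombin + S        (k_trigger)
    R2f S + H1                 -> S.H1                        (k_open)
    R2r S.H1                   -> S + H1                      (k_open_rev)
    R3  S.H1 + H2              -> Duplex(H1:H2) + S           (k_cat)
    R4  H1 + H2                -> Duplex(H1:H2)               (k_leak)

R3 regenerates the catalyst S, giving the multi-turnover amplification; R4 is
the slow target-independent leak that sets the background. Four moiety totals
are conserved structurally: thrombin, S, H1 and H2.

Concentrations are in nM, time in seconds, bimolecular rates in /nM/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RateConfig",
    "ReactionNetwork",
    "TimeCourse",
    "SPECIES",
    "ASSAY_INITIALS_NM",
    "build_network",
    "simulate",
    "amplification_ratio",
]

SPECIES = (
    "Thrombin",
    "AptamerS",
    "AptamerThrombin",
    "S",
    "H1",
    "H2",
    "S_H1",
    "DuplexH1H2",
)

#: Assay-condition initial concentrations (nM): 1 nM target, 50 nM probe
#: duplex, 300 nM of each hairpin.
ASSAY_INITIALS_NM = {
    "Thrombin": 1.0,
    "AptamerS": 50.0,
    "H1": 300.0,
    "H2": 300.0,
}


@dataclass(frozen=True)
class RateConfig:
    """Rate constants of the circuit (bimolecular /nM/s, unimolecular /s).

    Defaults put the triggered pathway in the fast, long-toehold
    strand-displacement regime (~1e6 /M/s) with a weak hairpin leak, the
    regime in which the assembled duplex at the assay endpoint exceeds the
    untriggered background by more than an order of magnitude. They are a
    configuration surface, not fitted constants.
    """

    k_trigger: float = 1e-3
    k_open: float = 1e-3
    k_open_rev: float = 1e-3
    k_cat: float = 1e-3
    k_leak: float = 1e-8

    def __post_init__(self) -> None:
        for name in ("k_trigger", "k_open", "k_open_rev", "k_cat", "k_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0")


@dataclass(frozen=True)
class ReactionNetwork:
    """Mass-action reaction list with its stoichiometry matrix."""

    rates: RateConfig
    species: tuple[str, ...] = SPECIES
    # (reactant indices, product indices, rate constant) per reaction
    reactions: tuple[tuple[tuple[int, ...], tuple[int, ...], float], ...] = ()
    stoichiometry: np.ndarray = field(default=None, repr=False)

    @property
    def conservation_vectors(self) -> np.ndarray:
        """Rows: thrombin, S, H1 and H2 moiety totals (left null space of N)."""
        idx = {s: i for i, s in enumerate(self.species)}
        vecs = np.zeros((4, len(self.species)))
        for v, members in enumerate(
            (
                ("Thrombin", "AptamerThrombin"),
                ("S", "AptamerS", "S_H1"),
                ("H1", "S_H1", "DuplexH1H2"),
                ("H2", "DuplexH1H2"),
            )
        ):
            for m in members:
                vecs[v, idx[m]] = 1.0
        return vecs


def build_network(rates: RateConfig) -> ReactionNetwork:
    """Assemble the five elementary reactions of the circuit."""
    idx = {s: i for i, s in enumerate(SPECIES)}
    rxns = (
        ((idx["Thrombin"], idx["AptamerS"]), (idx["AptamerThrombin"], idx["S"]), rates.k_trigger),
        ((idx["S"], idx["H1"]), (idx["S_H1"],), rates.k_open),
        ((idx["S_H1"],), (idx["S"], idx["H1"]), rates.k_open_rev),
        ((idx["S_H1"], idx["H2"]), (idx["DuplexH1H2"], idx["S"]), rates.k_cat),
        ((idx["H1"], idx["H2"]), (idx["DuplexH1H2"],), rates.k_leak),
    )
    stoich = np.zeros((len(SPECIES), len(rxns)))
    for r, (reac, prod, _k) in enumerate(rxns):
        for s in reac:
            stoich[s, r] -= 1
        for s in prod:
            stoich[s, r] += 1
    return ReactionNetwork(rates=rates, reactions=rxns, stoichiometry=stoich)


@dataclass
class TimeCourse:
    """Concentration trajectories (nM) on a time grid (s)."""

    time: np.ndarray
    concentrations: np.ndarray  # species x time, nM
    species: tuple[str, ...]

    def __getitem__(self, species_name: str) -> np.ndarray:
        return self.concentrations[self.species.index(species_name)]

    def terminal(self) -> dict[str, float]:
        return {
            s: float(self.concentrations[i, -1])
            for i, s in enumerate(self.species)
        }

    def to_dataframe(self):
        """Tidy (time, species, concentration_nM) table."""
        import pandas as pd

        frames = []
        for i, s in enumerate(self.species):
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": self.time,
                        "species": s,
                        "concentration_nM": self.concentrations[i],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _rhs(network: ReactionNetwork):
    rxns = network.reactions
    stoich = network.stoichiometry

    def fun(_t: float, y: np.ndarray) -> np.ndarray:
        v = np.empty(len(rxns))
        for r, (reac, _prod, k) in enumerate(rxns):
            rate = k
            for s in reac:
                rate *= y[s]
            v[r] = rate
        return stoich @ v

    return fun


def simulate(
    network: ReactionNetwork,
    initial_nM: dict[str, float],
    t_end: float,
    n_points: int = 400,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> TimeCourse:
    """Integrate the circuit deterministically (stiff-capable LSODA).

    ``initial_nM`` maps species names to initial concentrations; unnamed
    species start at zero.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    y0 = np.zeros(len(SPECIES))
    for name, conc in initial_nM.items():
        if name not in SPECIES:
            raise KeyError(f"unknown species {name!r}")
        if conc < 0:
            raise ValueError(f"negative initial concentration for {name!r}")
        y0[SPECIES.index(name)] = conc
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        _rhs(network),
        (0.0, t_end),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t = {sol.t[-1] if len(sol.t) else 0.0}: "
            f"{sol.message}"
        )
    return TimeCourse(sol.t, sol.y, SPECIES)


def amplification_ratio(
    rates: RateConfig,
    initials_nM: dict[str, float] | None = None,
    t_end: float = 7200.0,
) -> float:
    """Assembled-duplex ratio with vs without target at the assay endpoint.

    Runs the circuit twice — once as given, once with the target clamped to
    zero — and returns Duplex(t_end, with) / Duplex(t_end, without). With no
    leak pathway the background is exactly zero and the ratio is reported as
    ``inf`` rather than raising.
    """
    if initials_nM is None:
        initials_nM = dict(ASSAY_INITIALS_NM)
    network = build_network(rates)
    with_t = simulate(network, initials_nM, t_end)
    no_target = {k: v for k, v in initials_nM.items() if k != "Thrombin"}
    without_t = simulate(network, no_target, t_end)
    num = with_t["DuplexH1H2"][-1]
    den = without_t["DuplexH1H2"][-1]
    if den == 0.0:
        return float("inf") if num > 0 else 1.0
    return float(num / den)
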