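"""Complex enumeration, multi-strand partition functions, tube equilibria."""

import math

import numpy as np
import pytest

from chaforge.complexes import (
    ComplexSpecies,
    Tube,
    complex_partition_function,
    enumerate_complexes,
    solve_equilibrium,
    solve_tube,
)
from chaforge.ensemble import enumerate_pair_sets, pair_set_energy
from chaforge.strands import NucleotideStrand
from chaforge import partition_function


def oracle_complex_q(strands, model):
    """Brute force over connected structures of the ordered concatenation.

    Connectivity is decided by union-find over strands — fully independent
    of the DP's nick bookkeeping — and the association penalty and symmetry
    factor are applied the same way the DP route defines them.
    """
    seq = "".join(strands)
    nicks, pos = set(), 0
    for s in strands[:-1]:
        pos += len(s)
        nicks.add(pos - 1)
    strand_of = [si for si, s in enumerate(strands) for _ in s]
    total = 0.0
    for pairs in enumerate_pair_sets(seq, frozenset(nicks)):
        parent = list(range(len(strands)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in pairs:
            a, b = find(strand_of[i]), find(strand_of[j])
            if a != b:
                parent[a] = b
        if len(strands) > 1 and len({find(k) for k in range(len(strands))}) > 1:
            continue
        total += math.exp(-pair_set_energy(seq, pairs, frozenset(nicks), model) / model.kT)
    return total


def tiny_panel(**seqs):
    return {k: NucleotideStrand(k, v) for k, v in seqs.items()}


class TestEnumeration:
    def test_single_strand_dimerization(self):
        cxs = enumerate_complexes(["A"], 2)
        assert [c.strands for c in cxs] == [("A",), ("A", "A")]

    def test_three_strands_pairwise(self):
        assert len(enumerate_complexes(["A", "B", "C"], 2)) == 9

    def test_paper_tube_byproducts_present(self):
        cxs = enumerate_complexes(["S", "H1", "H2"], 4)
        orderings = {c.strands for c in cxs}
        assert ComplexSpecies(("S", "H1", "H2")).strands in orderings
        assert ComplexSpecies(("H1", "H2", "H1", "H2")).strands in orderings

    def test_guard(self):
        with pytest.raises(ValueError):
            enumerate_complexes(["A"], 0)

    def test_symmetry_orders(self):
        assert ComplexSpecies(("A", "A")).symmetry == 2
        assert ComplexSpecies(("A", "B")).symmetry == 1
        assert ComplexSpecies(("A", "B", "A", "B")).symmetry == 2


class TestComplexPartitionFunction:
    def test_monomer_consistent_with_single_strand_route(self, model):
        seq = "GGGAAACCC"
        c = ComplexSpecies(("x",))
        q = complex_partition_function(c, tiny_panel(x=seq), model)
        assert q == pytest.approx(partition_function(seq, model), rel=1e-12)

    def test_poly_a_dimer_cannot_connect(self, model):
        c = ComplexSpecies(("a", "a"))
        assert complex_partition_function(c, tiny_panel(a="AAAA"), model) == 0.0

    @pytest.mark.parametrize(
        "seqs",
        [("GGG", "CCC"), ("GCGC", "GCGC"), ("GGGAA", "TTCCC"), ("GC", "GC", "GC")],
    )
    def test_dp_matches_connected_enumeration(self, seqs, model):
        names = [f"s{i}" for i in range(len(seqs))]
        panel = tiny_panel(**dict(zip(names, seqs)))
        c = ComplexSpecies(tuple(names))
        q_dp = complex_partition_function(c, panel, model)
        q_oracle = (
            oracle_complex_q([panel[n].bases for n in c.strands], model)
            * math.exp(-(len(seqs) - 1) * model.association_energy / model.kT)
            / c.symmetry
        )
        if q_oracle == 0:
            assert q_dp == 0
        else:
            assert abs(q_dp - q_oracle) / q_oracle <= 1e-9

    def test_oracle_mode_guard(self, model):
        c = ComplexSpecies(("x", "y"))
        panel = tiny_panel(x="G" * 20, y="C" * 20)
        with pytest.raises(ValueError, match="guard"):
            complex_partition_function(c, panel, model, method="enumerate")


class TestEquilibriumSolver:
    def test_single_monomer_is_constraint_forced(self):
        tube = Tube({"A": 25.0}, max_complex_size=1)
        state = solve_equilibrium(tube, [ComplexSpecies(("A",), 7.0)])
        assert state.concentrations_molar[0] == pytest.approx(25e-9, rel=1e-12)

    @pytest.mark.parametrize("K", [1e3, 1e6, 1e9, 1e12, 1e15])
    @pytest.mark.parametrize("totals", [(100.0, 40.0), (50.0, 50.0), (300.0, 1.0), (10.0, 1000.0)])
    def test_dimer_closed_form(self, K, totals):
        """A + B <-> AB agrees with the quadratic mass-action solution."""
        qa, qb = 2.0, 3.0
        cxs = [
            ComplexSpecies(("A",), qa),
            ComplexSpecies(("B",), qb),
            ComplexSpecies(("A", "B"), K * qa * qb),
        ]
        a0, b0 = totals[0] * 1e-9, totals[1] * 1e-9
        state = solve_equilibrium(Tube(dict(A=totals[0], B=totals[1]), 2), cxs)
        roots = np.roots([K, -(K * (a0 + b0) + 1.0), K * a0 * b0])
        xab = min(r.real for r in roots if abs(r.imag) == 0 and r.real > 0)
        assert abs(state.concentrations_molar[2] - xab) / xab <= 1e-9
        assert state.mass_balance_residual <= 1e-8
        assert state.kkt_residual <= 1e-6

    def test_homodimer_symmetry_factor(self, model):
        """x_AA / x_A^2 equals Q_AA / Q_A^2 with the symmetry-halved Q_AA."""
        panel = tiny_panel(a="GGGGAAATCCCC")
        qa = complex_partition_function(ComplexSpecies(("a",)), panel, model)
        qaa = complex_partition_function(ComplexSpecies(("a", "a")), panel, model)
        cxs = [ComplexSpecies(("a",), qa), ComplexSpecies(("a", "a")), ]
        cxs[1] = cxs[1].with_Q(qaa)
        state = solve_equilibrium(Tube({"a": 500.0}, 2), cxs)
        xa, xaa = state.concentrations_molar
        assert xaa / xa**2 == pytest.approx(qaa / qa**2, rel=1e-6)

    def test_mass_conservation_on_random_tubes(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            totals = dict(A=float(rng.uniform(1, 500)), B=float(rng.uniform(1, 500)))
            cxs = [
                ComplexSpecies(("A",), float(rng.uniform(0.5, 50))),
                ComplexSpecies(("B",), float(rng.uniform(0.5, 50))),
                ComplexSpecies(("A", "B"), float(10 ** rng.uniform(2, 14))),
                ComplexSpecies(("A", "A"), float(10 ** rng.uniform(2, 10))),
                ComplexSpecies(("A", "A", "B"), float(10 ** rng.uniform(2, 18))),
            ]
            state = solve_equilibrium(Tube(totals, 3), cxs)
            assert state.mass_balance_residual <= 1e-8
            assert state.kkt_residual <= 1e-6
            obj = state.objective_history
            assert all(
                obj[i + 1] <= obj[i] + 1e-9 * max(1.0, abs(obj[i]))
                for i in range(len(obj) - 1)
            )

    def test_missing_monomer_rejected(self):
        with pytest.raises(ValueError, match="monomer"):
            solve_equilibrium(Tube({"A": 10.0}, 1), [ComplexSpecies(("A",), 0.0)])


class TestPaperTube:
    def test_untriggered_mix_is_dominated_by_h1_h2(self, panel, model):
        """In the S + H1 + H2 tube the assembled H1:H2 duplex far exceeds
        every by-product (trimer, tetramer) complex at equilibrium."""
        tube = Tube({"S": 50.0, "H1": 300.0, "H2": 300.0}, max_complex_size=4)
        state = solve_tube(tube, panel, model)
        assert state.mass_balance_residual <= 1e-8
        assert state.kkt_residual <= 1e-6
        conc = state.as_dict_nM()
        h1h2 = conc["H1·H2"]
        byproducts = {
            name: x
            for name, x in conc.items()
            if "·" in name and name != "H1·H2"
        }
        assert h1h2 > max(byproducts.values())
        # the trigger strand stays free, ready for the aptamer probe
        assert conc["S"] == pytest.approx(50.0, rel=0.05)
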