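import numpy as np
import pytest
import sympy as sp

from mirrorbreak import build_network, load_fixture
from mirrorbreak.frank_analyses import (
    CATEGORIES,
    ClassificationFailure,
    classify_six_categories,
    frank_inequality_current,
    frank_inequality_jacobian,
    reduce_multi_pair,
    run_algorithm,
    run_frank_sna,
    run_multi_pair,
    run_six_categories,
    six_category_constraints,
)
from mirrorbreak.sna_engine import current_matrix, extend_stoichiometric, extreme_currents
from mirrorbreak.symbolic_kinetics import (
    build_reaction_order_matrix,
    build_stoichiometric_matrix,
    j_symbols,
    k_symbols,
    x_symbols,
)

k = k_symbols(9)
x = x_symbols(2)
j = j_symbols(12)


class TestClassifySixCategories:
    def test_kn_labels(self, kn):
        labels = classify_six_categories(kn)
        by_cat = {l.category: l.reactions for l in labels}
        assert by_cat == {
            CATEGORIES[0]: (0, 1),
            CATEGORIES[1]: (2, 3),
            CATEGORIES[2]: (4, 5),
            CATEGORIES[3]: (6, 7),
            CATEGORIES[5]: (8,),
        }
        assert CATEGORIES[4] not in by_cat  # no LES reaction in this model

    def test_frank_inhibition_template(self):
        # the L + D -> P reaction of the Frank scheme is inhibition
        net = build_network(
            "frank-irr", ["L", "D", "A", "B", "P"],
            ["A + B -> L", "A + B -> D", "A + L -> 2 L", "A + D -> 2 D",
             "L + D -> P"],
        )
        labels = classify_six_categories(net)
        by_rxn = {i: l.category for l in labels for i in l.reactions}
        assert by_rxn[4] == CATEGORIES[5]

    def test_frank_cstr_reverse_inhibition_outside_templates(self):
        # P -> L + D (reverse inhibition) matches no template: the analysis
        # reports a structured failure on that reaction
        net = load_fixture("Frank-Rev-P-AB-CSTR")
        result = classify_six_categories(net)
        assert isinstance(result, ClassificationFailure)
        assert result.reaction == 11  # P -> L + D

    def test_les_reactions_are_r5(self):
        net = load_fixture("Blanco-et-al-LES-2013")
        labels = classify_six_categories(net)
        by_rxn = {i: l.category for l in labels for i in l.reactions}
        assert by_rxn[8] == CATEGORIES[4]

    def test_unclassifiable_reaction_fails_structurally(self):
        net = build_network("bad", ["L", "D"],
                            [" -> L", " -> D", "2 L -> D", "2 D -> L"])
        result = classify_six_categories(net)
        assert isinstance(result, ClassificationFailure)
        assert result.reaction == 2

    def test_relabelling_invariance(self, kn):
        swapped = build_network(
            "KN-swapped", ["D", "L"],
            [" -> D", " -> L", "D -> ", "L -> ", "D -> 2 D", "L -> 2 L",
             "2 D -> D", "2 L -> L", "D + L -> "],
        )
        a = {l.category for l in classify_six_categories(kn)}
        b = {l.category for l in classify_six_categories(swapped)}
        assert a == b


class TestSixCategoryConstraints:
    def test_kn_balance(self, kn):
        balance, ineqs, _ = six_category_constraints(kn)
        assert sp.expand(
            balance.expr - (-k[0] + k[2] - k[4] + k[6] + k[8])
        ) == 0
        assert balance.rel == "eq"

    def test_kn_frank_inequalities(self, kn):
        _, ineqs, _ = six_category_constraints(kn)
        assert sp.expand(ineqs[0].expr - (-k[2] + k[4] - 2 * k[6])) == 0
        # J11 + J12 < 0 stored as its negation > 0
        assert sp.expand(ineqs[1].expr - (k[2] - k[4] + 2 * k[6] + 2 * k[8])) == 0

    def test_kn_interval_table(self, kn, rng):
        report = run_six_categories(kn, {"num-samples": 2}, rng)
        sol = report.interval_solution
        k2, k4, k6, k8 = k[2], k[4], k[6], k[8]
        assert sol.order == [k2, k4, k6, k8]
        assert sol.lower_expr(k2) == 0 and sol.upper_expr(k2) is sp.oo
        assert sp.expand(sol.lower_expr(k4) - k2) == 0
        assert sol.upper_expr(k4) is sp.oo
        assert sol.lower_expr(k6) == 0
        assert sp.expand(sol.upper_expr(k6) - (k4 / 2 - k2 / 2)) == 0
        lows = {sp.expand(e) for e, _ in sol.lowers[k8]}
        assert lows == {
            sp.expand(-k2 + k4 - k6), sp.expand(-k2 / 2 + k4 / 2 - k6)
        }
        assert sp.expand(sol.derived[k[0]] - (k2 - k4 + k6 + k8)) == 0

    def test_no_autocatalysis_infeasible(self):
        """Dropping the autocatalytic pair leaves the Frank inequality
        unsatisfiable: no SMSB verdict (oracle: direct elimination)."""
        net = build_network(
            "KN-no-autocat", ["L", "D"],
            [" -> L", " -> D", "L -> ", "D -> ", "2 L -> L", "2 D -> D",
             "L + D -> "],
        )
        report = run_six_categories(net, {"num-samples": 1})
        assert report.feasible is False
        # independent check by substitution: with the autocatalytic rate
        # k4 = 0 the KN Frank inequality -k2 + k4 - 2 k6 > 0 cannot hold
        # for positive k2, k6
        assert sp.expand(-k[2] - 2 * k[6]).subs({k[2]: 1, k[6]: 1}) < 0

    def test_kn_samples_are_frank(self, kn, rng):
        report = run_six_categories(kn, {"num-samples": 4}, rng)
        assert report.possible
        for s in report.samples:
            assert s.flags["unstable"] and s.flags["frank"]


class TestFrankInequalityJacobian:
    def test_kn_steady_state_equation(self, kn):
        rep = frank_inequality_jacobian(kn)
        expected = k[0] - k[2] * x[0] + k[4] * x[0] - k[6] * x[0] ** 2 \
            - k[8] * x[0] ** 2
        assert sp.expand(rep.steady_state_equations[0] - expected) == 0

    def test_kn_frank_inequality(self, kn):
        rep = frank_inequality_jacobian(kn)
        assert sp.expand(rep.frank_inequality.expr - (-k[2] + k[4] - 2 * k[6] * x[0])) == 0

    def test_kn_determinant_condition(self, kn):
        rep = frank_inequality_jacobian(kn)
        d = -k[8] ** 2 * x[0] ** 2 + (
            -k[2] + k[4] - 2 * k[6] * x[0] - k[8] * x[0]
        ) ** 2
        assert sp.expand(rep.determinant_nonzero - d) == 0

    def test_not_sampleable(self, kn):
        rep = run_algorithm(4, kn)
        assert rep.sampleable is False


class TestFrankInequalityCurrent:
    def test_kn_extended(self, kn):
        S = build_stoichiometric_matrix(kn)
        K = build_reaction_order_matrix(kn)
        E = extreme_currents(extend_stoichiometric(S, kn.dual_pairs))
        V = current_matrix(S, E, K)
        frank = frank_inequality_current(V)
        assert sp.expand(frank.expr - (V[0, 0] - V[0, 1])) == 0
        # one positive (j5-like) and three negative current contributions
        poly = sp.Poly(frank.expr, *sorted(frank.expr.free_symbols, key=str))
        signs = sorted(poly.coeffs())
        assert signs == [-2, -1, -1, 1]

    def test_symmetric_matrix_infeasible(self):
        V = sp.Matrix([[-j[0], -j[0]], [-j[0], -j[0]]])
        frank = frank_inequality_current(V)
        assert frank.expr == 0  # 0 > 0: infeasible


class TestReduceMultiPair:
    def test_replicator_blocks(self, replicator):
        S = build_stoichiometric_matrix(replicator)
        K = build_reaction_order_matrix(replicator)
        E = extreme_currents(extend_stoichiometric(S, replicator.dual_pairs))
        V = current_matrix(S, E, K)
        red = reduce_multi_pair(V, replicator.enantiomeric_pairs)
        assert red.B == sp.zeros(2, 2)
        expected = sp.Matrix([[-j[0], j[1]], [j[1], -j[0]]])
        assert sp.expand(red.reduced - expected) == sp.zeros(2, 2)

    def test_one_pair_consistent_with_algorithm5(self, kn):
        S = build_stoichiometric_matrix(kn)
        K = build_reaction_order_matrix(kn)
        E = extreme_currents(extend_stoichiometric(S, kn.dual_pairs))
        V = current_matrix(S, E, K)
        red = reduce_multi_pair(V, kn.enantiomeric_pairs)
        assert red.reduced.shape == (1, 1)
        assert sp.expand(red.reduced[0, 0] - frank_inequality_current(V).expr) == 0

    def test_dimension_arithmetic_two_pairs_no_achiral(self):
        jj = j_symbols(2)
        a, b = jj
        V = sp.Matrix([
            [-a, 0, b, 0],
            [0, -a, 0, b],
            [b, 0, -a, 0],
            [0, b, 0, -a],
        ])
        red = reduce_multi_pair(V, [(0, 1), (2, 3)])
        assert red.reduced.shape == (2, 2)

    def test_symmetry_violation_detected(self):
        a = j_symbols(1)[0]
        V = sp.Matrix([[-a, 0], [0, -2 * a]])
        with pytest.raises(ValueError, match="symmetry"):
            reduce_multi_pair(V, [(0, 1)])

    def test_block_symmetry_all_fixtures(self):
        from mirrorbreak import list_fixtures

        for name in list_fixtures():
            net = load_fixture(name)
            S = build_stoichiometric_matrix(net)
            K = build_reaction_order_matrix(net)
            E = extreme_currents(extend_stoichiometric(S, net.dual_pairs))
            if E.shape[1] == 0:
                continue
            V = current_matrix(S, E, K)
            reduce_multi_pair(V, net.enantiomeric_pairs)  # must not raise


class TestRunAlgorithms:
    def test_algorithm5_kn_intervals(self, kn, rng):
        report = run_frank_sna(kn, {"num-samples": 2}, rng)
        assert report.feasible
        sol = report.interval_solution
        js = j_symbols(6)
        # five currents free on (0, oo); the inhibition-bearing current is
        # bounded below by max(0, sum of the opposing currents)
        bounded = [v for v in js if len(sol.lowers[v]) > 1]
        assert len(bounded) == 1
        lows = {sp.expand(e) for e, _ in sol.lowers[bounded[0]]}
        assert sp.Integer(0) in lows
        (combo,) = lows - {sp.Integer(0)}
        assert sorted(sp.Poly(combo, *sorted(combo.free_symbols, key=str)).coeffs()) == [1, 1, 2]

    def test_algorithm5_samples_verified(self, kn, rng):
        report = run_frank_sna(kn, {"num-samples": 3}, rng)
        for s in report.samples:
            assert s.flags["unstable"] and s.flags["frank"]
        assert report.frank_proportion == 1.0

    def test_algorithm6_replicator_restrictions(self, replicator, rng):
        report = run_multi_pair(
            replicator,
            {"instability-heuristic": "trace-determinant", "num-samples": 2},
            rng,
        )
        j0, j1 = j_symbols(2)
        exprs = {sp.expand(c.expr) for c in report.restrictions}
        assert exprs == {j0, j1, sp.expand(-j0**2 + j1**2)}
        assert report.samples
        for s in report.samples:
            assert s.flags["frank"]

    def test_algorithm6_char_degree_reduction(self, replicator):
        from mirrorbreak.sna_engine import characteristic_polynomial
        from mirrorbreak.symbolic_kinetics import LAMBDA

        report = run_multi_pair(replicator, {"num-samples": 0})
        assert sp.degree(characteristic_polynomial(report.V), LAMBDA) == 5
        assert sp.degree(
            characteristic_polynomial(report.reduction.reduced), LAMBDA
        ) == 2

    def test_dispatcher(self, kn):
        with pytest.raises(ValueError):
            run_algorithm(7, kn)


class TestLesExperiment:
    EQUAL = [(0, 2), (1, 3), (4, 6), (5, 7), (4, 8), (4, 10), (5, 9), (5, 11)]
    DISTINCT = [(0, 2), (1, 3), (4, 6), (5, 7), (8, 10), (9, 11)]

    def test_two_distinct_networks(self):
        eq = load_fixture("Blanco-et-al-LES-2013", dual_pairs=self.EQUAL)
        ne = load_fixture("Blanco-et-al-LES-2013", dual_pairs=self.DISTINCT)
        assert eq.dual_classes != ne.dual_classes
        assert (4, 6, 8, 10) in eq.dual_classes

    def test_equal_rates_forbid_symmetry_breaking(self, rng):
        eq = load_fixture("Blanco-et-al-LES-2013", dual_pairs=self.EQUAL)
        report = run_frank_sna(eq, {"num-samples": 2}, rng)
        assert report.feasible is False

    def test_distinct_rates_allow_symmetry_breaking(self, rng):
        ne = load_fixture("Blanco-et-al-LES-2013", dual_pairs=self.DISTINCT)
        report = run_frank_sna(ne, {"num-samples": 2}, rng)
        assert report.feasible is True
        assert report.samples
        assert any(s.flags["frank"] for s in report.samples)
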