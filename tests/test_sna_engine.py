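import numpy as np
import pytest
import sympy as sp

from conftest import (
    brute_force_extreme_rays,
    columns_as_set,
    match_column_permutation,
    parse_digit_grid,
)
from mirrorbreak import build_network, load_fixture
from mirrorbreak.sna_engine import (
    current_matrix,
    dual_pair_equalities,
    extend_stoichiometric,
    extreme_currents,
    instability_conditions,
    run_sna,
)
from mirrorbreak.symbolic_kinetics import (
    build_reaction_order_matrix,
    build_stoichiometric_matrix,
    j_symbols,
)

# the published 9 x 12 extreme-currents matrix of the Kondepudi-Nelson
# network (plain stoichiometric matrix)
E_KN_PLAIN = parse_digit_grid([
    "100010001010",
    "010000101100",
    "101000000000",
    "010100000000",
    "001001000101",
    "000100010011",
    "000011000000",
    "000000110000",
    "000000001111",
])

# ... and the 9 x 6 matrix from the extended stoichiometric matrix
E_KN_EXT = parse_digit_grid([
    "101010",
    "101010",
    "110000",
    "110000",
    "010101",
    "010101",
    "001100",
    "001100",
    "000011",
])

jp = j_symbols(12)


class TestExtendStoichiometric:
    def test_kn_extended_shape_and_rows(self, kn):
        S = build_stoichiometric_matrix(kn)
        Sx = extend_stoichiometric(S, kn.dual_pairs)
        assert Sx.shape == (6, 9)
        assert Sx[2].tolist() == [1, -1, 0, 0, 0, 0, 0, 0, 0]
        assert Sx[5].tolist() == [0, 0, 0, 0, 0, 0, 1, -1, 0]

    def test_no_dual_pairs_unchanged(self, kn):
        S = build_stoichiometric_matrix(kn)
        assert (extend_stoichiometric(S, []) == S).all()

    def test_thirteen_rows_for_eight_pairs(self, replicator):
        S = build_stoichiometric_matrix(replicator)
        pairs = [(0, 2), (1, 3), (4, 6), (5, 7), (8, 9), (8, 10), (8, 11), (8, 13)]
        assert extend_stoichiometric(S, pairs).shape == (5 + 8, 14)


class TestExtremeCurrents:
    def test_kn_plain_matches_published(self, kn):
        E = extreme_currents(build_stoichiometric_matrix(kn))
        assert E.shape[1] == 12
        assert columns_as_set(E) == columns_as_set(E_KN_PLAIN)

    def test_kn_extended_matches_published(self, kn):
        S = build_stoichiometric_matrix(kn)
        E = extreme_currents(extend_stoichiometric(S, kn.dual_pairs))
        assert E.shape[1] == 6
        assert columns_as_set(E) == columns_as_set(E_KN_EXT)
        # reaction-0 row participates in published rays {0, 2, 4}
        assert [c for c in range(6) if E_KN_EXT[0, c]] == [0, 2, 4]

    def test_trivial_two_reaction_cycle(self):
        S = np.array([[-1, 1]])
        E = extreme_currents(S)
        assert E.tolist() == [[1], [1]]

    def test_empty_cone(self):
        S = np.array([[1, 1]])  # only production: no steady flux
        E = extreme_currents(S)
        assert E.shape == (2, 0)

    def test_kernel_property_and_normalisation(self):
        for name in ("Kondepudi-Nelson", "Frank-Rev-P", "Blanco-et-al-LES-2013",
                     "Replicator-Hochberg-Ribo", "Blackmond-Rev-2020",
                     "Calvin-2-CSTR-LES", "Frank-Rev-P-AB-CSTR"):
            net = load_fixture(name)
            S = build_stoichiometric_matrix(net)
            for Su in (S, extend_stoichiometric(S, net.dual_pairs)):
                E = extreme_currents(Su)
                assert (Su @ E == 0).all(), name
                for c in range(E.shape[1]):
                    col = E[:, c]
                    assert (col >= 0).all() and col.any()
                    assert np.gcd.reduce(col[col > 0]) == 1
                sups = [frozenset(np.flatnonzero(E[:, c])) for c in range(E.shape[1])]
                assert not any(
                    a < b for a in sups for b in sups if a is not b
                ), name

    @pytest.mark.parametrize(
        "name", ["Kondepudi-Nelson", "Frank-Rev-P", "Blanco-et-al-LES-2013",
                 "APED-dimerization", "Blackmond-Scheme8",
                 "Replicator-Hochberg-Ribo"],
    )
    def test_agrees_with_brute_force_oracle(self, name):
        net = load_fixture(name)
        S = build_stoichiometric_matrix(net)
        for Su in (S, extend_stoichiometric(S, net.dual_pairs)):
            E = extreme_currents(Su)
            assert columns_as_set(E) == brute_force_extreme_rays(Su), name

    def test_extended_rays_live_in_plain_cone(self):
        for name in ("Kondepudi-Nelson", "Frank-Rev-P", "Replicator-Hochberg-Ribo"):
            net = load_fixture(name)
            S = build_stoichiometric_matrix(net)
            E = extreme_currents(extend_stoichiometric(S, net.dual_pairs))
            assert (S @ E == 0).all()
            for a, b in net.dual_pairs:
                assert (E[a] == E[b]).all()


class TestCurrentMatrix:
    def test_kn_extended_entries(self, kn):
        S = build_stoichiometric_matrix(kn)
        K = build_reaction_order_matrix(kn)
        E = extreme_currents(extend_stoichiometric(S, kn.dual_pairs))
        V = current_matrix(S, E, K)
        perm = match_column_permutation(E_KN_EXT, E)
        sub = {jp[c]: jp[perm[c]] for c in range(6)}
        published = sp.Matrix([
            [-jp[0] - 2 * jp[2] - jp[3] - jp[4], -jp[4] - jp[5]],
            [-jp[4] - jp[5], -jp[0] - 2 * jp[2] - jp[3] - jp[4]],
        ]).subs(sub, simultaneous=True)
        assert sp.expand(V - published) == sp.zeros(2, 2)

    def test_kn_plain_entries(self, kn):
        S = build_stoichiometric_matrix(kn)
        K = build_reaction_order_matrix(kn)
        E = extreme_currents(S)
        V = current_matrix(S, E, K)
        perm = match_column_permutation(E_KN_PLAIN, E)
        sub = {jp[c]: jp[perm[c]] for c in range(12)}
        published = sp.Matrix([
            [-jp[0] - jp[10] - 2 * jp[4] - jp[5] - jp[8],
             -jp[10] - jp[11] - jp[8] - jp[9]],
            [-jp[10] - jp[11] - jp[8] - jp[9],
             -jp[1] - 2 * jp[6] - jp[7] - jp[8] - jp[9]],
        ]).subs(sub, simultaneous=True)
        assert sp.expand(V - published) == sp.zeros(2, 2)

    def test_zero_E_gives_zero_matrix(self, kn):
        S = build_stoichiometric_matrix(kn)
        K = build_reaction_order_matrix(kn)
        V = current_matrix(S, np.zeros((9, 2), dtype=int), K)
        assert V == sp.zeros(2, 2)

    def test_dimension_mismatch(self, kn):
        S = build_stoichiometric_matrix(kn)
        K = build_reaction_order_matrix(kn)
        with pytest.raises(ValueError, match="dimension"):
            current_matrix(S, np.zeros((5, 2), dtype=int), K)


class TestDualPairEqualities:
    def test_kn_plain_has_four(self, kn):
        E = extreme_currents(build_stoichiometric_matrix(kn))
        eqs = dual_pair_equalities(E, kn.dual_pairs)
        assert len(eqs) == 4
        perm = match_column_permutation(E_KN_PLAIN, E)
        sub = {jp[c]: jp[perm[c]] for c in range(12)}
        published = sp.expand(
            (jp[0] + jp[10] + jp[4] + jp[8])
            - (jp[1] + jp[6] + jp[8] + jp[9])
        ).subs(sub, simultaneous=True)
        assert any(
            sp.expand(e.expr - published) == 0 or sp.expand(e.expr + published) == 0
            for e in eqs
        )

    def test_kn_extended_all_trivial(self, kn):
        S = build_stoichiometric_matrix(kn)
        E = extreme_currents(extend_stoichiometric(S, kn.dual_pairs))
        assert dual_pair_equalities(E, kn.dual_pairs) == []

    def test_no_pairs(self, kn):
        E = extreme_currents(build_stoichiometric_matrix(kn))
        assert dual_pair_equalities(E, []) == []


class TestInstabilityConditions:
    def test_kn_mineurs_is_minus_det(self, kn):
        S = build_stoichiometric_matrix(kn)
        K = build_reaction_order_matrix(kn)
        V = current_matrix(S, extreme_currents(S), K)
        cond = instability_conditions(V, "mineurs")
        assert len(cond.branches) == 1
        assert sp.expand(cond.branches[0][0].expr - sp.expand(-V.det())) == 0

    def test_published_quadratic(self, kn):
        """The published degree-2 condition polynomial equals -det(V)."""
        S = build_stoichiometric_matrix(kn)
        K = build_reaction_order_matrix(kn)
        E = extreme_currents(S)
        V = current_matrix(S, E, K)
        perm = match_column_permutation(E_KN_PLAIN, E)
        sub = {jp[c]: jp[perm[c]] for c in range(12)}
        published = (
            -jp[0]*jp[1] - 2*jp[0]*jp[6] - jp[0]*jp[7] - jp[0]*jp[8]
            - jp[0]*jp[9] - jp[1]*jp[10] - 2*jp[1]*jp[4] - jp[1]*jp[5]
            - jp[1]*jp[8] + jp[10]**2 + 2*jp[10]*jp[11] - 2*jp[10]*jp[6]
            - jp[10]*jp[7] + jp[10]*jp[8] + jp[10]*jp[9] + jp[11]**2
            + 2*jp[11]*jp[8] + 2*jp[11]*jp[9] - 4*jp[4]*jp[6] - 2*jp[4]*jp[7]
            - 2*jp[4]*jp[8] - 2*jp[4]*jp[9] - 2*jp[5]*jp[6] - jp[5]*jp[7]
            - jp[5]*jp[8] - jp[5]*jp[9] - 2*jp[6]*jp[8] - jp[7]*jp[8]
            + jp[8]*jp[9] + jp[9]**2
        )
        published = sp.expand(published.subs(sub, simultaneous=True))
        # published polynomial is required > 0, our canonical -det(V) > 0
        assert sp.expand(published + sp.expand(V.det())) == 0

    def test_diagonal_stable_matrix_has_no_branches(self):
        j0 = sp.Symbol("j0", positive=True)
        V = sp.Matrix([[-j0, 0], [0, -j0]])
        cond = instability_conditions(V, "mineurs", n_currents=1)
        assert cond.stable

    def test_trace_determinant_refused_on_3x3(self):
        with pytest.raises(ValueError):
            instability_conditions(sp.eye(3), "trace-determinant")

    def test_char_poly_branch_has_lambda(self, kn):
        from mirrorbreak.symbolic_kinetics import LAMBDA

        S = build_stoichiometric_matrix(kn)
        K = build_reaction_order_matrix(kn)
        V = current_matrix(S, extreme_currents(S), K)
        cond = instability_conditions(V, "characteristic-polynomial")
        assert cond.extra_symbols == [LAMBDA]
        assert LAMBDA in cond.branches[0][0].expr.free_symbols


class TestRunSna:
    def test_kn_extended_pipeline(self, kn, rng):
        report = run_sna(kn, {"dual-pairs-in-ec": True, "num-samples": 3}, rng)
        assert report.E.shape == (9, 6)
        assert report.V.shape == (2, 2)
        assert report.samples
        assert report.false_positive_rate == 0.0
        for s in report.samples:
            assert s.flags["unstable"]

    def test_kn_plain_pipeline(self, kn, rng):
        report = run_sna(kn, {"dual-pairs-in-ec": False, "num-samples": 2}, rng)
        assert report.E.shape == (9, 12)
        assert len(report.equalities) == 4
        assert report.samples

    def test_stable_toy_network(self, rng):
        # A <-> B with in/outflow of A: all char-poly coefficients positive
        net = build_network(
            "stable-toy", ["L", "D", "A", "B"],
            [" -> L", " -> D", "L -> ", "D -> ", " -> A", "A <-> B", "A -> "],
        )
        report = run_sna(net, {"instability-heuristic": "mineurs",
                               "num-samples": 2}, rng)
        assert report.conditions.stable
        assert not report.samples
        assert "stable" in report.verdict


def test_individual_minors_without_sum(kn):
    """sum-mineurs=False screens each principal minor separately."""
    S = build_stoichiometric_matrix(kn)
    K = build_reaction_order_matrix(kn)
    V = current_matrix(S, extreme_currents(S), K)
    summed = instability_conditions(V, "mineurs", sum_mineurs=True)
    split = instability_conditions(V, "mineurs", sum_mineurs=False)
    # for the 2x2 case there is a single order-2 principal minor, so both
    # settings coincide; order-1 minors are all-negative terms either way
    assert len(split.branches) == len(summed.branches) == 1
    assert sp.expand(
        split.branches[0][0].expr - summed.branches[0][0].expr
    ) == 0
    V3 = sp.diag(V, sp.Matrix([[-j_symbols(1)[0]]]))
    split3 = instability_conditions(V3, "mineurs", sum_mineurs=False)
    summed3 = instability_conditions(V3, "mineurs", sum_mineurs=True)
    assert len(split3.branches) >= len(summed3.branches)
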