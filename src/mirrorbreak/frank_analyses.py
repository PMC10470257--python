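"""Algorithms 3-6: six-category classification, the Frank inequality on the
Jacobian and on the current matrix, and the multi-pair block reduction.

The *Frank inequality* ``J11 - J12 > 0`` (equivalently ``V11 - V12 > 0`` on
the current matrix) is the necessary condition for a symmetry-breaking
unstable mode at a mirror-symmetric steady state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .network_model import ReactionNetwork
from .sna_engine import (
    Constraint,
    InstabilityConditionSet,
    current_matrix,
    dual_pair_equalities,
    extend_stoichiometric,
    extreme_currents,
    instability_conditions,
)
from .symbolic_kinetics import (
    build_reaction_order_matrix,
    build_stoichiometric_matrix,
    jacobian,
    j_symbols,
    k_symbols,
    merge_dual_rates,
    ode_system,
    velocity_vector,
    x_symbols,
)

__all__ = [
    "SixCategoryLabel", "ClassificationFailure", "classify_six_categories",
    "six_category_constraints", "frank_inequality_jacobian",
    "frank_inequality_current", "reduce_multi_pair", "ReducedCurrentMatrix",
    "run_six_categories", "run_frank_nonlinear", "run_frank_sna",
    "run_multi_pair", "run_algorithm",
]

CATEGORIES = (
    "R1 synthesis",
    "R2 fo-decomposition",
    "R3 autocatalytic",
    "R4 so-decomposition",
    "R5 no-enantioselective",
    "R6 inhibition",
)


@dataclass(frozen=True)
class SixCategoryLabel:
    category: str
    reactions: tuple[int, ...]  # the dual pair (or single self-mirror reaction)


@dataclass(frozen=True)
class ClassificationFailure:
    reaction: int
    message: str


def _chiral_pattern(rxn, L: int, D: int) -> tuple[int, int, int, int]:
    return (
        rxn.reactant_count(L), rxn.reactant_count(D),
        rxn.product_count(L), rxn.product_count(D),
    )


def _category_of(pattern: tuple[int, int, int, int]) -> str | None:
    a, b, c, d = pattern
    swapped = (b, a, d, c)
    for pat in (pattern, swapped):
        aa, bb, cc, dd = pat
        if (aa, bb) == (0, 0) and (cc, dd) == (1, 0):
            return CATEGORIES[0]
        if pat == (1, 0, 0, 0):
            return CATEGORIES[1]
        if pat == (1, 0, 2, 0):
            return CATEGORIES[2]
        if pat == (2, 0, 1, 0):
            return CATEGORIES[3]
        if pat == (1, 0, 1, 1):
            return CATEGORIES[4]
    # inhibition: one of each enantiomer consumed; product counts are free
    # (the mirror partner carries the swapped pattern)
    if a == 1 and b == 1:
        return CATEGORIES[5]
    return None


def classify_six_categories(
    network: ReactionNetwork,
) -> list[SixCategoryLabel] | ClassificationFailure:
    """Match every chiral reaction against the six reaction templates.

    Only the first enantiomeric pair (L, D) is chiral for this analysis;
    every other species is achiral context.  Reactions not involving L or D
    are context reactions and carry no label.  The first unclassifiable
    reaction aborts the analysis with a structured failure.
    """
    L, D = network.enantiomeric_pairs[0]
    groups: list[tuple[int, ...]] = list(network.dual_classes)
    grouped = {i for cls in groups for i in cls}
    groups += [(i,) for i in network.regular_reactions if i not in grouped]

    labels = []
    for group in sorted(groups):
        chiral = [
            i for i in group
            if _chiral_pattern(network.reactions[i], L, D) != (0, 0, 0, 0)
        ]
        if not chiral:
            continue  # achiral context reaction(s), e.g. CSTR flows
        cats = {
            _category_of(_chiral_pattern(network.reactions[i], L, D))
            for i in chiral
        }
        if len(cats) != 1 or None in cats:
            bad = next(
                (i for i in chiral
                 if _category_of(_chiral_pattern(network.reactions[i], L, D))
                 is None),
                chiral[0],
            )
            return ClassificationFailure(
                reaction=bad,
                message=f"reaction {bad} matches no category template",
            )
        labels.append(
            SixCategoryLabel(category=cats.pop(), reactions=tuple(chiral))
        )
    return labels


def six_category_constraints(
    network: ReactionNetwork,
    labels: list[SixCategoryLabel] | None = None,
) -> tuple[Constraint, list[Constraint], dict[str, sp.Expr]]:
    """The linear balance equality and the two Frank-type inequalities.

    Category sums (over class-representative rate constants): P synthesis,
    D fo-decomposition, A autocatalytic, DE so-decomposition, E
    no-enantioselective, C inhibition (weighted by its reactant
    coefficient).  The balance implemented is the worked-instance form
    ``D + DE + C - E - A - P = 0`` (the sign of C differs from the
    displayed general formula; see the report note).  The inequalities are
    the Frank pair ``J11 - J12 > 0`` and ``J11 + J12 < 0`` evaluated at the
    normalised symmetric steady state (all concentrations scaled to 1).
    """
    if labels is None:
        labels = classify_six_categories(network)
    if isinstance(labels, ClassificationFailure):
        raise ValueError(labels.message)
    ks = k_symbols(network.n_reactions)
    L, _ = network.enantiomeric_pairs[0]

    sums = {name: sp.Integer(0) for name in CATEGORIES}
    for label in labels:
        rep = ks[min(label.reactions)]
        if label.category == CATEGORIES[5]:
            weight = network.reactions[min(label.reactions)].reactant_count(L)
            sums[label.category] += weight * rep
        else:
            sums[label.category] += rep

    balance = sp.expand(
        sums[CATEGORIES[1]] + sums[CATEGORIES[3]] + sums[CATEGORIES[5]]
        - sums[CATEGORIES[4]] - sums[CATEGORIES[2]] - sums[CATEGORIES[0]]
    )

    J = _symmetric_unit_jacobian(network)
    frank = sp.expand(J[0, 0] - J[0, 1])
    antifrank = sp.expand(-(J[0, 0] + J[0, 1]))
    return (
        Constraint(balance, "eq"),
        [Constraint(frank, "gt"), Constraint(antifrank, "gt")],
        sums,
    )


def _symmetric_unit_jacobian(network: ReactionNetwork) -> sp.Matrix:
    """Dual-rate-merged Jacobian of the (L, D) block with all x set to 1."""
    S = build_stoichiometric_matrix(network)
    J = jacobian(ode_system(S, velocity_vector(network)), network.n_species)
    J = merge_dual_rates(network, J)
    xs = x_symbols(network.n_species)
    J = J.subs({x: 1 for x in xs})
    L, D = network.enantiomeric_pairs[0]
    return sp.Matrix([[J[L, L], J[L, D]], [J[D, L], J[D, D]]])


# ----------------------------------------------------------------------
# algorithm 3
# ----------------------------------------------------------------------

@dataclass
class SixCategoryReport:
    labels: list[SixCategoryLabel] | ClassificationFailure
    balance: Constraint | None = None
    inequalities: list[Constraint] = field(default_factory=list)
    interval_solution: object = None
    feasible: bool | None = None
    samples: list = field(default_factory=list)
    note: str = (
        "balance uses the worked-instance sign convention "
        "D + DE + C - E - A - P = 0 (C enters with +)"
    )

    @property
    def possible(self) -> bool:
        return not isinstance(self.labels, ClassificationFailure) and bool(
            self.feasible
        )


def run_six_categories(
    network: ReactionNetwork,
    options: dict | None = None,
    rng: np.random.Generator | None = None,
) -> SixCategoryReport:
    from . import sampler as _sampler

    opts = options or {}
    rng = rng or np.random.default_rng(0)
    labels = classify_six_categories(network)
    if isinstance(labels, ClassificationFailure):
        return SixCategoryReport(labels=labels, feasible=False)
    balance, inequalities, _ = six_category_constraints(network, labels)

    ks = k_symbols(network.n_reactions)
    reps = sorted({min(cls) for cls in network.dual_classes}
                  | set(network.regular_reactions))
    positivity = [Constraint(ks[i], "gt") for i in reps]
    # eliminate the synthesis representative through the balance, solve the
    # rest into nested intervals
    synth = [l for l in (labels or []) if l.category == CATEGORIES[0]]
    elim = min(synth[0].reactions) if synth else reps[0]
    order = [ks[i] for i in reps if i != elim]
    constraints = [balance] + positivity + inequalities
    try:
        solution = _sampler.linear_solve_intervals(constraints, order)
        feasible = True
    except _sampler.Infeasible:
        return SixCategoryReport(
            labels=labels, balance=balance, inequalities=inequalities,
            feasible=False,
        )

    n = int(opts.get("num-samples", 10))
    assignments = _sampler.sample_from_intervals(
        solution, n, rng, original_constraints=constraints
    )
    samples = []
    for a in assignments:
        rep_map = network.rate_representative()
        k_exact = {i: a[ks[rep_map[i]]] for i in range(network.n_reactions)}
        sample = _sampler.RateSample(
            model=network.name, algorithm="six-categories", seed=None,
            rate_constants={f"k{i}": float(k_exact[i]) for i in k_exact},
            initial_concentrations={s.name: 1.0 for s in network.species},
            currents={},
            exact_rates=k_exact,
        )
        kv = sample.rate_vector(network.n_reactions)
        xv = sample.concentration_vector(network.species_names)
        sample.flags["unstable"] = _sampler.is_unstable(network, kv, xv)
        sample.flags["frank"] = _sampler.is_frank(network, kv, xv)
        samples.append(sample)
    return SixCategoryReport(
        labels=labels, balance=balance, inequalities=inequalities,
        interval_solution=solution, feasible=feasible, samples=samples,
    )


# ----------------------------------------------------------------------
# algorithm 4
# ----------------------------------------------------------------------

@dataclass
class FrankNonlinearReport:
    steady_state_equations: list[sp.Expr]
    determinant_nonzero: sp.Expr
    frank_inequality: Constraint
    sampleable: bool = False  # nonlinear in (k, x): cannot easily sample
    note: str = "all equations are nonlinear; sampling is not attempted"


def frank_inequality_jacobian(network: ReactionNetwork) -> FrankNonlinearReport:
    """Algorithm 4: the Frank inequality over (k, x), report only.

    Everything is evaluated at the mirror-symmetric state (each enantiomer
    pair's concentrations identified) with dual rates merged: the steady
    state equations, the condition det(J) != 0, and the Frank inequality
    ``J11 - J12 > 0``.
    """
    S = build_stoichiometric_matrix(network)
    ode = ode_system(S, velocity_vector(network))
    J = jacobian(ode, network.n_species)
    xs = x_symbols(network.n_species)
    sym_subs = {xs[b]: xs[a] for a, b in network.enantiomeric_pairs}

    def sym(expr):
        return sp.expand(merge_dual_rates(network, expr).subs(sym_subs))

    L, D = network.enantiomeric_pairs[0]
    steady = [sym(f) for f in ode]
    det = sym(J.det())
    frank = sp.expand(sym(J[L, L]) - sym(J[L, D]))
    return FrankNonlinearReport(
        steady_state_equations=steady,
        determinant_nonzero=det,
        frank_inequality=Constraint(frank, "gt"),
    )


run_frank_nonlinear = frank_inequality_jacobian


# ----------------------------------------------------------------------
# algorithm 5
# ----------------------------------------------------------------------

def frank_inequality_current(V: sp.Matrix) -> Constraint:
    """``V11 - V12 > 0`` with species 0, 1 the enantiomeric pair."""
    return Constraint(sp.expand(V[0, 0] - V[0, 1]), "gt")


@dataclass
class FrankSnaReport:
    E: np.ndarray
    V: sp.Matrix
    frank_inequality: Constraint
    equalities: list[Constraint]
    interval_solution: object
    feasible: bool
    samples: list = field(default_factory=list)
    frank_proportion: float | None = None
    false_positive_rate: float | None = None
    verdict: str = ""


def run_frank_sna(
    network: ReactionNetwork,
    options: dict | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> FrankSnaReport:
    """Algorithm 5: Frank inequality on the current matrix, then sampling."""
    from . import sampler as _sampler
    from .network_model import DEFAULT_OPTIONS

    opts = dict(DEFAULT_OPTIONS)
    opts.update(options or {})
    rng = rng or np.random.default_rng(0)

    S = build_stoichiometric_matrix(network)
    K = build_reaction_order_matrix(network)
    use_extended = bool(opts.get("dual-pairs-in-ec", True))
    S_used = extend_stoichiometric(S, network.dual_pairs) if use_extended else S
    E = extreme_currents(S_used)
    js = j_symbols(E.shape[1])
    V = current_matrix(S, E, K)
    frank = frank_inequality_current(V)
    equalities = [] if use_extended else dual_pair_equalities(E, network.dual_pairs)
    positivity = [Constraint(j, "gt") for j in js]
    constraints = positivity + equalities + [frank]

    try:
        solution = _sampler.linear_solve_intervals(constraints, list(js))
        feasible = True
    except _sampler.Infeasible:
        solution, feasible = None, False

    conditions = InstabilityConditionSet(
        positivity=positivity, branches=[[frank]], heuristic="frank-inequality"
    )
    n_samples = int(opts.get("num-samples", 10))
    samples, fp = _sampler.sample_condition_set(
        network, E, conditions, equalities, rng,
        n_samples=n_samples,
        tries=int(opts.get("simplification-tries", 10000)),
        algorithm="frank-ineq-linear", seed=seed,
    )
    n_prop = opts.get("samples-for-proportion")
    proportion = _sampler.frank_proportion(samples, network)
    if samples and n_prop and int(n_prop) > n_samples:
        extra, _ = _sampler.sample_condition_set(
            network, E, conditions, equalities, rng,
            n_samples=int(n_prop) - n_samples,
            algorithm="frank-ineq-linear", seed=seed,
        )
        proportion = _sampler.frank_proportion(samples + extra, network)
    if not samples:
        verdict = "unable to find unstable steady states"
    else:
        n_frank = sum(1 for s in samples if s.flags.get("frank"))
        verdict = f"{n_frank} of {len(samples)} sampled points are frank"
        if not feasible:
            verdict += " (only degenerate boundary solutions exist)"
    return FrankSnaReport(
        E=E, V=V, frank_inequality=frank, equalities=equalities,
        interval_solution=solution, feasible=feasible, samples=samples,
        frank_proportion=proportion, false_positive_rate=fp, verdict=verdict,
    )


# ----------------------------------------------------------------------
# algorithm 6
# ----------------------------------------------------------------------

@dataclass
class ReducedCurrentMatrix:
    """``V'(J) = A - B`` with A the left-left and B the left-right block."""

    A: sp.Matrix
    B: sp.Matrix
    reduced: sp.Matrix
    species_order: list[int]  # lefts + rights + achiral
    reshaped: sp.Matrix       # V permuted to exhibit the [A B; B A] pattern


def reduce_multi_pair(
    V: sp.Matrix, enantiomeric_pairs: list[tuple[int, int]]
) -> ReducedCurrentMatrix:
    """Block reduction of the current matrix for multi-pair networks.

    Species are reordered (all-left, all-right, achiral); the [A B; B A]
    symmetry of the chiral blocks is verified exactly and ``A - B``
    (size m x m, m = number of pairs) is returned.
    """
    n = V.shape[0]
    lefts = [a for a, _ in enantiomeric_pairs]
    rights = [b for _, b in enantiomeric_pairs]
    achiral = [i for i in range(n) if i not in set(lefts) | set(rights)]
    order = lefts + rights + achiral
    P = sp.zeros(n, n)
    for new, old in enumerate(order):
        P[new, old] = 1
    reshaped = P * V * P.T
    m = len(lefts)
    A = reshaped[:m, :m]
    B = reshaped[:m, m:2 * m]
    A2 = reshaped[m:2 * m, m:2 * m]
    B2 = reshaped[m:2 * m, :m]
    bad = [
        (i, j)
        for i in range(m)
        for j in range(m)
        if sp.expand(A[i, j] - A2[i, j]) != 0
        or sp.expand(B[i, j] - B2[i, j]) != 0
    ]
    if bad:
        raise ValueError(
            f"[A B; B A] symmetry violated at block entries {bad}; "
            "check the declared dual pairs"
        )
    return ReducedCurrentMatrix(
        A=A, B=B, reduced=sp.expand(A - B), species_order=order,
        reshaped=reshaped,
    )


@dataclass
class MultiPairReport:
    E: np.ndarray
    V: sp.Matrix
    reduction: ReducedCurrentMatrix
    conditions: InstabilityConditionSet
    restrictions: list[Constraint]
    samples: list = field(default_factory=list)
    false_positive_rate: float | None = None
    verdict: str = ""


def run_multi_pair(
    network: ReactionNetwork,
    options: dict | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> MultiPairReport:
    """Algorithm 6: Frank reduction plus SNA machinery on ``V'(J)``."""
    from . import sampler as _sampler
    from .network_model import DEFAULT_OPTIONS

    opts = dict(DEFAULT_OPTIONS)
    opts.update(options or {})
    rng = rng or np.random.default_rng(0)

    pairs = [tuple(p) for p in opts.get("enantiomeric-pairs") or
             network.enantiomeric_pairs]
    S = build_stoichiometric_matrix(network)
    K = build_reaction_order_matrix(network)
    use_extended = bool(opts.get("dual-pairs-in-ec", True))
    S_used = extend_stoichiometric(S, network.dual_pairs) if use_extended else S
    E = extreme_currents(S_used)
    V = current_matrix(S, E, K)
    reduction = reduce_multi_pair(V, pairs)

    heuristic = opts.get("instability-heuristic", "mineurs")
    if heuristic == "trace-determinant" and reduction.reduced.shape[0] != 2:
        heuristic = "mineurs"
    conditions = instability_conditions(
        reduction.reduced, heuristic,
        sum_mineurs=bool(opts.get("sum-mineurs", True)),
        max_mineur_search_stop=int(opts.get("max-mineur-search-stop", 5)),
        n_currents=E.shape[1],
    )
    equalities = [] if use_extended else dual_pair_equalities(E, network.dual_pairs)
    restrictions = list(conditions.positivity)
    feasible_branch = _first_feasible_branch(conditions, equalities, E)
    if feasible_branch is not None:
        restrictions += feasible_branch

    samples, fp = _sampler.sample_condition_set(
        network, E, conditions, equalities, rng,
        n_samples=int(opts.get("num-samples", 10)),
        tries=int(opts.get("simplification-tries", 10000)),
        algorithm="frank-pseudoquiral", seed=seed,
    )
    verdict = (
        "no unstable symmetry-breaking states found" if not samples
        else f"sampled {len(samples)} candidate symmetry-breaking states"
    )
    return MultiPairReport(
        E=E, V=V, reduction=reduction, conditions=conditions,
        restrictions=restrictions, samples=samples,
        false_positive_rate=fp, verdict=verdict,
    )


def _first_feasible_branch(conditions, equalities, E):
    """The first branch whose *linear part* is not provably infeasible."""
    from . import sampler as _sampler

    js = j_symbols(E.shape[1])
    for branch in conditions.branches:
        linear = [
            c for c in list(conditions.positivity) + list(equalities) + list(branch)
            if _sampler._is_linear(c.expr, set(c.expr.free_symbols))
        ]
        try:
            _sampler.linear_solve_intervals(
                linear, list(js) + list(conditions.extra_symbols)
            )
            return list(branch)
        except _sampler.Infeasible:
            continue
    return None


# ----------------------------------------------------------------------

def run_algorithm(number: int, network: ReactionNetwork, options=None,
                  rng=None, seed=None):
    """Dispatch algorithms 3..6 by number."""
    if number == 3:
        return run_six_categories(network, options, rng)
    if number == 4:
        return run_frank_nonlinear(network)
    if number == 5:
        return run_frank_sna(network, options, rng, seed)
    if number == 6:
        return run_multi_pair(network, options, rng, seed)
    raise ValueError(f"no algorithm numbered {number}")
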