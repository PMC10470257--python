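"""Solve linear equality/strict-inequality systems into nested intervals,
linearise nonlinear systems heuristically, draw samples, and convert
current-space samples into concrete rate constants.

All interval arithmetic is exact (sympy rationals); random draws are
converted to exact rationals before entering any constraint check, so every
released sample satisfies every original constraint on exact
re-substitution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
import sympy as sp

from .network_model import ReactionNetwork
from .sna_engine import Constraint, InstabilityConditionSet
from .symbolic_kinetics import (
    build_reaction_order_matrix,
    evaluate_jacobian,
    j_symbols,
    k_symbols,
)

__all__ = [
    "IntervalSolution", "RateSample", "Infeasible",
    "linear_solve_intervals", "nonlinear_to_linear", "sample_from_intervals",
    "currents_to_rates", "frank_proportion", "sample_condition_set",
    "is_unstable", "is_frank", "antisymmetric_basis",
]

_OO = sp.oo


class Infeasible(Exception):
    """The constraint system has no solution (under the given relaxation)."""


class LinearizationFailure(Exception):
    """nonlinear_to_linear exhausted its attempt budget."""

    def __init__(self, attempts: int):
        super().__init__(f"could not linearise after {attempts} attempts")
        self.attempts = attempts


@dataclass
class IntervalSolution:
    """Nested-interval solution of a linear system.

    Variables are sampled in ``order``; each variable's bounds are
    expressions in the previously ordered variables.  ``derived`` maps
    variables eliminated through equalities to their back-substitution
    expressions.
    """

    order: list[sp.Symbol]
    lowers: dict[sp.Symbol, list[tuple[sp.Expr, bool]]]
    uppers: dict[sp.Symbol, list[tuple[sp.Expr, bool]]]
    derived: dict[sp.Symbol, sp.Expr] = field(default_factory=dict)

    def lower_expr(self, var: sp.Symbol) -> sp.Expr:
        exprs = [e for e, _ in self.lowers.get(var, [])]
        if not exprs:
            return -_OO
        return exprs[0] if len(exprs) == 1 else sp.Max(*exprs)

    def upper_expr(self, var: sp.Symbol) -> sp.Expr:
        exprs = [e for e, _ in self.uppers.get(var, [])]
        if not exprs:
            return _OO
        return exprs[0] if len(exprs) == 1 else sp.Min(*exprs)

    def describe(self) -> str:
        lines = []
        for var in self.order:
            lo, hi = self.lower_expr(var), self.upper_expr(var)
            lines.append(f"{var} in ({lo}, {hi})")
        for var, expr in self.derived.items():
            lines.append(f"{var} = {expr}")
        return "\n".join(lines)


def _is_linear(expr: sp.Expr, variables: set[sp.Symbol]) -> bool:
    expr = sp.expand(expr)
    for term in sp.Add.make_args(expr):
        degree = 0
        for factor in sp.Mul.make_args(term):
            base, exp = factor.as_base_exp()
            if base in variables:
                if not (exp.is_integer and exp >= 0):
                    return False
                degree += int(exp)
        if degree > 1:
            return False
    return True


def _substitute_equalities(
    constraints: Sequence[Constraint], order: Sequence[sp.Symbol]
) -> tuple[list[Constraint], dict[sp.Symbol, sp.Expr]]:
    """Eliminate equalities, preferring variables outside the FM order."""
    order = list(order)
    work = list(constraints)
    derived: dict[sp.Symbol, sp.Expr] = {}
    while True:
        eq = next((c for c in work if c.rel == "eq" and c.expr != 0), None)
        if eq is None:
            break
        work.remove(eq)
        syms = sorted(eq.expr.free_symbols, key=str)
        outside = [s for s in syms if s not in order]
        candidates = outside or [s for s in reversed(order) if s in syms]
        var = None
        for cand in candidates:
            if eq.expr.diff(cand).is_number:
                var = cand
                break
        if var is None:
            raise Infeasible(f"cannot solve equality {eq} linearly")
        sol = sp.solve(eq.expr, var)
        if not sol:
            raise Infeasible(f"inconsistent equality {eq}")
        repl = sp.expand(sol[0])
        derived = {v: sp.expand(e.subs(var, repl)) for v, e in derived.items()}
        derived[var] = repl
        work = [
            Constraint(sp.expand(c.expr.subs(var, repl)), c.rel) for c in work
        ]
        if var in order:
            order.remove(var)
    # drop constraints that became trivially true, catch trivially false
    kept = []
    for c in work:
        if c.expr.is_number:
            _check_constant(c)
        else:
            kept.append(c)
    return kept, derived, order


def _check_constant(c: Constraint) -> None:
    val = c.expr
    ok = {"gt": val > 0, "ge": val >= 0, "eq": val == 0}[c.rel]
    if not ok:
        raise Infeasible(f"contradictory constant constraint {c}")


def _prune_bounds(
    bounds: list[tuple[sp.Expr, bool]],
    others: Sequence[Constraint],
    kind: str,
) -> list[tuple[sp.Expr, bool]]:
    """Drop bounds provably dominated by another bound.

    A bound is dropped when the dominating difference is a nonnegative
    constant or a positive multiple of a single remaining constraint —
    mirroring the light-weight simplification a CAS applies, so nested
    ``max(...)``/``min(...)`` bounds keep exactly the non-trivial arms.
    """
    uniq: list[tuple[sp.Expr, bool]] = []
    for expr, strict in bounds:
        found = False
        for i, (e, s) in enumerate(uniq):
            if sp.expand(expr - e) == 0:
                uniq[i] = (e, s or strict)
                found = True
        if not found:
            uniq.append((expr, strict))
    exprs_pos = [sp.expand(c.expr) for c in others if c.rel in ("gt", "ge")]

    def dominated(b: sp.Expr, by: sp.Expr) -> bool:
        diff = sp.expand(by - b) if kind == "lower" else sp.expand(b - by)
        if diff.is_number:
            return diff >= 0
        for g in exprs_pos:
            q = sp.cancel(diff / g)
            if q.is_number and q > 0:
                return True
        return False

    keep = []
    for i, (b, strict) in enumerate(uniq):
        if not any(dominated(b, other) for k, (other, _) in enumerate(uniq) if k != i):
            keep.append((b, strict))
    return keep or uniq[:1]


def linear_solve_intervals(
    constraints: Sequence[Constraint],
    variable_order: Sequence[sp.Symbol],
) -> IntervalSolution:
    """Fourier-Motzkin elimination into a nested interval solution.

    Variables are eliminated in reverse of ``variable_order``; equalities
    eliminate variables by substitution first (preferring variables outside
    the order, recorded for back-substitution).  Raises :class:`Infeasible`
    when elimination produces a contradictory constant constraint.
    """
    variables = set(variable_order)
    for c in constraints:
        if c.rel != "eq" and not _is_linear(c.expr, set(c.expr.free_symbols)):
            raise ValueError(f"nonlinear constraint {c}: linearise first")
    work, derived, order = _substitute_equalities(constraints, variable_order)
    for c in work:
        if not _is_linear(c.expr, set(c.expr.free_symbols)):
            raise ValueError(f"nonlinear constraint {c}: linearise first")

    lowers: dict[sp.Symbol, list] = {}
    uppers: dict[sp.Symbol, list] = {}
    for var in reversed(order):
        involving = [c for c in work if var in c.expr.free_symbols]
        others = [c for c in work if var not in c.expr.free_symbols]
        lo, hi = [], []
        for c in involving:
            a = c.expr.diff(var)
            if not a.is_number:
                raise ValueError(f"nonlinear in {var}: {c}")
            rest = sp.expand(c.expr - a * var)
            bound = sp.expand(-rest / a)
            strict = c.rel == "gt"
            (lo if a > 0 else hi).append((bound, strict))
        lo = _prune_bounds(lo, others, "lower")
        hi = _prune_bounds(hi, others, "upper")
        lowers[var], uppers[var] = lo, hi
        for lb, ls in lo:
            for ub, us in hi:
                expr = sp.expand(ub - lb)
                rel = "gt" if (ls or us) else "ge"
                if expr.is_number:
                    _check_constant(Constraint(expr, rel))
                else:
                    others.append(Constraint(expr, rel))
        work = others
    for c in work:
        if c.expr.is_number:
            _check_constant(c)
        else:  # symbols outside the order: cannot be decided here
            raise ValueError(f"constraint {c} involves unordered symbols")
    return IntervalSolution(order=list(order), lowers=lowers, uppers=uppers,
                            derived=derived)


# ----------------------------------------------------------------------
# nonlinear -> linear heuristic
# ----------------------------------------------------------------------

def _nonlinear_var_counts(
    constraints: Sequence[Constraint], variables: set[sp.Symbol]
) -> dict[sp.Symbol, int]:
    counts: dict[sp.Symbol, int] = {}
    for c in constraints:
        for term in sp.Add.make_args(sp.expand(c.expr)):
            syms = term.free_symbols & variables
            degree = sum(
                int(f.as_base_exp()[1])
                for f in sp.Mul.make_args(term)
                if f.as_base_exp()[0] in variables
            )
            if degree > 1:
                for s in syms:
                    counts[s] = counts.get(s, 0) + 1
    return counts


def _reduce_univariate(
    constraint: Constraint, var: sp.Symbol
) -> list[Constraint] | None:
    """Turn a univariate polynomial inequality into linear bounds.

    The constraint is solved jointly with ``var > 0`` (all sampling
    variables are positive); a single-interval solution yields linear
    bounds, an empty set signals infeasibility, anything else gives up.
    """
    from sympy.solvers.inequalities import reduce_rational_inequalities

    rel = (constraint.expr > 0) if constraint.rel == "gt" else (constraint.expr >= 0)
    try:
        sol = reduce_rational_inequalities([[rel]], var, relational=False)
    except sp.PolynomialError:
        return None
    sol = sol.intersect(sp.Interval.open(0, _OO))
    if sol is sp.S.EmptySet:
        raise Infeasible(f"{constraint} has no positive solution")
    if isinstance(sol, sp.Union):
        # keep the component reaching +oo, else the rightmost one
        parts = [s for s in sol.args if isinstance(s, sp.Interval)]
        unbounded = [s for s in parts if s.sup is _OO]
        sol = unbounded[0] if unbounded else max(parts, key=lambda s: s.sup)
    if not isinstance(sol, sp.Interval):
        return None
    out = [Constraint(sp.expand(var - sol.inf),
                      "gt" if sol.left_open else "ge")]
    if sol.sup is not _OO:
        out.append(Constraint(sp.expand(sol.sup - var),
                              "gt" if sol.right_open else "ge"))
    return out


def _draw_log_uniform(rng: np.random.Generator, lo=1e-3, hi=1e3) -> sp.Rational:
    value = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return sp.Rational(Fraction(value))


def nonlinear_to_linear(
    constraints: Sequence[Constraint],
    rng: np.random.Generator,
    tries: int = 10000,
    draw: Callable[[sp.Symbol], object] | None = None,
    variables: Sequence[sp.Symbol] | None = None,
) -> tuple[list[Constraint], dict[sp.Symbol, sp.Rational]]:
    """Heuristic linearisation by pseudo-random substitution.

    Repeatedly: reduce univariate polynomial inequalities to interval
    bounds; otherwise pick the variable occurring in the most nonlinear
    monomials (ties broken by lowest index), substitute a pseudo-random
    positive value and simplify — until everything is linear or the attempt
    budget is exhausted.  Returns the linear system and the substitution
    map.
    """
    if variables is None:
        variables = sorted(
            set().union(*[c.expr.free_symbols for c in constraints]) or set(),
            key=str,
        )
    varset = set(variables)
    base = list(constraints)
    attempts = 0
    while attempts < max(tries, 1):
        work = list(base)
        fixed: dict[sp.Symbol, sp.Rational] = {}
        try:
            while True:
                nonlin = [c for c in work if not _is_linear(c.expr, varset)]
                if not nonlin:
                    return work, fixed
                progressed = False
                for c in nonlin:
                    vs = c.expr.free_symbols & varset
                    if len(vs) == 1:
                        reduced = _reduce_univariate(c, next(iter(vs)))
                        if reduced is not None:
                            work.remove(c)
                            work.extend(reduced)
                            progressed = True
                            break
                if progressed:
                    continue
                counts = _nonlinear_var_counts(nonlin, varset)
                var = min(counts, key=lambda s: (-counts[s], str(s)))
                attempts += 1
                value = sp.sympify(draw(var)) if draw else _draw_log_uniform(rng)
                fixed[var] = value
                new_work = []
                for c in work:
                    expr = sp.expand(c.expr.subs(var, value))
                    if expr.is_number:
                        _check_constant(Constraint(expr, c.rel))
                    else:
                        new_work.append(Constraint(expr, c.rel))
                work = new_work
        except Infeasible:
            if not fixed:
                raise  # infeasible before any substitution: hopeless
            continue  # redraw
    raise LinearizationFailure(attempts)


# ----------------------------------------------------------------------
# sampling
# ----------------------------------------------------------------------

def _exact(value: float) -> sp.Rational:
    return sp.Rational(Fraction(float(value)))

#: relative margin kept away from strict bounds
STRICT_MARGIN = 1e-9


def sample_from_intervals(
    solution: IntervalSolution,
    n: int,
    rng: np.random.Generator,
    original_constraints: Sequence[Constraint] = (),
    retry_budget: int = 100,
) -> list[dict[sp.Symbol, sp.Rational]]:
    """Draw ``n`` assignments respecting the nested interval solution.

    Variables are drawn in nesting order: bounded intervals uniformly,
    half-open intervals as ``bound +/- 10**U(-2, 2)``.  Every assignment is
    re-checked exactly against the original constraints before release.
    """
    out = []
    failures = 0
    while len(out) < n:
        if failures > retry_budget:
            break
        assignment: dict[sp.Symbol, sp.Rational] = {}
        ok = True
        for var in solution.order:
            lo = sp.expand(solution.lower_expr(var).subs(assignment))
            hi = sp.expand(solution.upper_expr(var).subs(assignment))
            lo_strict = any(s for _, s in solution.lowers.get(var, [(0, False)]))
            hi_strict = any(s for _, s in solution.uppers.get(var, [(0, False)]))
            value = _draw_in_interval(rng, lo, hi, lo_strict, hi_strict)
            if value is None:
                ok = False
                break
            assignment[var] = value
        if ok:
            for var, expr in solution.derived.items():
                assignment[var] = sp.expand(expr.subs(assignment))
            ok = all(c.holds(assignment) for c in original_constraints)
        if ok:
            out.append(assignment)
        else:
            failures += 1
    return out


def _draw_in_interval(rng, lo, hi, lo_strict, hi_strict):
    if lo is -_OO and hi is _OO:
        sign = 1 if rng.random() < 0.5 else -1
        return _exact(sign * 10.0 ** rng.uniform(-2, 2))
    if hi is _OO:
        return sp.expand(lo + _exact(10.0 ** rng.uniform(-2, 2)))
    if lo is -_OO:
        return sp.expand(hi - _exact(10.0 ** rng.uniform(-2, 2)))
    width = sp.expand(hi - lo)
    if width < 0:
        return None
    if width == 0:
        if lo_strict or hi_strict:
            return None
        return lo
    margin = STRICT_MARGIN
    u_lo = margin if lo_strict else 0.0
    u_hi = 1.0 - margin if hi_strict else 1.0
    u = _exact(rng.uniform(u_lo, u_hi))
    return sp.expand(lo + width * u)


# ----------------------------------------------------------------------
# currents -> rate constants
# ----------------------------------------------------------------------

@dataclass
class RateSample:
    """A concrete rate-constant set with provenance metadata."""

    model: str
    algorithm: str
    seed: int | None
    rate_constants: dict[str, float]
    initial_concentrations: dict[str, float]
    currents: dict[str, float]
    flags: dict[str, object] = field(default_factory=dict)
    exact_rates: dict[int, sp.Rational] = field(default_factory=dict)
    exact_concentrations: dict[int, sp.Rational] = field(default_factory=dict)

    def rate_vector(self, n_reactions: int) -> np.ndarray:
        return np.array(
            [float(self.rate_constants[f"k{i}"]) for i in range(n_reactions)]
        )

    def concentration_vector(self, species_names: Sequence[str]) -> np.ndarray:
        return np.array(
            [float(self.initial_concentrations[n]) for n in species_names]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model,
                "algorithm": self.algorithm,
                "seed": self.seed,
                "rate_constants": self.rate_constants,
                "initial_concentrations": self.initial_concentrations,
                "currents": self.currents,
                "flags": self.flags,
            },
            indent=2,
            sort_keys=True,
        )

    def save(self, folder: str, stem: str) -> str:
        """Write the sample as ``<stem>.simu.json`` inside ``folder``."""
        import os

        os.makedirs(folder, exist_ok=True)
        path = os.path.join(folder, f"{stem}.simu.json")
        with open(path, "w") as fh:
            fh.write(self.to_json())
        return path

    @classmethod
    def from_json(cls, text: str) -> "RateSample":
        data = json.loads(text)
        return cls(
            model=data["model"], algorithm=data["algorithm"],
            seed=data.get("seed"), rate_constants=data["rate_constants"],
            initial_concentrations=data["initial_concentrations"],
            currents=data.get("currents", {}), flags=data.get("flags", {}),
        )


def _concentration_classes(network: ReactionNetwork, K: np.ndarray) -> list[int]:
    """Species classes that must share a concentration value.

    Enantiomer partners are always drawn equal.  Additionally, when a dual
    pair ties reactions whose kinetic-order rows differ even after the
    partner identification (e.g. a rate shared between two cross-catalytic
    channels), the species involved are unified as well — otherwise the
    equal fluxes could not divide out to exactly equal rate constants.
    """
    parent = list(range(network.n_species))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for a, b in network.enantiomeric_pairs:
        union(a, b)
    changed = True
    while changed:
        changed = False
        for ra, rb in network.dual_pairs:
            rows = []
            for r in (ra, rb):
                row: dict[int, int] = {}
                for s in range(network.n_species):
                    if K[r, s]:
                        root = find(s)
                        row[root] = row.get(root, 0) + int(K[r, s])
                rows.append(row)
            if rows[0] != rows[1]:
                involved = set(rows[0]) | set(rows[1])
                first = min(involved)
                for s in involved:
                    union(first, s)
                changed = True
    return [find(s) for s in range(network.n_species)]


def currents_to_rates(
    E: np.ndarray,
    j_assignment: dict[sp.Symbol, sp.Rational],
    network: ReactionNetwork,
    rng: np.random.Generator,
    *,
    model_tag: str = "",
    algorithm: str = "",
    seed: int | None = None,
) -> RateSample:
    """Convert a current-space sample to rate constants via ``v = E.j``.

    Concentrations are drawn uniformly in [0.001, 0.01] (arbitrary units)
    with enantiomer partners assigned equal values, then
    ``k_i = v_i / prod_s x_s**K[i][s]``; the assigned concentrations are a
    steady state of the resulting rate set by construction.  Dual-pair rate
    equality is verified exactly.
    """
    K = build_reaction_order_matrix(network)
    js = j_symbols(E.shape[1])
    jvec = [sp.nsimplify(j_assignment[j], rational=True) for j in js]
    v = [
        sp.expand(sum(sp.Integer(int(E[i, c])) * jvec[c]
                      for c in range(E.shape[1])))
        for i in range(network.n_reactions)
    ]

    roots = _concentration_classes(network, K)
    draws: dict[int, sp.Rational] = {}
    x: dict[int, sp.Rational] = {}
    for sp_obj in network.species:
        root = roots[sp_obj.index]
        if root not in draws:
            draws[root] = _exact(rng.uniform(0.001, 0.01))
        x[sp_obj.index] = draws[root]

    zero_rates = []
    k: dict[int, sp.Rational] = {}
    for i in range(network.n_reactions):
        denom = sp.Integer(1)
        for s in range(network.n_species):
            if K[i, s]:
                denom *= x[s] ** int(K[i, s])
        k[i] = sp.nsimplify(v[i] / denom, rational=True)
        if k[i] == 0:
            zero_rates.append(i)

    for a, b in network.dual_pairs:
        if k[a] != k[b]:
            raise AssertionError(
                f"dual pair ({a}, {b}) produced unequal rates {k[a]} != {k[b]}"
            )

    flags: dict[str, object] = {}
    if zero_rates:
        flags["zero_rate_reactions"] = zero_rates
        flags["degenerate"] = True
    return RateSample(
        model=model_tag or network.name,
        algorithm=algorithm,
        seed=seed,
        rate_constants={f"k{i}": float(k[i]) for i in k},
        initial_concentrations={
            network.species[s].name: float(x[s]) for s in x
        },
        currents={str(j): float(j_assignment[j]) for j in js},
        flags=flags,
        exact_rates=k,
        exact_concentrations=x,
    )


# ----------------------------------------------------------------------
# numeric instability / frank checks
# ----------------------------------------------------------------------

_EIG_TOL = 1e-9


def antisymmetric_basis(network: ReactionNetwork) -> np.ndarray:
    """Orthonormal basis of the antisymmetric-under-enantiomer-swap subspace."""
    cols = []
    for a, b in network.enantiomeric_pairs:
        col = np.zeros(network.n_species)
        col[a], col[b] = 1.0, -1.0
        cols.append(col / np.sqrt(2.0))
    return np.array(cols).T


def is_unstable(network: ReactionNetwork, k, x) -> bool:
    J = evaluate_jacobian(network, k, x)
    return float(np.max(np.linalg.eigvals(J).real)) > _EIG_TOL


def is_frank(network: ReactionNetwork, k, x) -> bool:
    """Unstable along an antisymmetric (symmetry-breaking) direction.

    The enantiomer swap commutes with the Jacobian at a symmetric state, so
    the antisymmetric subspace is invariant; a positive real-part eigenvalue
    of the Jacobian restricted to it is exactly a symmetry-breaking mode.
    """
    J = evaluate_jacobian(network, k, x)
    B = antisymmetric_basis(network)
    JA = B.T @ J @ B
    return float(np.max(np.linalg.eigvals(JA).real)) > _EIG_TOL


def frank_proportion(
    samples: Sequence[RateSample], network: ReactionNetwork
) -> float | None:
    """Fraction of samples whose steady state has an antisymmetric unstable
    mode; ``None`` (undefined) for an empty sample list."""
    if not samples:
        return None
    hits = 0
    names = network.species_names
    for sample in samples:
        k = sample.rate_vector(network.n_reactions)
        x = sample.concentration_vector(names)
        if is_frank(network, k, x):
            hits += 1
    return hits / len(samples)


# ----------------------------------------------------------------------
# orchestration used by the analyses
# ----------------------------------------------------------------------

def _relax(constraints: Sequence[Constraint]) -> list[Constraint]:
    return [
        Constraint(c.expr, "ge" if c.rel == "gt" else c.rel) for c in constraints
    ]


def sample_condition_set(
    network: ReactionNetwork,
    E: np.ndarray,
    conditions: InstabilityConditionSet,
    equalities: Sequence[Constraint],
    rng: np.random.Generator,
    *,
    n_samples: int = 10,
    tries: int = 10000,
    algorithm: str = "sna",
    allow_degenerate: bool = True,
    seed: int | None = None,
) -> tuple[list[RateSample], float | None]:
    """Sample rate sets satisfying any branch of an instability condition set.

    Branches are tried in order; when no branch is strictly feasible and
    ``allow_degenerate`` is set, strict inequalities are relaxed to
    non-strict and boundary solutions (some currents exactly zero) are
    sampled, flagged ``degenerate``.  Returns the samples and the measured
    false-positive rate (fraction not numerically unstable), which is
    reported, never hidden.
    """
    js = j_symbols(E.shape[1])
    base = list(conditions.positivity) + list(equalities)
    order = list(js) + list(conditions.extra_symbols)

    samples: list[RateSample] = []
    for relaxed in (False, True):
        if relaxed and not allow_degenerate:
            break
        for branch in conditions.branches:
            system = base + list(branch)
            if relaxed:
                system = _relax(system)
            try:
                # equalities are eliminated exactly first; substituting
                # random values before enforcing them would almost surely
                # contradict them
                work, derived, eliminated_order = _substitute_equalities(
                    system, order
                )
                linear, fixed = nonlinear_to_linear(
                    work, rng, tries=tries, variables=eliminated_order
                )
                remaining = [v for v in eliminated_order if v not in fixed]
                solution = linear_solve_intervals(linear, remaining)
            except (Infeasible, LinearizationFailure):
                continue
            check = [
                Constraint(sp.expand(c.expr.subs(fixed)), c.rel) for c in work
            ] if fixed else list(work)
            check = [c for c in check if not c.expr.is_number]
            assignments = sample_from_intervals(
                solution, n_samples, rng, original_constraints=check
            )
            for a in assignments:
                a.update(fixed)
                for var, expr in derived.items():
                    a[var] = sp.expand(expr.subs(a))
                assert all(c.holds(a) for c in system), \
                    "sample violates an original constraint"
                full = {j: a.get(j, sp.Integer(0)) for j in js}
                sample = currents_to_rates(
                    E, full, network, rng,
                    algorithm=algorithm, seed=seed,
                )
                if relaxed:
                    sample.flags["degenerate"] = True
                k = sample.rate_vector(network.n_reactions)
                x = sample.concentration_vector(network.species_names)
                sample.flags["unstable"] = is_unstable(network, k, x)
                sample.flags["frank"] = is_frank(network, k, x)
                samples.append(sample)
            if samples:
                break
        if samples:
            break
    if not samples:
        return [], None
    fp = sum(1 for s in samples if not s.flags["unstable"]) / len(samples)
    return samples, fp
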