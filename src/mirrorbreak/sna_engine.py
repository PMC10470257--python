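"""Stoichiometric network analysis: extreme currents, current matrix,
instability conditions.

The steady-state flux cone ``{v >= 0 : S.v = 0}`` is spanned by its extreme
rays (extreme currents), collected column-wise in an integer matrix ``E``.
Any steady flux is ``E.j`` with convex parameters ``j >= 0``, and the
steady-state Jacobian factorises as ``S.diag(E.j).K.diag(h)``; the last
factor does not affect stability and is dropped, leaving the current matrix
``V(J) = S.diag(E.j).K`` whose entries are linear in ``j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gcd
from typing import Sequence

import numpy as np
import sympy as sp

from .network_model import ReactionNetwork
from .symbolic_kinetics import (
    LAMBDA,
    build_reaction_order_matrix,
    build_stoichiometric_matrix,
    j_symbols,
)

__all__ = [
    "Constraint", "InstabilityConditionSet",
    "extend_stoichiometric", "extreme_currents", "current_matrix",
    "dual_pair_equalities", "instability_conditions", "run_sna", "SnaReport",
]


# ----------------------------------------------------------------------
# constraints
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Constraint:
    """A polynomial constraint ``expr rel 0`` with rel in {'gt','ge','eq'}."""

    expr: sp.Expr
    rel: str = "gt"

    def __post_init__(self):
        if self.rel not in ("gt", "ge", "eq"):
            raise ValueError(f"unknown relation {self.rel!r}")

    def __str__(self) -> str:
        op = {"gt": ">", "ge": ">=", "eq": "="}[self.rel]
        return f"{self.expr} {op} 0"

    def holds(self, assignment: dict, tol: float = 0.0) -> bool:
        val = self.expr.subs(assignment)
        if val.free_symbols:
            raise ValueError(f"unbound symbols in {self}: {val.free_symbols}")
        val = float(val) if not isinstance(val, (int, float)) else val
        if self.rel == "gt":
            return val > tol
        if self.rel == "ge":
            return val >= -tol
        return abs(val) <= tol


@dataclass
class InstabilityConditionSet:
    """Restrictions whose joint solutions encode candidate unstable states."""

    positivity: list[Constraint]
    equalities: list[Constraint] = field(default_factory=list)
    branches: list[list[Constraint]] = field(default_factory=list)
    heuristic: str = "mineurs"
    extra_symbols: list[sp.Symbol] = field(default_factory=list)

    @property
    def stable(self) -> bool:
        """No candidate instability condition was found."""
        return not self.branches


# ----------------------------------------------------------------------
# extreme currents
# ----------------------------------------------------------------------

def extend_stoichiometric(S: np.ndarray, dual_pairs: Sequence[tuple[int, int]]
                          ) -> np.ndarray:
    """Append one +1/-1 row per dual pair, forcing equal fluxes on the pair."""
    n_rxn = S.shape[1]
    rows = []
    for a, b in dual_pairs:
        row = np.zeros(n_rxn, dtype=np.int64)
        row[a], row[b] = 1, -1
        rows.append(row)
    if not rows:
        return S.copy()
    return np.vstack([S, np.array(rows, dtype=np.int64)])


def extreme_currents(S_used: np.ndarray) -> np.ndarray:
    """Extreme rays of ``{v >= 0 : S_used.v = 0}`` as integer columns.

    Double description over exact integers: start from the orthant's unit
    rays and intersect with one kernel hyperplane at a time, keeping only
    support-minimal rays (for cones of this form the extreme rays are
    exactly the support-minimal nonzero solutions).  Columns are normalised
    to coprime integers and ordered descending-lexicographically.
    """
    n_rows, n_rxn = S_used.shape
    rays: list[tuple[int, ...]] = [
        tuple(1 if i == r else 0 for i in range(n_rxn)) for r in range(n_rxn)
    ]
    for row in S_used:
        row = [int(c) for c in row]
        pos, neg, zero = [], [], []
        for ray in rays:
            d = sum(a * b for a, b in zip(row, ray))
            (pos if d > 0 else neg if d < 0 else zero).append((ray, d))
        new = [ray for ray, _ in zero]
        for rp, dp in pos:
            for rn, dn in neg:
                combo = tuple(dp * b - dn * a for a, b in zip(rp, rn))
                new.append(_normalize_ray(combo))
        rays = _support_minimal(new)
        if not rays:
            break
    rays = sorted(set(rays), reverse=True)
    if not rays:
        return np.zeros((n_rxn, 0), dtype=np.int64)
    return np.array(rays, dtype=np.int64).T


def _normalize_ray(ray: tuple[int, ...]) -> tuple[int, ...]:
    g = 0
    for c in ray:
        g = gcd(g, c)
    return ray if g in (0, 1) else tuple(c // g for c in ray)


def _support_minimal(rays: list[tuple[int, ...]]) -> list[tuple[int, ...]]:
    uniq = sorted(set(_normalize_ray(r) for r in rays if any(r)))
    supports = [frozenset(i for i, c in enumerate(r) if c) for r in uniq]
    keep = []
    for i, (ray, sup) in enumerate(zip(uniq, supports)):
        if not any(
            other < sup for k, other in enumerate(supports) if k != i
        ):
            keep.append(ray)
    return keep


# ----------------------------------------------------------------------
# current matrix and restrictions
# ----------------------------------------------------------------------

def current_matrix(S: np.ndarray, E: np.ndarray, K: np.ndarray) -> sp.Matrix:
    """``V(J) = S.diag(E.j).K`` with symbolic convex parameters j.

    ``S`` and ``K`` are always the original matrices; only ``E`` changes
    when the extended stoichiometric matrix is used.
    """
    n, r = S.shape
    rK, nK = K.shape
    if E.shape[0] != r or rK != r or nK != n:
        raise ValueError(
            f"dimension mismatch: S {S.shape}, E {E.shape}, K {K.shape}"
        )
    js = j_symbols(E.shape[1])
    flux = [
        sp.expand(sum(int(E[i, c]) * js[c] for c in range(E.shape[1])))
        for i in range(r)
    ]
    V = sp.zeros(n, n)
    for s in range(n):
        for t in range(n):
            V[s, t] = sp.expand(
                sum(int(S[s, i]) * flux[i] * int(K[i, t]) for i in range(r))
            )
    return V


def dual_pair_equalities(E: np.ndarray, dual_pairs: Sequence[tuple[int, int]]
                         ) -> list[Constraint]:
    """Equal-flux restrictions ``row_a(E).j = row_b(E).j``, dropping trivial ones."""
    js = j_symbols(E.shape[1])
    out = []
    for a, b in dual_pairs:
        expr = sp.expand(
            sum(int(E[a, c] - E[b, c]) * js[c] for c in range(E.shape[1]))
        )
        if expr != 0:
            out.append(Constraint(expr, "eq"))
    return out


def characteristic_polynomial(V: sp.Matrix) -> sp.Expr:
    return sp.expand((LAMBDA * sp.eye(V.shape[0]) - V).det())


def _principal_minors(V: sp.Matrix, order: int) -> list[sp.Expr]:
    from itertools import combinations

    n = V.shape[0]
    return [
        sp.expand(V[idx, idx].det())
        for idx in map(list, combinations(range(n), order))
    ]


def _has_negative_term(expr: sp.Expr) -> bool:
    expr = sp.expand(expr)
    terms = expr.as_ordered_terms() if not expr.is_number else [expr]
    return any(sp.Poly(t, *sorted(t.free_symbols, key=str)).coeffs()[0] < 0
               if t.free_symbols else t < 0 for t in terms)


def instability_conditions(
    V: sp.Matrix,
    heuristic: str = "mineurs",
    *,
    sum_mineurs: bool = True,
    max_mineur_search_stop: int = 5,
    n_currents: int | None = None,
) -> InstabilityConditionSet:
    """Candidate conditions on j under which V(J) admits positive eigenvalues.

    ``trace-determinant`` (2x2 only) emits the two unstable regions of the
    trace-determinant plane.  ``mineurs`` screens characteristic-polynomial
    coefficients ``c_{n-m} = (-1)^m * sum(m x m principal minors)`` and emits
    ``c_{n-m} < 0`` (canonically ``-c > 0``) for every order whose expansion
    contains a negative monomial; without negative monomials anywhere the
    network is reported stable.  ``characteristic-polynomial`` emits
    ``char(lam) < 0`` with a fresh variable ``lam > 0``, which certifies a
    real positive root when satisfiable.
    """
    n = V.shape[0]
    if n_currents is None:
        syms = set().union(*[e.free_symbols for e in V]) if any(V) else set()
        n_currents = max(
            (int(s.name[1:]) + 1 for s in syms if s.name.startswith("j")),
            default=0,
        )
    js = j_symbols(n_currents)
    positivity = [Constraint(j, "gt") for j in js]

    cond = InstabilityConditionSet(positivity=positivity, heuristic=heuristic)
    if heuristic == "trace-determinant":
        if n != 2:
            raise ValueError(
                f"trace-determinant requires a 2x2 matrix, got {n}x{n}"
            )
        trace = sp.expand(V.trace())
        det = sp.expand(V.det())
        cond.branches = [
            [Constraint(sp.expand(-det), "gt")],
            [Constraint(det, "gt"), Constraint(trace, "gt")],
        ]
    elif heuristic == "mineurs":
        for m in range(1, min(n, max_mineur_search_stop) + 1):
            minors = _principal_minors(V, m)
            candidates = [sum(minors)] if sum_mineurs else minors
            for cand in candidates:
                coeff = sp.expand((-1) ** m * cand)
                if _has_negative_term(coeff):
                    cond.branches.append([Constraint(sp.expand(-coeff), "gt")])
    elif heuristic == "characteristic-polynomial":
        char = characteristic_polynomial(V)
        cond.branches = [
            [Constraint(sp.expand(-char), "gt"), Constraint(LAMBDA, "gt")]
        ]
        cond.extra_symbols = [LAMBDA]
    else:
        raise ValueError(f"unknown instability heuristic {heuristic!r}")
    return cond


# ----------------------------------------------------------------------
# the full second-algorithm pipeline
# ----------------------------------------------------------------------

@dataclass
class SnaReport:
    network_name: str
    heuristic: str
    dual_pairs_in_ec: bool
    S_used: np.ndarray
    E: np.ndarray
    V: sp.Matrix
    conditions: InstabilityConditionSet
    equalities: list[Constraint]
    verdict: str
    samples: list = field(default_factory=list)
    false_positive_rate: float | None = None


def run_sna(
    network: ReactionNetwork,
    options: dict | None = None,
    rng: np.random.Generator | None = None,
) -> SnaReport:
    """Clarke's SNA with sampling of the instability restrictions."""
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
    if E.shape[1] == 0:
        return SnaReport(
            network.name, opts["instability-heuristic"], use_extended,
            S_used, E, sp.zeros(S.shape[0], S.shape[0]),
            InstabilityConditionSet(positivity=[]), [],
            verdict="network admits no steady-state flux",
        )

    V = current_matrix(S, E, K)
    heuristic = opts.get("instability-heuristic", "mineurs")
    if heuristic == "trace-determinant" and S.shape[0] != 2:
        heuristic = "mineurs"
    conditions = instability_conditions(
        V,
        heuristic,
        sum_mineurs=bool(opts.get("sum-mineurs", True)),
        max_mineur_search_stop=int(opts.get("max-mineur-search-stop", 5)),
    )
    equalities = (
        [] if use_extended else dual_pair_equalities(E, network.dual_pairs)
    )

    if conditions.stable:
        return SnaReport(
            network.name, heuristic, use_extended, S_used, E, V, conditions,
            equalities, verdict="stable: no negative terms, computation ends",
        )

    samples, fp_rate = _sampler.sample_condition_set(
        network, E, conditions, equalities, rng,
        n_samples=int(opts.get("num-samples", 10)),
        tries=int(opts.get("simplification-tries", 10000)),
    )
    verdict = (
        "no unstable steady states found" if not samples
        else f"sampled {len(samples)} candidate unstable steady states"
    )
    return SnaReport(
        network.name, heuristic, use_extended, S_used, E, V, conditions,
        equalities, verdict, samples, fp_rate,
    )
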