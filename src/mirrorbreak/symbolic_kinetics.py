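"""Exact symbolic kinetics: S, K, velocity vector, mass-action ODEs, Jacobian.

All coefficients are exact rationals (sympy ``Rational``); no floating point
enters any symbolic object.  Symbols follow the convention ``k{i}`` for rate
constants, ``x{s}`` for concentrations, ``j{c}`` for convex (current)
parameters and ``lam`` for the characteristic-polynomial variable.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import sympy as sp

from .network_model import ReactionNetwork

__all__ = [
    "LAMBDA", "k_symbols", "x_symbols", "j_symbols",
    "build_stoichiometric_matrix", "build_reaction_order_matrix",
    "velocity_vector", "ode_system", "jacobian",
    "merge_dual_rates", "canonical_str", "evaluate_jacobian",
]

LAMBDA = sp.Symbol("lam", real=True)


def k_symbols(n: int) -> list[sp.Symbol]:
    return [sp.Symbol(f"k{i}", positive=True) for i in range(n)]


def x_symbols(n: int) -> list[sp.Symbol]:
    return [sp.Symbol(f"x{i}", positive=True) for i in range(n)]


def j_symbols(n: int) -> list[sp.Symbol]:
    return [sp.Symbol(f"j{i}", positive=True) for i in range(n)]


def build_stoichiometric_matrix(network: ReactionNetwork) -> np.ndarray:
    """``S[s][r] = nu_plus - nu_minus``, an n_species x n_reactions int matrix."""
    S = np.zeros((network.n_species, network.n_reactions), dtype=np.int64)
    for rxn in network.reactions:
        for s, c in rxn.reactants:
            S[s, rxn.index] -= c
        for s, c in rxn.products:
            S[s, rxn.index] += c
    return S


def build_reaction_order_matrix(network: ReactionNetwork) -> np.ndarray:
    """``K[r][s] = nu_minus``: mass-action kinetic orders, reactions x species."""
    K = np.zeros((network.n_reactions, network.n_species), dtype=np.int64)
    for rxn in network.reactions:
        for s, c in rxn.reactants:
            K[rxn.index, s] = c
    return K


def velocity_vector(network: ReactionNetwork) -> list[sp.Expr]:
    """Mass-action velocities ``v_r = k_r * prod_s x_s**K[r][s]``."""
    K = build_reaction_order_matrix(network)
    ks = k_symbols(network.n_reactions)
    xs = x_symbols(network.n_species)
    out = []
    for r in range(network.n_reactions):
        term = ks[r]
        for s in range(network.n_species):
            if K[r, s]:
                term *= xs[s] ** int(K[r, s])
        out.append(term)
    return out


def ode_system(S: np.ndarray, v: Sequence[sp.Expr]) -> list[sp.Expr]:
    """``xdot = S . v``, expanded."""
    n, r = S.shape
    assert len(v) == r, "dimension mismatch between S and v"
    return [
        sp.expand(sum(int(S[s, i]) * v[i] for i in range(r)))
        for s in range(n)
    ]


def jacobian(ode: Sequence[sp.Expr], n_species: int) -> sp.Matrix:
    """Exact symbolic Jacobian d(xdot_s)/d(x_t)."""
    xs = x_symbols(n_species)
    return sp.Matrix(
        [[sp.expand(sp.diff(f, x)) for x in xs] for f in ode]
    )


def merge_dual_rates(network: ReactionNetwork, expr: sp.Expr | sp.Matrix):
    """Substitute every dual rate constant by its class representative."""
    rep = network.rate_representative()
    ks = k_symbols(network.n_reactions)
    subs = {ks[i]: ks[r] for i, r in rep.items() if i != r}
    return expr.subs(subs, simultaneous=True)


def evaluate_jacobian(
    network: ReactionNetwork,
    rate_constants: Sequence[float],
    concentrations: Sequence[float],
) -> np.ndarray:
    """Numeric Jacobian at a concrete state, from the exact factorisation.

    Uses ``J = S . diag(v) . K . diag(1/x)`` with ``v`` the mass-action
    velocities, which equals the symbolic Jacobian for mass-action kinetics.
    """
    S = build_stoichiometric_matrix(network).astype(float)
    K = build_reaction_order_matrix(network).astype(float)
    k = np.asarray(rate_constants, dtype=float)
    x = np.asarray(concentrations, dtype=float)
    v = k * np.prod(x[None, :] ** K, axis=1)
    return S @ (v[:, None] * K) @ np.diag(1.0 / x)


def canonical_str(expr: sp.Expr, gens: Sequence[sp.Symbol] | None = None) -> str:
    """Deterministic polynomial rendering in graded lexicographic order."""
    expr = sp.expand(expr)
    if expr.is_number:
        return str(expr)
    if gens is None:
        gens = sorted(expr.free_symbols, key=_symbol_key)
    poly = sp.Poly(expr, *gens)
    pieces = []
    for monom, coeff in sorted(
        poly.terms(), key=lambda t: (sum(t[0]), t[0]), reverse=True
    ):
        factors = []
        for g, e in zip(gens, monom):
            if e == 1:
                factors.append(str(g))
            elif e > 1:
                factors.append(f"{g}^{e}")
        body = "*".join(factors)
        if coeff == 1 and body:
            piece = body
        elif coeff == -1 and body:
            piece = f"-{body}"
        else:
            piece = f"{coeff}*{body}" if body else str(coeff)
        pieces.append(piece)
    out = pieces[0]
    for piece in pieces[1:]:
        out += f" - {piece[1:]}" if piece.startswith("-") else f" + {piece}"
    return out


def _symbol_key(s: sp.Symbol) -> tuple:
    name = s.name
    head = name.rstrip("0123456789")
    tail = name[len(head):]
    return (head, int(tail) if tail else -1)
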