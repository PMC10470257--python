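"""Algorithm 1: stability classification of 2-species networks on the
trace-determinant plane."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy as sp

from .network_model import ReactionNetwork
from .symbolic_kinetics import (
    build_stoichiometric_matrix,
    jacobian,
    k_symbols,
    merge_dual_rates,
    ode_system,
    velocity_vector,
    x_symbols,
)

__all__ = [
    "PlaneClassification", "symbolic_plane", "classify_point",
    "random_point_scan", "eigen_2x2", "run_trace_determinant",
]

#: relative threshold below which a float is treated as an exact zero
ZERO_TOL = 1e-12


@dataclass(frozen=True)
class PlaneClassification:
    trace: object
    determinant: object
    discriminant: object
    verdict: str


def symbolic_plane(J: sp.Matrix) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
    """Trace, determinant and discriminant of a 2x2 Jacobian, expanded."""
    if J.shape != (2, 2):
        raise ValueError(
            f"trace-determinant plane needs a 2x2 Jacobian; got {J.shape[0]}x{J.shape[1]} "
            "(only two species can be involved)"
        )
    trace = sp.expand(J[0, 0] + J[1, 1])
    det = sp.expand(J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0])
    disc = sp.expand(trace**2 - 4 * det)
    return trace, det, disc


def _sign(value) -> int:
    if isinstance(value, (sp.Rational, sp.Integer)) or getattr(value, "is_Rational", False):
        return 0 if value == 0 else (1 if value > 0 else -1)
    value = float(value)
    if abs(value) < ZERO_TOL:
        return 0
    return 1 if value > 0 else -1


def classify_point(trace, det, disc) -> str:
    """Verdict from the signs of (trace, det, disc).

    Negative determinant: unstable with saddle points.  Positive
    determinant with positive trace: unstable.  Positive determinant with
    negative trace: stable.  A zero anywhere is a bifurcation point.
    Rationals are tested exactly; floats within ``ZERO_TOL`` count as zero.
    """
    s_det, s_tr, s_disc = _sign(det), _sign(trace), _sign(disc)
    if 0 in (s_det, s_tr, s_disc):
        return "bifurcation"
    if s_det < 0:
        return "saddle-unstable"
    return "unstable" if s_tr > 0 else "stable"


def eigen_2x2(J: sp.Matrix) -> tuple[sp.Expr, sp.Expr]:
    """Eigenvalues of a 2x2 matrix via the quadratic formula."""
    trace, det, disc = symbolic_plane(J)
    root = sp.sqrt(disc)
    return sp.together((trace + root) / 2), sp.together((trace - root) / 2)


def random_point_scan(
    network: ReactionNetwork,
    n_samples: int,
    seed: int,
    concentration: float = 0.01,
) -> list[tuple[dict[str, float], str]]:
    """Assign pseudo-random rate constants and classify each point.

    Concentrations are fixed at 0.01 (arbitrary units); rate constants are
    drawn log-uniformly on [1e-3, 1e3] with dual pairs forced equal.
    """
    if network.n_species != 2:
        raise ValueError("random_point_scan requires exactly two species")
    rng = np.random.default_rng(seed)
    S = build_stoichiometric_matrix(network)
    J = jacobian(ode_system(S, velocity_vector(network)), 2)
    trace, det, disc = symbolic_plane(J)
    ks = k_symbols(network.n_reactions)
    xs = x_symbols(2)
    rep = network.rate_representative()

    out = []
    for _ in range(n_samples):
        draws = {
            i: float(np.exp(rng.uniform(np.log(1e-3), np.log(1e3))))
            for i in sorted(set(rep.values()))
        }
        assignment = {ks[i]: draws[rep[i]] for i in range(network.n_reactions)}
        assignment.update({xs[0]: concentration, xs[1]: concentration})
        t = float(trace.subs(assignment))
        d = float(det.subs(assignment))
        q = float(disc.subs(assignment))
        out.append(
            ({f"k{i}": assignment[ks[i]] for i in range(network.n_reactions)},
             classify_point(t, d, q))
        )
    return out


def save_scatter(points, network, symbolic, path: str) -> None:
    """Optional (trace, det) scatter of scanned points, written to a file.

    Needs matplotlib; raises ImportError otherwise.  No interactive window
    is ever opened.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    trace_e, det_e, _ = symbolic
    from .symbolic_kinetics import k_symbols, x_symbols

    ks = k_symbols(network.n_reactions)
    xs = x_symbols(2)
    ts, ds, colors = [], [], []
    palette = {"stable": "tab:blue", "unstable": "tab:red",
               "saddle-unstable": "tab:orange", "bifurcation": "tab:gray"}
    for assignment, verdict in points:
        subs = {ks[i]: assignment[f"k{i}"] for i in range(network.n_reactions)}
        subs.update({xs[0]: 0.01, xs[1]: 0.01})
        ts.append(float(trace_e.subs(subs)))
        ds.append(float(det_e.subs(subs)))
        colors.append(palette.get(verdict, "k"))
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ts, ds, c=colors, s=18)
    ax.axhline(0.0, lw=0.5, color="k")
    ax.axvline(0.0, lw=0.5, color="k")
    ax.set_xlabel("trace")
    ax.set_ylabel("determinant")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class TraceDeterminantReport:
    jacobian: sp.Matrix
    trace: sp.Expr
    determinant: sp.Expr
    discriminant: sp.Expr
    eigenvalues: tuple[sp.Expr, sp.Expr]
    points: list[tuple[dict[str, float], str]]


def run_trace_determinant(
    network: ReactionNetwork,
    options: dict | None = None,
    seed: int = 0,
) -> TraceDeterminantReport:
    opts = options or {}
    if network.n_species != 2:
        raise ValueError(
            f"trace-determinant plane refused: {network.n_species} species "
            "(only two species can be involved)"
        )
    S = build_stoichiometric_matrix(network)
    J = jacobian(ode_system(S, velocity_vector(network)), 2)
    if opts.get("2by2-jacobian", True):
        J_used = J
    else:
        J_used = merge_dual_rates(network, J)
    trace, det, disc = symbolic_plane(J_used)
    points = random_point_scan(network, int(opts.get("num-samples", 10)), seed)
    return TraceDeterminantReport(
        jacobian=J_used, trace=trace, determinant=det, discriminant=disc,
        eigenvalues=eigen_2x2(J_used), points=points,
    )
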