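"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from mirrorbreak import load_fixture


@pytest.fixture(scope="session")
def kn():
    return load_fixture("Kondepudi-Nelson")


@pytest.fixture(scope="session")
def replicator():
    return load_fixture("Replicator-Hochberg-Ribo")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# ----------------------------------------------------------------------
# independent oracle: extreme rays by support enumeration
# ----------------------------------------------------------------------

def _fraction_nullspace(rows: list[list[Fraction]], n: int) -> list[list[Fraction]]:
    """Exact nullspace basis of a matrix given as Fraction rows."""
    mat = [row[:] for row in rows]
    pivots = []
    r = 0
    for c in range(n):
        pivot = next((i for i in range(r, len(mat)) if mat[i][c] != 0), None)
        if pivot is None:
            continue
        mat[r], mat[pivot] = mat[pivot], mat[r]
        inv = mat[r][c]
        mat[r] = [v / inv for v in mat[r]]
        for i in range(len(mat)):
            if i != r and mat[i][c] != 0:
                f = mat[i][c]
                mat[i] = [a - f * b for a, b in zip(mat[i], mat[r])]
        pivots.append(c)
        r += 1
    free = [c for c in range(n) if c not in pivots]
    basis = []
    for fc in free:
        vec = [Fraction(0)] * n
        vec[fc] = Fraction(1)
        for i, pc in enumerate(pivots):
            vec[pc] = -mat[i][fc]
        basis.append(vec)
    return basis


def brute_force_extreme_rays(S_used: np.ndarray) -> set[tuple[int, ...]]:
    """Support-minimal nonnegative kernel vectors by support enumeration.

    For every candidate support (ascending size, supersets of found
    supports pruned) the equality system restricted to the support is
    solved exactly; one-dimensional strictly one-signed solutions are the
    extreme rays.  Exponential, usable up to ~14 reactions.
    """
    m, n = S_used.shape
    found: dict[frozenset, tuple[int, ...]] = {}
    for size in range(1, n + 1):
        for subset in combinations(range(n), size):
            sup = frozenset(subset)
            if any(other < sup or other == sup for other in found):
                continue
            rows = [[Fraction(int(S_used[i, j])) for j in subset] for i in range(m)]
            basis = _fraction_nullspace(rows, size)
            if len(basis) != 1:
                continue
            vec = basis[0]
            if any(v == 0 for v in vec):
                continue
            if all(v > 0 for v in vec) or all(v < 0 for v in vec):
                if vec[0] < 0:
                    vec = [-v for v in vec]
                full = [Fraction(0)] * n
                for j, v in zip(subset, vec):
                    full[j] = v
                denom = np.lcm.reduce([v.denominator for v in full])
                ints = [int(v * denom) for v in full]
                g = np.gcd.reduce([abs(i) for i in ints if i] or [1])
                found[sup] = tuple(i // g for i in ints)
    return set(found.values())


def columns_as_set(E: np.ndarray) -> set[tuple[int, ...]]:
    return {tuple(int(v) for v in E[:, c]) for c in range(E.shape[1])}


def match_column_permutation(E_ref: np.ndarray, E_mine: np.ndarray) -> list[int]:
    """perm[c] = index of E_ref's column c inside E_mine (exact match)."""
    mine = {tuple(int(v) for v in E_mine[:, c]): c for c in range(E_mine.shape[1])}
    perm = []
    for c in range(E_ref.shape[1]):
        key = tuple(int(v) for v in E_ref[:, c])
        assert key in mine, f"reference column {c} not found"
        perm.append(mine[key])
    return perm


def parse_digit_grid(rows: list[str]) -> np.ndarray:
    return np.array([[int(ch) for ch in row] for row in rows], dtype=np.int64)
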