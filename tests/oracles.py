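"""Independent brute-force oracles used to cross-check the LP/QP solvers.

These deliberately share no code with the package's solvers: FBA is checked
against exhaustive vertex enumeration of the flux polytope, and MOMA against
the analytic null-space (KKT) solution of the equality-constrained least
squares problem on instances whose box constraints are inactive.
"""

from __future__ import annotations

import itertools

import numpy as np


def feasible_vertices(S, lb, ub, tol=1e-9):
    """Enumerate the vertices of {v : S v = 0, lb <= v <= ub}.

    A vertex fixes n - rank(S) coordinates at a bound such that the remaining
    square system is nonsingular.  Only valid for small, fully bounded
    instances.
    """
    S = np.asarray(S, float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S)
    k = n - rank
    vertices = []
    for fixed_tuple in itertools.combinations(range(n), k):
        fixed = list(fixed_tuple)
        free = [j for j in range(n) if j not in fixed]
        S_free = S[:, free]
        if np.linalg.matrix_rank(S_free) < rank:
            continue
        for choice in itertools.product((0, 1), repeat=k):
            v = np.zeros(n)
            for j, c in zip(fixed, choice):
                v[j] = lb[j] if c == 0 else ub[j]
            rhs = -S[:, fixed] @ v[fixed]
            sol, residual, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
            v[free] = sol
            if np.abs(S @ v).max() > tol * (1 + np.abs(v).max()):
                continue
            if (v < lb - tol).any() or (v > ub + tol).any():
                continue
            vertices.append(v)
    return vertices


def fba_by_vertex_enumeration(S, lb, ub, c):
    """LP optimum max c·v over the flux polytope, by vertex enumeration."""
    vertices = feasible_vertices(S, lb, ub)
    if not vertices:
        return None
    values = [float(np.dot(c, v)) for v in vertices]
    return max(values)


def moma_by_nullspace(S, ref, fixed: dict[int, float]):
    """Analytic minimizer of ||v - ref||^2 s.t. S v = 0 and v_j = fixed[j].

    Exact only when no box constraint is active at the optimum; the caller
    must verify interiority.
    """
    S = np.asarray(S, float)
    n = S.shape[1]
    rows = [S]
    b = [np.zeros(S.shape[0])]
    for j, val in fixed.items():
        e = np.zeros(n)
        e[j] = 1.0
        rows.append(e.reshape(1, -1))
        b.append(np.array([val]))
    A = np.vstack(rows)
    b = np.concatenate(b)
    # v = ref - A^T (A A^T)^+ (A ref - b)
    lam = np.linalg.lstsq(A @ A.T, A @ ref - b, rcond=None)[0]
    return ref - A.T @ lam


def sample_nullspace_point(S, lb, ub, rng, shrink=0.8, x0=None):
    """A random feasible point: step from a feasible ``x0`` along the null
    space of ``S`` while staying inside the box (``x0`` defaults to 0, which
    must then itself be feasible)."""
    from scipy.linalg import null_space

    n = S.shape[1]
    x0 = np.zeros(n) if x0 is None else np.asarray(x0, float)
    N = null_space(S)
    if N.shape[1] == 0:
        return x0.copy()
    d = N @ rng.standard_normal(N.shape[1])
    # allowed step range [a_min, a_max] along d from x0
    a_max, a_min = np.inf, -np.inf
    for j in range(n):
        if d[j] > 1e-12:
            a_max = min(a_max, (ub[j] - x0[j]) / d[j])
            a_min = max(a_min, (lb[j] - x0[j]) / d[j])
        elif d[j] < -1e-12:
            a_max = min(a_max, (lb[j] - x0[j]) / d[j])
            a_min = max(a_min, (ub[j] - x0[j]) / d[j])
    if not np.isfinite(a_max):
        a_max = 1.0
    if not np.isfinite(a_min):
        a_min = -1.0
    # + 0.0 normalizes a possible -0.0, which numpy's uniform() rejects
    a_min, a_max = min(a_min, 0.0) + 0.0, max(a_max, 0.0) + 0.0
    return x0 + shrink * rng.uniform(a_min, a_max) * d


def random_toy_instance(rng, m=6, n=10, bound=10.0):
    """A random bounded stoichiometric instance with 0 feasible.

    Each reaction touches 1-3 metabolites with small integer coefficients;
    lower bounds are 0 or -bound (reversible), upper bounds positive, so the
    zero flux vector is always feasible and the polytope is bounded.
    """
    S = np.zeros((m, n))
    for j in range(n):
        touched = rng.choice(m, size=rng.integers(1, 4), replace=False)
        for i in touched:
            S[i, j] = rng.choice([-2.0, -1.0, 1.0, 2.0])
    lb = np.where(rng.random(n) < 0.5, -bound, 0.0)
    ub = np.full(n, bound)
    objective = int(rng.integers(0, n))
    return S, lb, ub, objective
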