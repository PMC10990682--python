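"""Brute-force vertex-enumeration oracle for tiny LPs.

The steady-state polytope {S·v = 0, lb ≤ v ≤ ub} is bounded (box bounds), so
any LP optimum is attained at a vertex.  Vertices are enumerated by fixing
each variable to its lower bound, its upper bound, or leaving it free, and
solving the equality system for the free variables — exponential, hence only
for models with ≤ ~7 reactions.  Completely independent of the solver used by
the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def _dense(model):
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for met, coeff in r.stoichiometry.items():
            S[met_index[met], j] = coeff
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    return S, lb, ub


def enumerate_vertices(model, tol: float = 1e-8) -> list[np.ndarray]:
    S, lb, ub = _dense(model)
    n = S.shape[1]
    vertices = []
    for assignment in itertools.product((0, 1, 2), repeat=n):
        free = [j for j in range(n) if assignment[j] == 0]
        v = np.array(
            [lb[j] if a == 1 else ub[j] if a == 2 else 0.0
             for j, a in enumerate(assignment)]
        )
        if free:
            Sf = S[:, free]
            if np.linalg.matrix_rank(Sf, tol=1e-10) < len(free):
                continue  # not a basic solution
            rhs = -S @ v
            x, *_ = np.linalg.lstsq(Sf, rhs, rcond=None)
            v[free] = x
        if np.linalg.norm(S @ v) > tol:
            continue
        if np.all(v >= lb - tol) and np.all(v <= ub + tol):
            vertices.append(np.clip(v, lb, ub))
    return vertices


def brute_force_fba(model, objective: str, direction: str = "max"):
    """(status, optimum) by vertex enumeration."""
    vertices = enumerate_vertices(model)
    if not vertices:
        return "infeasible", None
    j = model.reaction_ids.index(objective)
    values = [v[j] for v in vertices]
    return "optimal", (max(values) if direction == "max" else min(values))


def brute_force_fva(model, reaction_id: str):
    """(min, max) flux by vertex enumeration; None when infeasible."""
    vertices = enumerate_vertices(model)
    if not vertices:
        return None
    j = model.reaction_ids.index(reaction_id)
    values = [v[j] for v in vertices]
    return min(values), max(values)
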