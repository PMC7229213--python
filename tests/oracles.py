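"""Independent brute-force oracles for the LP/QP solvers.

These never call the package's solvers: LPs are solved by enumerating basic
feasible points (vertices), convex QPs by enumerating active sets of the
inequality constraints and solving the corresponding equality-constrained
KKT systems directly.  Both are exponential and only meant for networks
with a handful of reactions.
"""

from itertools import combinations

import numpy as np

from netgs._solvers import LinearSystem


def _rows(system: LinearSystem):
    """All inequality rows (A_ub plus finite bounds) as G x <= h."""
    n = system.n
    G, h = [], []
    if system.A_ub is not None:
        G.append(system.A_ub)
        h.append(system.b_ub)
    eye = np.eye(n)
    fin = np.isfinite(system.ub)
    G.append(eye[fin])
    h.append(system.ub[fin])
    fin = np.isfinite(system.lb)
    G.append(-eye[fin])
    h.append(-system.lb[fin])
    return np.vstack(G), np.concatenate(h)


def lp_vertex_oracle(c, system: LinearSystem, sense="max", tol=1e-7):
    """Optimal objective value by vertex enumeration."""
    n = system.n
    A_eq = system.A_eq if system.A_eq is not None else np.zeros((0, n))
    b_eq = system.b_eq if system.b_eq is not None else np.zeros(0)
    G, h = _rows(system)
    need = n - np.linalg.matrix_rank(A_eq) if A_eq.size else n
    best = None
    for combo in combinations(range(G.shape[0]), need):
        A = np.vstack([A_eq, G[list(combo)]])
        b = np.concatenate([b_eq, h[list(combo)]])
        if np.linalg.matrix_rank(A) < n:
            continue
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ x - b)) > tol:
            continue
        if np.max(G @ x - h, initial=0.0) > tol:
            continue
        if A_eq.size and np.max(np.abs(A_eq @ x - b_eq)) > tol:
            continue
        val = float(c @ x)
        if best is None or (val > best if sense == "max" else val < best):
            best = val
    return best


def qp_kkt_oracle(H, c, system: LinearSystem, tol=1e-8):
    """Unique minimizer of a strictly convex QP by active-set enumeration."""
    n = system.n
    H = np.diag(H) if np.ndim(H) == 1 else np.asarray(H, float)
    A_eq = system.A_eq if system.A_eq is not None else np.zeros((0, n))
    b_eq = system.b_eq if system.b_eq is not None else np.zeros(0)
    G, h = _rows(system)
    m = G.shape[0]
    free_dim = n - (np.linalg.matrix_rank(A_eq) if A_eq.size else 0)
    best_x, best_obj = None, np.inf
    for k in range(min(free_dim, m) + 1):
        for combo in combinations(range(m), k):
            A = np.vstack([A_eq, G[list(combo)]])
            b = np.concatenate([b_eq, h[list(combo)]])
            na = A.shape[0]
            M = np.zeros((n + na, n + na))
            M[:n, :n] = H
            M[:n, n:] = A.T
            M[n:, :n] = A
            rhs = np.concatenate([-c, b])
            try:
                sol = np.linalg.solve(M, rhs)
            except np.linalg.LinAlgError:
                continue
            x = sol[:n]
            lam = sol[n + A_eq.shape[0]:]
            if np.max(G @ x - h, initial=0.0) > tol:
                continue
            if len(lam) and np.min(lam) < -tol:
                continue
            obj = float(0.5 * x @ H @ x + c @ x)
            if obj < best_obj - 1e-12:
                best_obj, best_x = obj, x
    return best_x, best_obj


def random_full_support_network(rng):
    """A small random network whose reference FBA solution uses every reaction.

    Layout: uptake -> A, two parallel conversions A -> B with different
    yields and capacity caps forcing both to run, B -> biomass.  Between 4
    and 6 reactions, all with non-zero flux at the optimum.
    """
    from netgs.io import _build_model

    y2 = rng.uniform(0.5, 1.2)
    y1 = y2 + rng.uniform(0.1, 0.5)  # capped route 1 is strictly more efficient,
    cap = rng.uniform(2.0, 5.0)      # so at the optimum both routes carry flux
    uptake = rng.uniform(8.0, 15.0)
    bio_coeff = rng.uniform(0.5, 2.0)
    records = [
        {"id": "UP", "stoich": {"A": 1}, "lb": 0.0, "ub": uptake, "tag": ""},
        {"id": "C1", "stoich": {"A": -1, "B": round(y1, 3)}, "lb": 0.0, "ub": cap, "tag": ""},
        {"id": "C2", "stoich": {"A": -1, "B": round(y2, 3)}, "lb": 0.0, "ub": 1000.0, "tag": ""},
        {"id": "BIO", "stoich": {"B": -round(bio_coeff, 3)}, "lb": 0.0, "ub": 1000.0,
         "tag": "biomass"},
    ]
    mets = ["A", "B"]
    if rng.random() < 0.5:
        # an extra intermediate on the second route
        mets.append("D")
        records[2] = {"id": "C2", "stoich": {"A": -1, "D": 1.0}, "lb": 0.0, "ub": 1000.0,
                      "tag": ""}
        records.insert(3, {"id": "C3", "stoich": {"D": -1, "B": round(y2, 3)},
                           "lb": 0.0, "ub": 1000.0, "tag": ""})
    return _build_model(mets, records, model_id="oracle_net")
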