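"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the LP oracle
enumerates basic feasible points of the flux polytope by brute force, and
the component oracle is a plain union-find, independent of networkx.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_lp(S, lb, ub, c, sense="max"):
    """Brute-force the LP ``opt c.v s.t. S v = 0, lb <= v <= ub``.

    The feasible set is a bounded polyhedron, so if it is non-empty the
    optimum is attained at a vertex, i.e. a point where the free variables
    (not pinned at a bound) solve the equality system uniquely.  Enumerate
    every split of variables into free/pinned, every bound assignment of
    the pinned ones, and keep the best feasible solution.

    Returns (status, value) with status in {"optimal", "infeasible"}.
    """
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    n = S.shape[1]
    best = None
    for r in range(n + 1):
        for free in itertools.combinations(range(n), r):
            free = list(free)
            pinned = [j for j in range(n) if j not in free]
            Sf = S[:, free]
            if free and np.linalg.matrix_rank(Sf) < len(free):
                continue  # not a vertex basis; covered by a smaller split
            for assignment in itertools.product(*[(lb[j], ub[j]) for j in pinned]):
                v = np.empty(n)
                v[pinned] = assignment
                if free:
                    rhs = -S[:, pinned] @ np.asarray(assignment)
                    x, *_ = np.linalg.lstsq(Sf, rhs, rcond=None)
                    v[free] = x
                if np.max(np.abs(S @ v)) > 1e-8:
                    continue
                if np.any(v < lb - 1e-9) or np.any(v > ub + 1e-9):
                    continue
                value = float(c @ v)
                if best is None:
                    best = value
                elif sense == "max":
                    best = max(best, value)
                else:
                    best = min(best, value)
    if best is None:
        return "infeasible", 0.0
    return "optimal", best


class UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def component_count(participants, currency=frozenset()):
    """Number of connected components of the reaction/metabolite bipartite
    graph, counting only components containing a reaction."""
    uf = UnionFind()
    for rid, mets in participants.items():
        uf.find(("R", rid))
        for cid in mets:
            if cid not in currency:
                uf.union(("R", rid), ("M", cid))
    roots = {uf.find(("R", rid)) for rid in participants}
    return len(roots)
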