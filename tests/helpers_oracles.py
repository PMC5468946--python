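"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths: the FBA oracle
enumerates basic feasible solutions of the flux polytope, the GPR oracle
evaluates the boolean expression tree directly, and the dead-end oracle
re-derives producer/consumer sets straight from the definition.
"""

from itertools import combinations, product

import numpy as np


def fba_vertex_oracle(S, lb, ub, c, tol=1e-7):
    """Maximum of c·v over {S·v = 0, lb ≤ v ≤ ub} by vertex enumeration.

    Every vertex of the (bounded) flux polytope has at least
    n − rank(S) flux bounds active; enumerating all choices of that many
    variables fixed at a bound and solving the remaining square system
    visits every basic feasible solution.  Only valid for small n with
    finite bounds.
    """
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    k = n - rank
    best = None
    for fixed in combinations(range(n), k):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        if free and np.linalg.matrix_rank(A) < len(free):
            continue  # non-unique; the vertex shows up under another basis
        for vals in product(*[(lb[j], ub[j]) for j in fixed]):
            if not all(np.isfinite(v) for v in vals):
                continue
            b = -S[:, fixed] @ np.asarray(vals) if fixed else np.zeros(S.shape[0])
            if free:
                x_free, *_ = np.linalg.lstsq(A, b, rcond=None)
            else:
                x_free = np.zeros(0)
            v = np.zeros(n)
            v[list(fixed)] = vals
            v[free] = x_free
            if np.max(np.abs(S @ v), initial=0.0) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            val = float(c @ v)
            if best is None or val > best:
                best = val
    return best


def network_arrays(network):
    """(S, lb, ub) plus reaction-id order, straight off the dataclasses."""
    S, _, rxn_ids = network.stoichiometric_matrix()
    lb = np.array([r.lower_bound for r in network.reactions])
    ub = np.array([r.upper_bound for r in network.reactions])
    return S, lb, ub, rxn_ids


# ------------------------------------------------------------------
# boolean expression trees for GPR cross-checks
# ------------------------------------------------------------------

def random_bool_tree(rng, genes, depth=0):
    """Random and/or tree over the gene pool; returns (tree, text)."""
    if depth >= 3 or rng.random() < 0.4:
        g = str(rng.choice(genes))
        return ("gene", g), g
    op = "and" if rng.random() < 0.5 else "or"
    left, lt = random_bool_tree(rng, genes, depth + 1)
    right, rt = random_bool_tree(rng, genes, depth + 1)
    return (op, left, right), f"({lt} {op} {rt})"


def eval_bool_tree(tree, present):
    kind = tree[0]
    if kind == "gene":
        return tree[1] in present
    a = eval_bool_tree(tree[1], present)
    b = eval_bool_tree(tree[2], present)
    return (a and b) if kind == "and" else (a or b)


# ------------------------------------------------------------------
# dead-end oracle
# ------------------------------------------------------------------

def dead_end_oracle(network):
    """Single-pass dead-ends directly from the definition."""
    internal = {m.id for m in network.metabolites if not m.is_boundary}
    producers = {m: set() for m in internal}
    consumers = {m: set() for m in internal}
    for r in network.reactions:
        for mid, coef in r.stoichiometry.items():
            if mid not in internal or coef == 0:
                continue
            forward_makes = coef > 0
            if r.upper_bound > 0:
                (producers if forward_makes else consumers)[mid].add(r.id)
            if r.lower_bound < 0:
                (consumers if forward_makes else producers)[mid].add(r.id)
    return {
        m
        for m in internal
        if not (producers[m] and consumers[m])
    }
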