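"""Independent oracles used by the test suite.

These deliberately re-derive quantities by brute force (enumeration,
quadrature, exhaustive search) rather than calling the implementation under
test.
"""

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm

COMP = str.maketrans("ACGT", "TGCA")


def brute_force_canonical(k):
    """All canonical k-mers by direct enumeration of the 4^k k-mers."""
    return sorted({
        min(km, km.translate(COMP)[::-1])
        for km in ("".join(p) for p in itertools.product("ACGT", repeat=k))
    })


def kl_by_integration(m1, v1, m2, v2):
    """KL(N(m1,v1) || N(m2,v2)) by adaptive quadrature of p log(p/q)."""
    p = norm(m1, np.sqrt(v1))
    q = norm(m2, np.sqrt(v2))

    def integrand(x):
        return p.pdf(x) * (p.logpdf(x) - q.logpdf(x))

    lo = min(m1, m2) - 12 * max(np.sqrt(v1), np.sqrt(v2))
    hi = max(m1, m2) + 12 * max(np.sqrt(v1), np.sqrt(v2))
    val, _err = quad(integrand, lo, hi, limit=500, epsabs=1e-12, epsrel=1e-12)
    return val


def brute_force_sparse(node_ids, sim, max_edges):
    """Top-k-per-node edge selection, restated independently."""
    n = len(node_ids)
    kept = {}
    for i in range(n):
        ranked = sorted(
            (j for j in range(n) if j != i and sim[i, j] > 0),
            key=lambda j: (-sim[i, j], node_ids[j]),
        )
        for j in ranked[:max_edges]:
            kept[(min(i, j), max(i, j))] = sim[min(i, j), max(i, j)]
    return kept


def map_equation(nodes, edges, modules):
    """Two-level map equation codelength for a weighted undirected graph.

    ``edges`` maps (node, node) -> weight; ``modules`` is a list of node
    lists. Lower codelength = better partition.
    """
    strength = {v: 0.0 for v in nodes}
    total = 0.0
    for (a, b), w in edges.items():
        strength[a] += w
        strength[b] += w
        total += w
    p = {v: strength[v] / (2 * total) for v in nodes}
    member = {}
    for m, vs in enumerate(modules):
        for v in vs:
            member[v] = m
    q = np.zeros(len(modules))
    for (a, b), w in edges.items():
        if member[a] != member[b]:
            q[member[a]] += w / (2 * total)
            q[member[b]] += w / (2 * total)
    q_tot = q.sum()

    def plogp(x):
        return x * np.log2(x) if x > 0 else 0.0

    codelength = 0.0
    if q_tot > 0:
        codelength += q_tot * -sum(plogp(qm / q_tot) for qm in q if qm > 0)
    for m, vs in enumerate(modules):
        p_circ = q[m] + sum(p[v] for v in vs)
        if p_circ == 0:
            continue
        h = -sum(plogp(p[v] / p_circ) for v in vs) - plogp(q[m] / p_circ)
        codelength += p_circ * h
    return codelength


def finite_difference(f, x, eps=1e-6):
    """Central finite-difference gradient of scalar f with respect to x."""
    g = np.zeros_like(x)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f()
        flat[i] = orig - eps
        lo = f()
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g
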