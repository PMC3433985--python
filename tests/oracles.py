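"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by the most literal route available —
direct formula evaluation, exhaustive enumeration, brute-force search or
high-order numerics — sharing no code with the package implementation it
checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def tn93_direct(P1, P2, Q, gA, gC, gG, gT, gamma_shape=None):
    """Literal evaluation of the TN93 closed form (optionally gamma)."""
    gR, gY = gA + gG, gC + gT
    k1 = 2 * gA * gG / gR
    k2 = 2 * gT * gC / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1 - P1 / k1 - Q / (2 * gR)
    w2 = 1 - P2 / k2 - Q / (2 * gY)
    w3 = 1 - Q / (2 * gR * gY)
    if gamma_shape is None:
        f = lambda w: -math.log(w)
    else:
        a = gamma_shape
        f = lambda w: a * (w ** (-1 / a) - 1)
    return k1 * f(w1) + k2 * f(w2) + k3 * f(w3)


def fisher_exact_enumeration(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration of 2x2 tables."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x):
        return (
            Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))
        )

    p_obs = table_prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = table_prob(x)
        if p <= p_obs:
            total += p
    return float(total)


def amova_direct(d2, groups):
    """Direct evaluation of the two-level variance decomposition."""
    N = sum(len(g) for g in groups)
    P = len(groups)
    ssd_total = sum(
        d2[i][j] for i in range(N) for j in range(i + 1, N)
    ) / N
    ssd_within = 0.0
    for g in groups:
        g = list(g)
        ssd_within += sum(
            d2[g[i]][g[j]] for i in range(len(g)) for j in range(i + 1, len(g))
        ) / len(g)
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / (N - P)
    n_prime = (N - sum(len(g) ** 2 for g in groups) / N) / (P - 1)
    sigma_a = max((ssd_among / (P - 1) - sigma_w) / n_prime, 0.0)
    phi = sigma_a / (sigma_a + sigma_w) if sigma_a + sigma_w > 0 else float("nan")
    return ssd_among, ssd_within, sigma_a, sigma_w, phi


def amova_exhaustive_p(d2, sizes, phi_obs):
    """p as the fraction of all distinct assignments with phi >= observed."""
    n = sum(sizes)
    hits = total = 0
    for combo in itertools.combinations(range(n), sizes[0]):
        rest = [i for i in range(n) if i not in combo]
        # only two-group enumeration needed for the tests
        assert len(sizes) == 2
        phi = amova_direct(d2, [list(combo), rest])[4]
        total += 1
        if phi >= phi_obs - 1e-12:
            hits += 1
    return hits / total


def mannwhitney_enumeration(x, y):
    """Two-sided exact U-test p by enumerating raw group assignments."""
    x, y = list(map(float, x)), list(map(float, y))
    pooled = x + y
    n1 = len(x)

    def u_stat(sample1, sample2):
        u = 0.0
        for a in sample1:
            for b in sample2:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    mu = n1 * len(y) / 2
    u_obs = u_stat(x, y)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        s1 = [pooled[i] for i in combo]
        s2 = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(u_stat(s1, s2) - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
    return hits / total


def ward_brute_force(points):
    """Greedy Ward agglomeration by exhaustively minimising the ESS increase.

    Returns the sequence of merged partitions (each a frozenset of point
    indices) in merge order.
    """
    points = np.asarray(points, dtype=float)
    clusters = [frozenset([i]) for i in range(len(points))]
    merges = []

    def ess(cluster):
        sub = points[sorted(cluster)]
        return ((sub - sub.mean(axis=0)) ** 2).sum()

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                merged = clusters[i] | clusters[j]
                delta = ess(merged) - ess(clusters[i]) - ess(clusters[j])
                if best is None or delta < best[0] - 1e-12:
                    best = (delta, i, j, merged)
        _, i, j, merged = best
        merges.append(merged)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


def auc_all_pairs(scores, y):
    """AUC as the fraction of positive-negative pairs ranked correctly."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def firth_loglik_direct(beta, X, y):
    """Penalised binomial log-likelihood, written out independently."""
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    W = np.diag(p * (1 - p))
    info = X.T @ W @ X
    return ll + 0.5 * math.log(np.linalg.det(info))


def firth_fit_by_optimizer(X, y):
    """Maximise the penalised likelihood directly with a generic optimizer."""
    from scipy.optimize import minimize

    res = minimize(
        lambda b: -firth_loglik_direct(b, X, y),
        np.zeros(X.shape[1]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 50_000},
    )
    return res.x


def poisson_glmm_loglik_plain_gh(beta, sigma, y, X, group_index, n_nodes=201):
    """Marginal GLMM log-likelihood by *non*-adaptive high-order GH quadrature."""
    from scipy.special import gammaln, logsumexp

    gx, gw = np.polynomial.hermite.hermgauss(n_nodes)
    eta = X @ beta
    total = 0.0
    for g in np.unique(group_index):
        sel = group_index == g
        e, yy = eta[sel], y[sel]
        z = math.sqrt(2.0) * gx  # integrate against standard normal density
        f = (yy[:, None] * (e[:, None] + sigma * z[None, :])).sum(axis=0) - np.exp(
            e[:, None] + sigma * z[None, :]
        ).sum(axis=0)
        total += logsumexp(f + np.log(gw)) - 0.5 * math.log(math.pi)
        total -= gammaln(yy + 1).sum()
    return float(total)


def minimum_spanning_network_adjacency(step_matrix):
    """Brute-force MSN: for each level, link pairs in distinct components
    as of the previous level; return the set of linked index pairs."""
    steps = np.asarray(step_matrix)
    n = steps.shape[0]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edges = set()
    for level in sorted(set(steps[np.triu_indices(n, 1)])):
        if level == 0:
            continue
        snapshot = [find(i) for i in range(n)]
        new = []
        for i in range(n):
            for j in range(i + 1, n):
                if steps[i, j] == level and snapshot[i] != snapshot[j]:
                    edges.add((i, j))
                    new.append((i, j))
        for i, j in new:
            parent[find(i)] = find(j)
    return edges


def parsimony_probability_exact(steps, length):
    """Distinct-sites probability as an exact rational falling factorial."""
    num = Fraction(1)
    for i in range(steps):
        num *= Fraction(length - i, length)
    return float(num)


def normal_equations_fit(x, y):
    """OLS slope/intercept by solving the normal equations explicitly."""
    X = np.column_stack([np.ones(len(x)), x])
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, dtype=float))
    return beta[1], beta[0]
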