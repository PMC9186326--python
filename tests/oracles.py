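"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: probabilities
are assembled with scalar arithmetic and explicit loops, denominators by
exhaustive enumeration of capture histories, and shortest paths by
Floyd-Warshall over an explicitly constructed dense adjacency matrix.
"""

import itertools
import math

import numpy as np
from scipy.sparse.csgraph import floyd_warshall


def scalar_p(d, g0, sigma, u):
    """Effort-adjusted half-normal detection probability, scalar arithmetic."""
    q = g0 * math.exp(-(d * d) / (2.0 * sigma * sigma))
    return 1.0 - (1.0 - q) ** u


def _p_of(params, sex, cls, bk, d, u):
    g0 = 1.0 / (1.0 + math.exp(-(params.beta0
                                 + params.beta_male * (sex == "M")
                                 + params.beta_bk * bk)))
    sigma = math.exp(params.gamma0 + params.gamma_male * (sex == "M")
                     + params.gamma_h2 * (cls == 2))
    return scalar_p(d, g0, sigma, u)


def history_prob(omega_i, sex, cls, params, dists_x, usage):
    """Pr(full history | activity center x, class) with bk dynamics."""
    S, K = omega_i.shape
    pr = 1.0
    for k in range(K):
        seen = False
        for s in range(S):
            p = _p_of(params, sex, cls, int(seen), dists_x[k], usage[k, s])
            pr *= p if omega_i[s, k] else (1.0 - p)
            seen = seen or bool(omega_i[s, k])
    return pr


def pdot_enumeration(sex, cls, params, dists_x, usage, with_bk=False):
    """P(detected at least once) by summing over all non-null histories.

    ``with_bk=False`` freezes the learned response at 0 (naive animal), the
    form entering the conditional-likelihood denominator.
    """
    S, K = usage.shape[1], usage.shape[0]
    total = 0.0
    for bits in itertools.product([0, 1], repeat=S * K):
        omega = np.array(bits, dtype=np.uint8).reshape(S, K)
        if not omega.any():
            continue
        if with_bk:
            total += history_prob(omega, sex, cls, params, dists_x, usage)
        else:
            pr = 1.0
            for s in range(S):
                for k in range(K):
                    p = _p_of(params, sex, cls, 0, dists_x[k], usage[k, s])
                    pr *= p if omega[s, k] else (1.0 - p)
            total += pr
    return total


def oracle_negloglik(data, mesh, traps, params, spec, dmat):
    """Conditional negative log-likelihood by explicit summation."""
    A = mesh.cell_area_km2
    if spec.mixture:
        pi = 1.0 / (1.0 + math.exp(-params.logit_pi))
        classes = [(1, pi), (2, 1.0 - pi)]
    else:
        classes = [(1, 1.0)]
    nll = 0.0
    for i in range(data.n_individuals):
        sex = data.sex[i]
        num = 0.0
        den = 0.0
        for cls, w in classes:
            for xi in range(mesh.n_points):
                dists_x = dmat[xi]
                num += w * A * history_prob(data.omega[i], sex, cls, params,
                                            dists_x, traps.usage)
                den += w * A * pdot_enumeration(sex, cls, params, dists_x,
                                                traps.usage)
        nll -= math.log(num / den)
    return nll


def grid_moves(directions):
    queen = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1),
             (1, -1), (1, 0), (1, 1)]
    knight = [(-2, -1), (-2, 1), (-1, -2), (-1, 2),
              (1, -2), (1, 2), (2, -1), (2, 1)]
    return queen + (knight if directions == 16 else [])


def floyd_warshall_distances(cost_values, cellsize, directions=16, alpha2=0.0):
    """All-pairs least-cost distances from a dense adjacency matrix."""
    nr, nc = cost_values.shape
    n = nr * nc
    adj = np.full((n, n), np.inf)
    cost = np.exp(alpha2 * cost_values)
    for r in range(nr):
        for c in range(nc):
            for dr, dc in grid_moves(directions):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nr and 0 <= c2 < nc:
                    w = (cellsize * math.hypot(dr, dc)
                         * 0.5 * (cost[r, c] + cost[r2, c2]))
                    adj[r * nc + c, r2 * nc + c2] = w
    return floyd_warshall(adj)
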