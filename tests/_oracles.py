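"""Independent brute-force oracles used by the test suite.

Deliberately naive: explicit loops over the 256 site-patterns and the 16
internal-state pairs, `scipy.linalg.expm` for every transition matrix, and
midpoint quadrature for the continuous gamma — no code shared with the
implementation under test.
"""

import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

_SIDES = {"q1": ((0, 1), (2, 3)), "q2": ((0, 2), (1, 3)), "q3": ((0, 3), (1, 2))}


def gtr_generator(exchangeabilities, freqs):
    """Normalized GTR generator built element by element."""
    pi = np.asarray(freqs, float)
    s = np.zeros((4, 4))
    order = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for val, (i, j) in zip(exchangeabilities, order):
        s[i, j] = s[j, i] = val
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i != j:
                Q[i, j] = s[i, j] * pi[j]
        Q[i, i] = -sum(Q[i, j] for j in range(4) if j != i)
    mu = -sum(pi[i] * Q[i, i] for i in range(4))
    return Q / mu


def site_pattern_probs(topology, branch_lengths, exchangeabilities, freqs,
                       rates, p_inv):
    """Pattern probabilities via the explicit double sum over internal states,
    averaging over the supplied rate multipliers (equal weights)."""
    Q = gtr_generator(exchangeabilities, freqs)
    pi = np.asarray(freqs, float)
    (l1, l2), (r1, r2) = _SIDES[topology]
    bl = branch_lengths
    probs = np.zeros(256)
    for code in range(256):
        s = [code // 64 % 4, code // 16 % 4, code // 4 % 4, code % 4]
        p_var = 0.0
        for r in rates:
            P = [expm(Q * bl[i] * r) for i in range(4)]
            Pi = expm(Q * bl[4] * r)
            tot = 0.0
            for x in range(4):
                for y in range(4):
                    tot += (pi[x] * P[l1][x, s[l1]] * P[l2][x, s[l2]]
                            * Pi[x, y] * P[r1][y, s[r1]] * P[r2][y, s[r2]])
            p_var += tot
        p_var /= len(rates)
        p = (1.0 - p_inv) * p_var
        if s[0] == s[1] == s[2] == s[3]:
            p += p_inv * pi[s[0]]
        probs[code] = p
    return probs


def continuous_gamma_midpoint_rates(alpha, n_points):
    """Midpoints of equal-probability slices of Gamma(alpha, mean 1), a
    quadrature for the continuous rate distribution."""
    q = (np.arange(n_points) + 0.5) / n_points
    return gamma_dist.ppf(q, a=alpha, scale=1.0 / alpha)
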