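"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's vectorized implementations:
the aligner oracle is a plain-Python cellwise Smith-Waterman, the
correlation oracle is the textbook two-pass formula evaluated per pair,
and the t-distribution tail is obtained by numerical integration of the
density written from its gamma-function definition.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad

MATCH, MISMATCH, GAP = 1, -1, -2


def sw_align_oracle(probe: str, target: str):
    """Cellwise local alignment; returns (score, n_matches).

    Uses the same published tie-break convention as the implementation
    (best score at the lowest target end then probe end; traceback
    prefers diagonal, then probe-gap, then target-gap) but shares no
    code with it.
    """
    p, t = probe.upper(), target.upper()
    m, n = len(p), len(t)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        row = H[i]
        prev = H[i - 1]
        for j in range(1, n + 1):
            s = MATCH if (p[i - 1] == t[j - 1] and p[i - 1] != "N") else MISMATCH
            v = max(0, prev[j - 1] + s, prev[j] + GAP, row[j - 1] + GAP)
            row[j] = v
    for j in range(n + 1):  # scan target-major for the tie-break
        for i in range(m + 1):
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best <= 0:
        return 0, 0
    i, j, matches = bi, bj, 0
    while i > 0 and j > 0 and H[i][j] > 0:
        s = MATCH if (p[i - 1] == t[j - 1] and p[i - 1] != "N") else MISMATCH
        if H[i][j] == H[i - 1][j - 1] + s:
            if s == MATCH:
                matches += 1
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + GAP:
            i -= 1
        else:
            j -= 1
    return best, matches


def pearson_two_pass(x, y) -> float:
    """Textbook two-pass sample correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def t_sf_oracle(t_value: float, df: int) -> float:
    """Upper-tail probability of Student's t by numerical integration."""
    c = math.exp(math.lgamma((df + 1) / 2.0) - math.lgamma(df / 2.0)) \
        / math.sqrt(df * math.pi)

    def pdf(x):
        return c * (1.0 + x * x / df) ** (-(df + 1) / 2.0)

    tail, _ = quad(pdf, abs(t_value), np.inf)
    return tail


def pearson_pvalue_oracle(r: float, n: int) -> float:
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return min(1.0, 2.0 * t_sf_oracle(t, n - 2))
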