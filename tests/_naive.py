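"""Deliberately naive reference implementations used as independent oracles.

Pure Python, sorting-based, no vectorization — transcribed step by step from
the textbook recipe so they share no code path with the package.
"""

import math
from statistics import median


def naive_bend_scale(x, beta, rule="round"):
    n = len(x)
    m = median(x)
    w = sorted(abs(v - m) for v in x)
    if rule == "round":
        k = math.floor((1.0 - beta) * n + 0.5)
    else:
        k = math.floor((1.0 - beta) * n)
    k = min(max(k, 1), n)
    return w[k - 1]


def naive_pb_location(x, beta, rule="round"):
    n = len(x)
    m = median(x)
    omega = naive_bend_scale(x, beta, rule)
    if omega == 0:
        raise ZeroDivisionError("degenerate bend scale")
    psi = [(v - m) / omega for v in x]
    i1 = sum(1 for p in psi if p < -1)
    i2 = sum(1 for p in psi if p > 1)
    core = sum(v for v, p in zip(x, psi) if -1 <= p <= 1)
    return (core + omega * (i2 - i1)) / (n - i1 - i2)


def naive_pb_correlation(x, y, beta, rule="round"):
    ox = naive_bend_scale(x, beta, rule)
    oy = naive_bend_scale(y, beta, rule)
    if ox == 0 or oy == 0:
        raise ZeroDivisionError("degenerate bend scale")
    lx = naive_pb_location(x, beta, rule)
    ly = naive_pb_location(y, beta, rule)
    a = [min(1.0, max(-1.0, (v - lx) / ox)) for v in x]
    b = [min(1.0, max(-1.0, (v - ly) / oy)) for v in y]
    num = sum(ai * bi for ai, bi in zip(a, b))
    den = math.sqrt(sum(ai * ai for ai in a) * sum(bi * bi for bi in b))
    if den == 0:
        raise ZeroDivisionError("degenerate score norm")
    return num / den


def naive_ols(rows_x, y):
    """Least squares by explicitly solving the normal equations (3x3)."""
    import numpy as np

    X = np.asarray(rows_x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)
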