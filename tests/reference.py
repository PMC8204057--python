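"""Naive double-loop reference implementations used as independent oracles.

These follow the estimator definitions literally, one pair at a time, with
no vectorization or shared distance work, so they are an implementation-
independent check on the optimized estimators.
"""

from __future__ import annotations

import math

import numpy as np


def apen_naive(x, m: int, r_factor: float) -> float:
    x = np.asarray(x, dtype=float)
    N = len(x)
    r = r_factor * x.std()

    def phi(mm: int) -> float:
        n = N - mm + 1
        vecs = [x[i : i + mm] for i in range(n)]
        total = 0.0
        for i in range(n):
            count = 0
            for j in range(n):  # self-match j == i included
                if np.max(np.abs(vecs[i] - vecs[j])) <= r:
                    count += 1
            total += math.log(count / n)
        return total / n

    return phi(m) - phi(m + 1)


def sampen_naive(x, m: int, r_factor: float) -> float:
    x = np.asarray(x, dtype=float)
    N = len(x)
    r = r_factor * x.std()
    n = N - m

    def matches(mm: int) -> int:
        vecs = [x[i : i + mm] for i in range(n)]
        count = 0
        for i in range(n):
            for j in range(i + 1, n):
                if np.max(np.abs(vecs[i] - vecs[j])) <= r:
                    count += 1
        return count

    b = matches(m)
    a = matches(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return math.log(b / a)


def fuzzyen_naive(x, m: int, r_factor: float, n_exp: float) -> float:
    x = np.asarray(x, dtype=float)
    x = x / x.std()  # distances in SD units; membership amplitude-invariant
    N = len(x)
    r = r_factor
    nt = N - m

    def phi(mm: int) -> float:
        vecs = [x[i : i + mm] - np.mean(x[i : i + mm]) for i in range(nt)]
        total = 0.0
        for i in range(nt):
            s = 0.0
            for j in range(nt):
                if j == i:
                    continue
                d = np.max(np.abs(vecs[i] - vecs[j]))
                s += math.exp(-(d**n_exp) / r)
            total += s / (nt - 1)
        return total / nt

    return math.log(phi(m)) - math.log(phi(m + 1))


def trapezoid_naive(values, scales) -> float:
    """Independent trapezoid sum over unit-ordered scale points."""
    area = 0.0
    for k in range(len(values) - 1):
        area += 0.5 * (values[k] + values[k + 1]) * (scales[k + 1] - scales[k])
    return area
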