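"""Independent brute-force oracles for the numerical operations.

Each function here re-derives a quantity from its definition by the
most literal route available (direct summation, double loops,
exhaustive enumeration), deliberately sharing no code with the
package implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def dft_coef_oracle(x, k: int) -> complex:
    """Direct O(N) summation of one DFT coefficient."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    return complex(
        sum(x[t] * np.exp(-2j * np.pi * k * t / n) for t in range(n))
    )


def apen_oracle(x, m: int, r: float) -> float:
    """Naive double-loop ApEn with Chebyshev distance, self-matches included."""
    x = list(map(float, x))
    n = len(x)

    def phi(mm):
        templates = [x[i : i + mm] for i in range(n - mm + 1)]
        k = len(templates)
        total = 0.0
        for a in templates:
            c = 0
            for b in templates:
                if max(abs(u - v) for u, v in zip(a, b)) <= r:
                    c += 1
            total += math.log(c / k)
        return total / k

    return phi(m) - phi(m + 1)


def pe_oracle(x, order: int, delay: int) -> float:
    """Exhaustive ordinal-pattern counting; ties by order of appearance."""
    x = list(map(float, x))
    counts: dict[tuple, int] = {}
    n_win = len(x) - (order - 1) * delay
    for i in range(n_win):
        w = [x[i + j * delay] for j in range(order)]
        # stable ranks: position of each index in the stable sort order
        pattern = tuple(sorted(range(order), key=lambda j: (w[j], j)))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    h = -sum((c / total) * math.log(c / total) for c in counts.values())
    return h / math.log(math.factorial(order))


def lz76_oracle(symbols) -> int:
    """LZ76 phrase count by the substring definition.

    Extend the current phrase while it (minus nothing) occurs as a
    substring of everything before its last character; a phrase ends
    at the first character that breaks reproducibility.
    """
    s = "".join(str(int(v)) for v in symbols)
    n = len(s)
    if n == 0:
        return 0
    c = 0
    i = 0
    while i < n:
        j = i + 1
        # grow phrase while s[i:j] occurs in s[:j-1]
        while j <= n and s[i:j] in s[: j - 1]:
            j += 1
        c += 1
        i = j
    return c


def tw_oracle(t, excess) -> float:
    """Per-interval trapezoid loop over the clamped excess."""
    total = 0.0
    for k in range(len(t) - 1):
        a = max(0.0, excess[k])
        b = max(0.0, excess[k + 1])
        total += 0.5 * (a + b) * (t[k + 1] - t[k])
    return total


def arv_oracle(t, m) -> float:
    T = t[-1] - t[0]
    return sum(
        (t[k + 1] - t[k]) * abs(m[k + 1] - m[k]) for k in range(len(m) - 1)
    ) / T


def arvs_oracle(t, m) -> float:
    T = t[-1] - t[0]
    return sum(
        (m[k + 1] - m[k]) ** 2 / (t[k + 1] - t[k]) for k in range(len(m) - 1)
    ) / T


def ols_oracle(xs, ys):
    """Slope/intercept/slope-stderr by the normal equations."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    n = len(xs)
    xbar, ybar = xs.mean(), ys.mean()
    sxx = ((xs - xbar) ** 2).sum()
    slope = ((xs - xbar) * (ys - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    resid = ys - (intercept + slope * xs)
    if n > 2:
        se = math.sqrt((resid**2).sum() / (n - 2) / sxx)
    else:
        se = 0.0
    return slope, intercept, se


def conv_same_oracle(x, kernel) -> np.ndarray:
    """Direct O(N*K) 'same'-mode convolution."""
    x = np.asarray(x, float)
    k = np.asarray(kernel, float)
    full = np.zeros(len(x) + len(k) - 1)
    for i in range(len(x)):
        for j in range(len(k)):
            full[i + j] += x[i] * k[j]
    start = (len(k) - 1) // 2
    return full[start : start + len(x)]


def auc_pair_oracle(scores, labels) -> float:
    """Concordant-pair fraction with ties counted 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


# ------------------------------------------------- exhaustive tree Shapley

def _tree_expectation(tree, x, subset) -> float:
    """E[f(x_S, X_notS)] by cover-weighted descent (path-dependent)."""

    def rec(node):
        if tree["children_left"][node] < 0:
            return tree["values"][node]
        f = tree["features"][node]
        l, r = tree["children_left"][node], tree["children_right"][node]
        if f in subset:
            nxt = l if x[f] <= tree["thresholds"][node] else r
            return rec(nxt)
        wl = tree["cover"][l] / tree["cover"][node]
        return wl * rec(l) + (1 - wl) * rec(r)

    return rec(0)


def shapley_tree_oracle(tree, x, n_features: int) -> np.ndarray:
    """Exact Shapley values by enumeration over all feature subsets."""
    phi = np.zeros(n_features)
    players = list(range(n_features))
    for i in players:
        others = [j for j in players if j != i]
        for size in range(len(others) + 1):
            for subset in itertools.combinations(others, size):
                s = len(subset)
                w = (
                    math.factorial(s)
                    * math.factorial(n_features - s - 1)
                    / math.factorial(n_features)
                )
                gain = _tree_expectation(
                    tree, x, set(subset) | {i}
                ) - _tree_expectation(tree, x, set(subset))
                phi[i] += w * gain
    return phi
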