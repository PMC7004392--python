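"""Independent brute-force oracles used by the test suite.

Each oracle evaluates its statistic by direct definition (enumeration,
closed form, or naive loops) without touching the package's optimised code
paths, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def entropy_oracle(window: str) -> float:
    """Direct evaluation of SE = -sum (n_i/L) log2(n_i/L)."""
    L = len(window)
    return -sum(
        (n / L) * math.log2(n / L) for n in Counter(window).values()
    ) + 0.0


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Tables sharing the observed margins are enumerated; those whose point
    probability does not exceed the observed one (exact integer comparison,
    so ties are exact) contribute.  All arithmetic on integers until the
    final division.
    """
    N, K, n = a + b + c + d, a + c, a + b
    if min(a + b, c + d, a + c, b + d) == 0:
        return 1.0
    w_obs = math.comb(K, a) * math.comb(N - K, n - a)
    total = math.comb(N, n)
    acc = 0
    for k in range(max(0, n - (N - K)), min(n, K) + 1):
        w = math.comb(K, k) * math.comb(N - K, n - k)
        if w <= w_obs:
            acc += w
    return min(acc / total, 1.0)


def holm_sidak_oracle(p_values) -> np.ndarray:
    """Closed-form step-down Sidak: adj_(i) = max_{j<=i} 1-(1-p_(j))^(m-j+1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        step = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, step)
        adjusted[idx] = min(running, 1.0)
    return adjusted


def ols_oracle(x, y) -> tuple[float, float, float, np.ndarray]:
    """Normal-equation OLS: slope, intercept, Pearson r, residuals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - (intercept + slope * x)
    r = (n * sxy - sx * sy) / math.sqrt(
        (n * sxx - sx * sx) * (n * (y * y).sum() - sy * sy)
    )
    return slope, intercept, r, resid


def naive_bin_profile(chains, amino_acid: str, w: int, cmap):
    """Direct-loop re-implementation of composition-binned mean profiles.

    Returns (n_windows, sums) keyed by residue count k; sums are per-category
    fraction totals, accumulated window by window with python loops.
    """
    from lcdstruct.core import AA_INDEX

    n_cat = cmap.n_categories
    n = {k: 0 for k in range(w + 1)}
    sums = {k: np.zeros(n_cat) for k in range(w + 1)}
    for chain in chains:
        cat = cmap.residue_categories(chain)
        for start in range(len(chain) - w + 1):
            window = chain.sequence[start : start + w]
            if "X" in window:
                continue
            k = window.count(amino_acid)
            frac = np.zeros(n_cat)
            for ci in cat[start : start + w]:
                frac[ci] += 1.0 / w
            n[k] += 1
            sums[k] += frac
    return n, sums
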