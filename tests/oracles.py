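"""Independent oracles used only by the test suite.

These deliberately avoid the package's code paths: the ML oracle minimizes
the discrepancy by naive grid refinement, and the ANOVA oracle computes
intraclass correlations from explicitly looped sums of squares.
"""

from __future__ import annotations

import math

import numpy as np


def fml(S: np.ndarray, sigma: np.ndarray) -> float:
    det_sigma = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] * sigma[1, 0]
    det_s = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
    if det_sigma <= 0 or det_s <= 0:
        return math.inf
    inv = np.array([[sigma[1, 1], -sigma[0, 1]], [-sigma[1, 0], sigma[0, 0]]]) / det_sigma
    return math.log(det_sigma) + float((S * inv.T).sum()) - math.log(det_s) - 2.0


def grid_search_constrained(S: np.ndarray, refinements: int = 8) -> tuple[float, float]:
    """Brute-force minimizer of F_ML for the equal-error model over (b, e)."""
    smax = max(S[0, 0], S[1, 1])
    b_lo, b_hi = -smax, 2 * smax
    e_lo, e_hi = 1e-9, 3 * smax
    best = (math.inf, 0.0, 0.0)
    for _ in range(refinements):
        bs = np.linspace(b_lo, b_hi, 61)
        es = np.linspace(e_lo, e_hi, 61)
        for b in bs:
            for e in es:
                val = fml(S, np.array([[b + e, b], [b, b + e]]))
                if val < best[0]:
                    best = (val, b, e)
        db = (b_hi - b_lo) / 60
        de = (e_hi - e_lo) / 60
        b_lo, b_hi = best[1] - 2 * db, best[1] + 2 * db
        e_lo, e_hi = max(1e-12, best[2] - 2 * de), best[2] + 2 * de
    return best[1], best[2]


def anova_icc(matrix: np.ndarray) -> tuple[float, float]:
    """Brute-force two-way ANOVA mean squares -> (ICC(2,1), ICC(3,1))."""
    x = np.asarray(matrix, dtype=float)
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    bms = k * sum((r - grand) ** 2 for r in row) / (n - 1)
    jms = n * sum((c - grand) ** 2 for c in col) / (k - 1)
    ss_err = sum(
        (x[i, j] - row[i] - col[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    ems = ss_err / ((n - 1) * (k - 1))
    icc31 = (bms - ems) / (bms + (k - 1) * ems)
    icc21 = (bms - ems) / (bms + (k - 1) * ems + k * (jms - ems) / n)
    return icc21, icc31


def baseline_chisq(S: np.ndarray, n: int) -> float:
    """Closed-form independence-model chi-square for a bivariate normal."""
    r2 = S[0, 1] ** 2 / (S[0, 0] * S[1, 1])
    return -(n - 1) * math.log(1 - r2)


def random_psd(rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    a = rng.normal(size=(2, 2)) * scale
    S = a @ a.T + 0.05 * scale**2 * np.eye(2)
    return S
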