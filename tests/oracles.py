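"""Independent brute-force oracles used to check the implementation.

Each oracle is deliberately naive (double loops, full enumeration, textbook
formulas) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def naive_grs(dosages: np.ndarray, sample_ids, marker_ids,
              weights: dict[str, float]) -> np.ndarray:
    """Double-loop weighted allele count, one score per sample."""
    out = np.zeros(len(sample_ids))
    for i in range(len(sample_ids)):
        total = 0.0
        for j, m in enumerate(marker_ids):
            if m in weights:
                total += weights[m] * dosages[i, j]
        out[i] = total
    return out


def hwe_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p by full enumeration of the conditional distribution.

    Probabilities are computed with exact fractions (math.comb) so the
    oracle carries no floating-point cancellation of its own.
    """
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    if n_A == 0 or n_a == 0:
        return 1.0
    rare = min(n_A, n_a)
    weights = {}
    for het in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - het) // 2
        hom_common = (max(n_A, n_a) - het) // 2
        # multinomial count of genotype arrangements x 2^het phase choices
        weights[het] = (math.comb(n, hom_rare) * math.comb(n - hom_rare, het)
                        * (2 ** het))
    total = sum(weights.values())
    obs = weights[n_Aa]
    return min(1.0, sum(w for w in weights.values() if w <= obs) / total)


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, int, int]:
    """Textbook sums-of-squares one-way ANOVA (F, df1, df2)."""
    k = len(groups)
    alldata = np.concatenate(groups)
    grand = alldata.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, len(alldata) - k
    return (ssb / df1) / (ssw / df2), df1, df2


def ols_normal_equations(X: np.ndarray, y: np.ndarray
                         ) -> tuple[np.ndarray, float]:
    """beta = (X'X)^-1 X'y and unadjusted R², computed the long way."""
    beta = np.linalg.inv(X.T @ X) @ (X.T @ y)
    resid = y - X @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return beta, 1.0 - (resid @ resid) / tss


def logistic_newton(X: np.ndarray, y: np.ndarray, n_iter: int = 100
                    ) -> tuple[np.ndarray, float]:
    """Two-parameter logistic MLE by explicit Newton iteration."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        grad = X.T @ (y - p)
        hess = X.T @ (X * W[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-12:
            break
    eta = X @ beta
    ll = float((y * eta - np.log1p(np.exp(eta))).sum())
    return beta, ll


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Textbook Pearson correlation."""
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am ** 2).sum() * (bm ** 2).sum()))
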