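"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity from its definition with simple
loops, staying deliberately independent of the code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def midranks(x) -> list[float]:
    """Average ranks with ties -> mean rank, by explicit enumeration."""
    x = list(x)
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def spearman_oracle(x, y) -> tuple[float, float]:
    """Spearman rho as Pearson on midranks; p via the t approximation."""
    from scipy.stats import t as tdist

    rho = pearson(midranks(x), midranks(y))
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return rho, 2.0 * tdist.sf(abs(t), n - 2)


def spearman_sum_d2(x, y) -> float:
    """Tie-free closed form 1 - 6*sum(d^2)/(n(n^2-1))."""
    rx = midranks(x)
    ry = midranks(y)
    n = len(x)
    d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def size_factors_oracle(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios per its definition, with explicit loops."""
    n_mirna, n_sample = counts.shape
    ref_rows = [i for i in range(n_mirna) if all(counts[i, j] > 0 for j in range(n_sample))]
    geo = {}
    for i in ref_rows:
        geo[i] = math.exp(sum(math.log(counts[i, j]) for j in range(n_sample)) / n_sample)
    sf = []
    for j in range(n_sample):
        ratios = sorted(counts[i, j] / geo[i] for i in ref_rows)
        m = len(ratios)
        med = ratios[m // 2] if m % 2 else 0.5 * (ratios[m // 2 - 1] + ratios[m // 2])
        sf.append(med)
    return np.array(sf)


def bh_oracle(p) -> np.ndarray:
    """Step-up Benjamini–Hochberg with explicit monotonicity pass."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return np.array(adj)


def gene_score_oracle(de_rows, target_rows) -> dict[str, float]:
    """Per-gene signed -log10(p) aggregation by dictionary loops.

    de_rows: iterable of (mirna_id, log2fc, adjusted_p);
    target_rows: iterable of (mirna_id, gene_id).
    """
    weight = {}
    for mirna, fc, p in de_rows:
        sign = 1.0 if fc > 0 else (-1.0 if fc < 0 else 0.0)
        weight[mirna] = -sign * (-math.log10(p))
    scores: dict[str, float] = {}
    for mirna, gene in target_rows:
        if mirna in weight:
            scores[gene] = scores.get(gene, 0.0) + weight[mirna]
    return scores


def logistic_irls_oracle(y: np.ndarray, x: np.ndarray, tol=1e-12, maxiter=200):
    """Unpenalized logistic IRLS: returns (intercept, slope, slope_se, wald_p)."""
    from scipy.stats import norm

    X = np.column_stack([np.ones_like(x, dtype=float), np.asarray(x, dtype=float)])
    beta = np.zeros(2)
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = (X * W[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1 - mu)
    cov = np.linalg.inv((X * W[:, None]).T @ X)
    se = math.sqrt(cov[1, 1])
    z = beta[1] / se
    return beta[0], beta[1], se, 2.0 * norm.sf(abs(z))


def chi2_2x2_oracle(a, b, c, d, correction=True) -> float:
    """Pearson chi-square statistic for a 2x2 table (Yates-corrected)."""
    n = a + b + c + d
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    stat = 0.0
    for obs, r, cc in ((a, row1, col1), (b, row1, col2), (c, row2, col1), (d, row2, col2)):
        exp = r * cc / n
        dev = abs(obs - exp)
        if correction:
            dev = max(0.0, dev - 0.5)
        stat += dev * dev / exp
    return stat


def trend_oracle(values) -> str:
    """Strict-chain classification by exhaustive pairwise comparison."""
    v = [abs(float(a)) for a in values]
    inc = all(v[i] < v[j] for i in range(len(v)) for j in range(i + 1, len(v)))
    dec = all(v[i] > v[j] for i in range(len(v)) for j in range(i + 1, len(v)))
    if inc:
        return "increasing"
    if dec:
        return "decreasing"
    return "none"


def median_split_oracle(values) -> list[str]:
    """Sort-based median; strictly-above -> high, else low."""
    v = sorted(values)
    n = len(v)
    med = v[n // 2] if n % 2 else 0.5 * (v[n // 2 - 1] + v[n // 2])
    return ["high" if x > med else "low" for x in values]
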