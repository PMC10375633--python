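"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (pure-python
loops, explicit formulas) and must stay independent of the package's
implementation paths.
"""

from __future__ import annotations

import numpy as np


def midranks(x) -> list[float]:
    """Average ranks computed by explicit counting (1-based)."""
    x = list(x)
    out = []
    for xi in x:
        less = sum(1 for xj in x if xj < xi)
        equal = sum(1 for xj in x if xj == xi)
        # ranks occupied by the tie group: less+1 .. less+equal
        out.append(less + (equal + 1) / 2.0)
    return out


def spearman_oracle(a, b) -> float:
    """Spearman rho as the Pearson correlation of mid-ranks, explicit sums."""
    ra, rb = midranks(a), midranks(b)
    n = len(ra)
    ma = sum(ra) / n
    mb = sum(rb) / n
    num = sum((ra[i] - ma) * (rb[i] - mb) for i in range(n))
    da = sum((ra[i] - ma) ** 2 for i in range(n)) ** 0.5
    db = sum((rb[i] - mb) ** 2 for i in range(n)) ** 0.5
    return num / (da * db)


def pbsi_oracle(profiles) -> list[float]:
    """Per-subject mean pairwise Spearman, brute force."""
    n = len(profiles)
    out = []
    for i in range(n):
        rhos = [spearman_oracle(profiles[i], profiles[j])
                for j in range(n) if j != i]
        out.append(sum(rhos) / len(rhos))
    return out


def contributions_oracle(profiles) -> np.ndarray:
    """Leave-one-region-out contribution matrix, rebuilt from scratch."""
    profiles = [list(p) for p in profiles]
    n, r = len(profiles), len(profiles[0])
    full = pbsi_oracle(profiles)
    out = np.empty((n, r))
    for region in range(r):
        reduced = [[p[j] for j in range(r) if j != region] for p in profiles]
        red = pbsi_oracle(reduced)
        for s in range(n):
            out[s, region] = abs(full[s] - red[s])
    return out


def bh_stepup_oracle(p, q_threshold=0.05):
    """BH step-up by its textbook definition: reject the k largest-rank
    hypotheses where k = max{i : p_(i) <= (i/m) q}; q-values by min over
    j >= i of m p_(j) / j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank / m * q_threshold:
            k = rank
    reject = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= k:
            reject[idx] = True
    q = [None] * m
    best = float("inf")
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        best = min(best, m * p[idx] / rank)
        q[idx] = min(best, 1.0)
    return np.array(q), np.array(reject)


def combat_reference(X, batch, covariates=None, n_iter=100, tol=1e-4):
    """Reference parametric EB ComBat (loops over batches, explicit priors)."""
    X = np.asarray(X, float)
    n, p = X.shape
    batch = np.asarray(batch)
    batches = list(dict.fromkeys(batch.tolist()))
    B = np.column_stack([(batch == b).astype(float) for b in batches])
    D = B if covariates is None else np.column_stack([B, np.asarray(covariates, float)])
    nb = len(batches)
    sizes = B.sum(axis=0)

    beta = np.linalg.lstsq(D, X, rcond=None)[0]
    grand = (sizes / n) @ beta[:nb]
    fitted = D @ beta
    var_pooled = np.mean((X - fitted) ** 2, axis=0)
    stand = np.tile(grand, (n, 1))
    if covariates is not None:
        stand = stand + np.asarray(covariates, float) @ beta[nb:]
    Z = (X - stand) / np.sqrt(var_pooled)

    Z_adj = np.empty_like(Z)
    for b in batches:
        idx = np.flatnonzero(batch == b)
        zb = Z[idx]
        n_b = idx.size
        g_hat = zb.mean(axis=0)
        d_hat = zb.var(axis=0, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m, s2 = d_hat.mean(), d_hat.var(ddof=1)
        a = (2 * s2 + m ** 2) / s2
        bb = (m * s2 + m ** 3) / s2
        g_star, d_star = g_hat.copy(), d_hat.copy()
        for _ in range(n_iter):
            g_new = (n_b * t2 * g_hat + d_star * g_bar) / (n_b * t2 + d_star)
            sse = ((zb - g_new) ** 2).sum(axis=0)
            d_new = (0.5 * sse + bb) / (n_b / 2.0 + a - 1.0)
            change = max(abs(g_new - g_star).max(), abs(d_new - d_star).max())
            g_star, d_star = g_new, d_new
            if change < tol:
                break
        Z_adj[idx] = (zb - g_star) / np.sqrt(d_star)
    return Z_adj * np.sqrt(var_pooled) + stand
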