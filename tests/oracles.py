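"""Independent brute-force oracles for SSIM, the agreement metrics and losses.

Everything here is computed directly from the textbook definitions with
plain loops / dense windows, deliberately sharing no code with the package
implementations it checks.
"""

import numpy as np


def gaussian_window(radius: int = 5, sigma: float = 1.5) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k1 = np.exp(-0.5 * x**2 / sigma**2)
    k1 /= k1.sum()
    return np.outer(k1, k1)


def ssim_bruteforce(a: np.ndarray, b: np.ndarray, k1=0.01, k2=0.03, L=1.0) -> float:
    """Sliding 11x11 Gaussian-weighted SSIM, mean over fully-contained windows."""
    w = gaussian_window()
    r = w.shape[0] // 2
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    H, W = a.shape
    vals = []
    for i in range(r, H - r):
        for j in range(r, W - r):
            pa = a[i - r : i + r + 1, j - r : j + r + 1]
            pb = b[i - r : i + r + 1, j - r : j + r + 1]
            ua = (w * pa).sum()
            ub = (w * pb).sum()
            va = (w * pa * pa).sum() - ua * ua
            vb = (w * pb * pb).sum() - ub * ub
            cov = (w * pa * pb).sum() - ua * ub
            vals.append(
                ((2 * ua * ub + c1) * (2 * cov + c2))
                / ((ua * ua + ub * ub + c1) * (va + vb + c2))
            )
    return float(np.mean(vals))


def _ranks_average_ties(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=np.float64)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def pearson_bruteforce(x, y) -> float:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def spearman_bruteforce(x, y) -> float:
    return pearson_bruteforce(_ranks_average_ties(np.asarray(x, float)),
                              _ranks_average_ties(np.asarray(y, float)))


def kendall_taub_bruteforce(x, y) -> float:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    conc = disc = 0
    for i in range(n):
        for j in range(i + 1, n):
            prod = (x[i] - x[j]) * (y[i] - y[j])
            if prod > 0:
                conc += 1
            elif prod < 0:
                disc += 1
    # tau-b = (C - D) / sqrt((n0 - Tx)(n0 - Ty)), Tx/Ty = tied pairs per variable
    n0 = n * (n - 1) / 2
    n_tx = sum(1 for i in range(n) for j in range(i + 1, n) if x[i] == x[j])
    n_ty = sum(1 for i in range(n) for j in range(i + 1, n) if y[i] == y[j])
    return float((conc - disc) / np.sqrt((n0 - n_tx) * (n0 - n_ty)))


def rmse_bruteforce(x, y) -> float:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    return float(np.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)) / len(x)))


def loss_ed_bruteforce(pairs) -> float:
    total = 0.0
    for orig, recon in pairs:
        o = np.asarray(orig, dtype=np.float64).ravel()
        r = np.asarray(recon, dtype=np.float64).ravel()
        total += sum(abs(a - b) for a, b in zip(o, r))
    return total


def loss_fusion_bruteforce(y_true, y_hat) -> float:
    a = np.asarray(y_true, dtype=np.float64).ravel()
    b = np.asarray(y_hat, dtype=np.float64).ravel()
    return sum(abs(u - v) for u, v in zip(a, b)) / len(a)


def loss_g_bruteforce(fake_scores, l_fusion, alpha) -> float:
    s = np.asarray(fake_scores, dtype=np.float64).ravel()
    return sum((v - 1.0) ** 2 for v in s) / len(s) + alpha * l_fusion


def loss_d_bruteforce(real_scores, fake_scores) -> float:
    r = np.asarray(real_scores, dtype=np.float64).ravel()
    f = np.asarray(fake_scores, dtype=np.float64).ravel()
    return (sum((v - 1.0) ** 2 for v in r) / len(r) + sum(v**2 for v in f) / len(f)) / 2.0
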