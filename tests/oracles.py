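"""Independent reference implementations used to cross-check the package.

These deliberately use different algorithms/code paths than the library
(normal equations instead of lstsq/pinv, scipy.stats convenience tests
instead of vectorized formulas, breadth-first flood fill instead of
ndimage labeling).
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy import stats


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients via explicitly solved normal equations."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta = ols_normal_equations(X, y)
    r = y - X @ beta
    return float(r @ r)


def one_sample_t(values: np.ndarray, direction: str) -> tuple[float, float]:
    """One-sample t against 0 with one-sided p, via scipy.stats.ttest_1samp."""
    alternative = "less" if direction == "negative" else "greater"
    res = stats.ttest_1samp(values, 0.0, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def slope_t(x: np.ndarray, y: np.ndarray, direction: str) -> tuple[float, float]:
    """Simple-regression slope t and one-sided p via scipy.stats.linregress."""
    res = stats.linregress(x, y)
    t = res.slope / res.stderr
    df = len(x) - 2
    p = stats.t.cdf(t, df) if direction == "negative" else stats.t.sf(t, df)
    return float(t), float(p)


def covariate_regression(y, x_cont, sex) -> tuple[float, float, tuple[float, float]]:
    """OLS y ~ 1 + x + 1[sex==M]: returns (beta_x, two-sided p, 95% CI)."""
    y = np.asarray(y, float)
    x = np.asarray(x_cont, float)
    s = (np.asarray(sex) == "M").astype(float)
    X = np.column_stack([np.ones_like(x), x, s])
    beta = ols_normal_equations(X, y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(cov[1, 1])
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    return float(beta[1]), float(p), (float(beta[1] - tcrit * se), float(beta[1] + tcrit * se))


def flood_fill_label(mask: np.ndarray, connectivity: int) -> list[set[tuple[int, int, int]]]:
    """Connected components of a 3D boolean mask by explicit BFS."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dx) + abs(dy) + abs(dz) != 1:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for idx in zip(*np.nonzero(mask)):
        if seen[idx]:
            continue
        comp = set()
        queue = deque([idx])
        seen[idx] = True
        while queue:
            cur = queue.popleft()
            comp.add(cur)
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if any(n < 0 or n >= s for n, s in zip(nb, mask.shape)):
                    continue
                if mask[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        components.append(comp)
    return components


def gaussian_kernel_1d(sigma: float) -> np.ndarray:
    """Truncated (radius 4 sigma) normalized sampled Gaussian."""
    r = int(4.0 * sigma + 0.5)
    x = np.arange(-r, r + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()
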