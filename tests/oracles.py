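"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most literal route available
(explicit neighborhood lists, flood fill, full enumeration, numerical
integration) and is kept free of any code shared with the implementation
it checks.
"""

from collections import deque
from itertools import product

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm, rankdata


def phansalkar_bruteforce(img, radius, k=0.25, r=0.5, p=2.0, q=10.0):
    """Per-pixel Phansalkar classification from explicit neighborhood lists."""
    h, w = img.shape
    padded = np.pad(img, radius, mode="symmetric")  # == ndimage 'reflect'
    offsets = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    mask = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            vals = np.array(
                [padded[y + radius + dy, x + radius + dx] for dy, dx in offsets]
            )
            mu = vals.mean()
            sigma = vals.std()  # population SD
            t = mu * (1 + p * np.exp(-q * mu) + k * (sigma / r - 1))
            mask[y, x] = img[y, x] <= t
    return mask


def floodfill_component_areas(mask, connectivity):
    """Connected-component areas by breadth-first flood fill."""
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        steps = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                 if (dy, dx) != (0, 0)]
    else:
        raise ValueError(connectivity)
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    areas = []
    for y0 in range(h):
        for x0 in range(w):
            if not mask[y0, x0] or seen[y0, x0]:
                continue
            area = 0
            queue = deque([(y0, x0)])
            seen[y0, x0] = True
            while queue:
                y, x = queue.popleft()
                area += 1
                for dy, dx in steps:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] \
                            and not seen[ny, nx]:
                        seen[ny, nx] = True
                        queue.append((ny, nx))
            areas.append(area)
    return sorted(areas)


def wilcoxon_exact_enum(a, b):
    """Two-sided exact signed-rank p by enumerating every sign pattern."""
    d = np.asarray(a, float) - np.asarray(b, float)
    nz = d[d != 0]
    n = nz.size
    ranks = rankdata(np.abs(nz))
    w_obs = ranks[nz > 0].sum()
    ws = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product((0, 1), repeat=n)
    ])
    cdf = np.mean(ws <= w_obs + 1e-9)
    sf = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(cdf, sf))


def icc2_oracle(x):
    """ICC(2,1) from explicitly summed squares (Shrout-Fleiss)."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (x[i].mean() - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (x[:, j].mean() - grand) ** 2
    ss_total = 0.0
    for i in range(n):
        for j in range(k):
            ss_total += (x[i, j] - grand) ** 2
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def rm_anova_oracle(x):
    """One-factor repeated-measures ANOVA F from explicit sums of squares."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ss_subj = k * sum((x[i].mean() - grand) ** 2 for i in range(n))
    ss_cond = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_subj - ss_cond
    ms_cond = ss_cond / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_cond / ms_err


def studentized_range_sf_oracle(q, k, df):
    """P(Q > q) for the studentized range by direct numerical integration."""

    def inner(s):
        # P(range of k std normals <= q*s)
        def f(z):
            return k * norm.pdf(z) * (norm.cdf(z) - norm.cdf(z - q * s)) ** (k - 1)

        val, _ = quad(f, -8, 8, limit=200)
        return val

    # density of s = chi_df / sqrt(df)
    from scipy.special import gammaln

    log_c = (df / 2) * np.log(df) - gammaln(df / 2) - (df / 2 - 1) * np.log(2)

    def outer(s):
        log_pdf = log_c + (df - 1) * np.log(s) - df * s * s / 2
        return np.exp(log_pdf) * inner(s)

    cdf, _ = quad(outer, 1e-6, 10, limit=200)
    return 1.0 - cdf
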