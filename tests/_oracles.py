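"""Independent oracles for the test suite.

These deliberately avoid the package's trust-region-reflective fit path:
nonlinear fits are solved by variable projection (profile the single
nonlinear diffusivity on a grid, solve the conditionally linear amplitudes
in closed form / by NNLS, polish with Brent), and combinatorial checks are
done by brute-force enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize_scalar, nnls


def _profile_minimum(sse, lo, hi, n_grid=2000):
    """Grid-scan then Brent-polish a 1-D SSE profile on [lo, hi]."""
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([sse(g) for g in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(sse, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-13})
    return float(res.x)


def monoexp_varpro(y, b_ms, ds_range=(0.0, 1.0)):
    """Best-fit (s0s, ds) of s0s*exp(-b*ds) by variable projection."""
    y = np.asarray(y, dtype=float)
    b_ms = np.asarray(b_ms, dtype=float)

    def amp(ds):
        e = np.exp(-b_ms * ds)
        return max(float(e @ y) / float(e @ e), 0.0)

    def sse(ds):
        return float(np.sum((amp(ds) * np.exp(-b_ms * ds) - y) ** 2))

    ds = _profile_minimum(sse, *ds_range)
    return amp(ds), ds


def biexp_varpro(y, b_ms, d_fw=3.0, md_range=(0.0, 3.0)):
    """Best-fit (s0, ft, md) of s0*[ft e^(-b md) + (1-ft) e^(-b d_fw)].

    For fixed md the model is linear in the two non-negative amplitudes
    a = s0*ft and c = s0*(1-ft); NNLS solves them, Brent polishes md.
    """
    y = np.asarray(y, dtype=float)
    b_ms = np.asarray(b_ms, dtype=float)

    def amps(md):
        A = np.column_stack([np.exp(-b_ms * md), np.exp(-b_ms * d_fw)])
        x, _ = nnls(A, y)
        return x

    def sse(md):
        a = amps(md)
        A = np.column_stack([np.exp(-b_ms * md), np.exp(-b_ms * d_fw)])
        return float(np.sum((A @ a - y) ** 2))

    md = _profile_minimum(sse, *md_range)
    a, c = amps(md)
    s0 = a + c
    ft = a / s0 if s0 > 0 else np.nan
    return float(s0), float(ft), float(md)


def mannwhitney_exact_p(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of rank splits."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, m = x.size, y.size

    def u_stat(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_stat(x, y)
    dev_obs = abs(u_obs - n * m / 2)
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        if abs(u_stat(xs, ys) - n * m / 2) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def mannwhitney_permutation_p(x, y, n_perm=100_000, seed=0):
    """Monte-Carlo permutation two-sided p for tied data."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n = x.size

    def u_stat(xs, ys):
        return np.sum((xs[:, None] > ys[None, :]) + 0.5 * (xs[:, None] == ys[None, :]))

    dev_obs = abs(u_stat(x, y) - n * y.size / 2)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(u_stat(perm[:n], perm[n:]) - n * y.size / 2) >= dev_obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def icc21_hand(m):
    """ICC(2,1) spelled out via explicit variance-component sums."""
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = m.mean()
    msr = k / (n - 1) * sum((m[i].mean() - grand) ** 2 for i in range(n))
    msc = n / (k - 1) * sum((m[:, j].mean() - grand) ** 2 for j in range(k))
    sse = sum(
        (m[i, j] - m[i].mean() - m[:, j].mean() + grand) ** 2
        for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def brute_force_filter(ft, fs, ds, labelled, ft_min=0.3, pct=99.0):
    """Recount of the voxel-inclusion rule, written independently.

    Voxel kept iff labelled, finite, ft > ft_min, and fs and ds do not
    exceed the pct-th percentile of the post-ft-filter labelled values.
    """
    keep = []
    base_idx = [
        i for i in range(len(ft))
        if labelled[i] and np.isfinite(ft[i]) and np.isfinite(fs[i])
        and np.isfinite(ds[i]) and ft[i] > ft_min
    ]
    if not base_idx:
        return []
    fs_cut = np.percentile([fs[i] for i in base_idx], pct)
    ds_cut = np.percentile([ds[i] for i in base_idx], pct)
    for i in base_idx:
        if fs[i] <= fs_cut and ds[i] <= ds_cut:
            keep.append(i)
    return keep
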