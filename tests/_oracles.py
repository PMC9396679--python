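"""Independent oracles used by the test suite.

These deliberately avoid the package's own implementations: brute-force
DFT, exhaustive shift search, and per-chain dynamic programming.
"""

from __future__ import annotations

import numpy as np


def dft_magnitude(x: np.ndarray) -> np.ndarray:
    """Brute-force O(n^2) DFT magnitude of a real/complex sequence."""
    n = len(x)
    k = np.arange(n)
    basis = np.exp(-2j * np.pi * np.outer(k, k) / n)
    return np.abs(basis @ np.asarray(x, dtype=complex))


def best_integer_shift(ref: np.ndarray, mov: np.ndarray, max_shift: int = 8):
    """Exhaustive search over integer circular shifts maximising the
    correlation of ``np.roll(ref, s)`` with ``mov``."""
    best, best_s = -np.inf, (0, 0)
    for dz in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            c = float((np.roll(ref, (dz, dx), axis=(0, 1)) * mov).sum())
            if c > best:
                best, best_s = c, (dz, dx)
    return best_s


def best_fractional_shift_1d(ref, mov, grid_step=0.05, max_shift=3.0):
    """Correlation argmax of axis-0 Fourier-shifted ``ref`` against
    ``mov`` over a fractional shift grid."""
    from scipy.ndimage import fourier_shift

    shifts = np.arange(-max_shift, max_shift + grid_step / 2, grid_step)
    F = np.fft.fft2(ref)
    best, best_s = -np.inf, 0.0
    for s in shifts:
        cand = np.fft.ifft2(fourier_shift(F, (s, 0.0))).real
        c = float((cand * mov).sum())
        if c > best:
            best, best_s = c, s
    return best_s


def dp_surface_chain(cost: np.ndarray, delta: int):
    """Exact minimiser of sum(cost[x, z_x]) over a 1-D chain of columns
    with |z_x - z_{x-1}| <= delta, by dynamic programming.

    Returns (surface, total_cost)."""
    cost = np.asarray(cost)
    nx, nd = cost.shape
    dp = cost[0].astype(np.int64).copy()
    back = np.zeros((nx, nd), dtype=np.int64)
    for x in range(1, nx):
        arg = np.empty(nd, dtype=np.int64)
        for z in range(nd):
            lo, hi = max(0, z - delta), min(nd, z + delta + 1)
            arg[z] = lo + int(np.argmin(dp[lo:hi]))
        back[x] = arg
        dp = cost[x].astype(np.int64) + dp[arg]
    z = np.empty(nx, dtype=np.int64)
    z[-1] = int(np.argmin(dp))
    total = int(dp[z[-1]])
    for x in range(nx - 1, 0, -1):
        z[x - 1] = back[x, z[x]]
    return z, total


def rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) statistic."""
    from scipy.stats import rankdata

    vals = np.concatenate([pos, neg])
    ranks = rankdata(vals)
    r_pos = ranks[: len(pos)].sum()
    n_p, n_n = len(pos), len(neg)
    return float((r_pos - n_p * (n_p + 1) / 2) / (n_p * n_n))
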