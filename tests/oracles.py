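"""Independent oracles used by the test suite.

Deliberately naive implementations (explicit micro-step integration,
aggregated stochastic simulation, normal-equation least squares, bisection)
kept separate from the package so the checks do not share code with the
implementations they validate.
"""

from __future__ import annotations

import numpy as np


def euler_occupancy(Q: np.ndarray, p0: np.ndarray, t_end: float, dt: float = 1e-6):
    """Explicit micro-step master-equation integration (classic RK4 at a
    1 us step by default); returns p(t_end)."""
    p = np.asarray(p0, dtype=float).copy()
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        k1 = p @ Q
        k2 = (p + 0.5 * dt * k1) @ Q
        k3 = (p + 0.5 * dt * k2) @ Q
        k4 = (p + dt * k3) @ Q
        p = p + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return p


def gillespie_mean_occupancy(
    Q: np.ndarray, p0: np.ndarray, t_grid: np.ndarray, n_channels: int, rng
):
    """Exact SSA on aggregated state counts of independent channels.

    Returns mean occupancy (n_times, n_states) over the ensemble.
    """
    n = Q.shape[0]
    counts = rng.multinomial(n_channels, p0)
    rates = Q.copy()
    np.fill_diagonal(rates, 0.0)
    out = np.empty((t_grid.size, n))
    t = 0.0
    k = 0
    while k < t_grid.size:
        prop = counts[:, None] * rates  # propensity of each i->j transition
        total = prop.sum()
        if total <= 0:
            while k < t_grid.size:
                out[k] = counts / n_channels
                k += 1
            break
        dt = rng.exponential(1.0 / total)
        while k < t_grid.size and t + dt > t_grid[k]:
            out[k] = counts / n_channels
            k += 1
        t += dt
        flat = rng.choice(n * n, p=(prop / total).ravel())
        i, j = divmod(flat, n)
        counts[i] -= 1
        counts[j] += 1
    return out


def ols_line(x: np.ndarray, y: np.ndarray):
    """Straight-line least squares via the normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    A = np.vstack([x, np.ones_like(x)]).T
    slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
    return slope, intercept


def bisect_root(fun, lo: float, hi: float, tol: float = 1e-15, it: int = 200):
    """Plain bisection for a sign-changing scalar function."""
    flo = fun(lo)
    for _ in range(it):
        mid = 0.5 * (lo + hi)
        fm = fun(mid)
        if flo * fm <= 0:
            hi = mid
        else:
            lo, flo = mid, fm
        if hi - lo < tol * max(1.0, abs(hi)):
            break
    return 0.5 * (lo + hi)


def grid_minimize(fun, lo: float, hi: float, n: int = 100001):
    """Brute-force grid minimizer, returns argmin."""
    xs = np.linspace(lo, hi, n)
    vals = np.array([fun(x) for x in xs])
    return float(xs[np.argmin(vals)])
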