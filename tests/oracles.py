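"""Independent brute-force oracles used by the test suite.

Each oracle re-derives its quantity from the defining formula or by
exhaustive search, sharing no code with the implementation under test.
"""

import numpy as np
from scipy.optimize import linprog


def best_two_partition(values):
    """Exhaustively minimise WSS over all contiguous 2-partitions of sorted data.

    The optimal 2-means partition of univariate data is contiguous in sorted
    order, so scanning every split point is exhaustive.
    """
    x = np.sort(np.asarray(values, dtype=float))
    best = None
    for cut in range(1, x.size):
        a, b = x[:cut], x[cut:]
        wss = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
        if best is None or wss < best[0]:
            best = (wss, cut)
    wss, cut = best
    tss = float(np.sum((x - x.mean()) ** 2))
    return {"wss": float(wss), "tss": tss, "sizes": (cut, x.size - cut)}


def logrank_z_direct(time, event, group1):
    """Direct term-by-term evaluation of the two-group logrank Z statistic."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group1 = np.asarray(group1, dtype=bool)
    num = 0.0
    var = 0.0
    for t in sorted(set(time[event])):
        at_risk = time >= t
        y = at_risk.sum()
        if y < 2:
            continue
        y1 = (at_risk & group1).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & group1).sum()
        num += d1 - y1 * d / y
        var += (y1 / y) * (1 - y1 / y) * ((y - d) / (y - 1)) * d
    return num / np.sqrt(var) if var > 0 else 0.0


def dip_lp_oracle(values, n_grid=250):
    """Minimise sup|F_n - G| over unimodal CDFs G by linear programming.

    G is piecewise linear on a dense grid, convex below the mode and concave
    above it, nondecreasing between 0 and 1, with a possible upward jump
    (atom) at the mode; every grid placement of the mode is tried.  The band
    constraints use both one-sided limits of F_n at the data points.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    pad = 0.3 * (np.ptp(x) + 1.0)
    grid = np.unique(np.concatenate(
        [np.linspace(x[0] - pad, x[-1] + pad, n_grid), x, x - 1e-7, x + 1e-7]))
    m = grid.size
    f_right = np.searchsorted(x, grid, side="right") / n   # F_n at grid point
    f_left = np.searchsorted(x, grid, side="left") / n     # left limit

    best = np.inf
    for mode_i in range(m):
        # variables: d, g_0..g_{m-1} (g_mode = left limit), w = G(mode)
        nv = m + 1
        rows, rhs = [], []

        def add(pairs, dcoef, bound):
            row = np.zeros(nv + 1)
            row[0] = dcoef
            for idx, coef in pairs:
                row[idx + 1] = coef
            rows.append(row)
            rhs.append(bound)

        for j in range(m):
            if j == mode_i:
                add([(j, -1.0)], -1.0, -f_left[j])
                add([(j, 1.0)], -1.0, f_left[j])
                add([(m, -1.0)], -1.0, -f_right[j])
                add([(m, 1.0)], -1.0, f_right[j])
            else:
                add([(j, -1.0)], -1.0, -f_right[j])
                add([(j, 1.0)], -1.0, f_right[j])
        for j in range(m - 1):
            left_var = j if j != mode_i else m
            add([(left_var, 1.0), (j + 1, -1.0)], 0.0, 0.0)      # monotone
        add([(mode_i, 1.0), (m, -1.0)], 0.0, 0.0)                # jump up only
        add([(0, -1.0)], 0.0, 0.0)                               # G >= 0
        add([(m - 1 if mode_i != m - 1 else m, 1.0)], 0.0, 1.0)  # G <= 1
        for j in range(1, m - 1):
            dx1 = grid[j] - grid[j - 1]
            dx2 = grid[j + 1] - grid[j]
            if j < mode_i:       # convex branch
                add([(j - 1, -1 / dx1), (j, 1 / dx1 + 1 / dx2), (j + 1, -1 / dx2)],
                    0.0, 0.0)
            elif j > mode_i:     # concave branch
                left_var = j - 1 if j - 1 != mode_i else m
                add([(left_var, 1 / dx1), (j, -1 / dx1 - 1 / dx2), (j + 1, 1 / dx2)],
                    0.0, 0.0)
        cost = np.zeros(nv + 1)
        cost[0] = 1.0
        res = linprog(cost, A_ub=np.array(rows), b_ub=np.array(rhs),
                      bounds=[(None, None)] * (nv + 1), method="highs")
        if res.status == 0:
            best = min(best, res.fun)
    return best


def km_survival_direct(time, event):
    """Hand product-limit estimator at each distinct event time."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    out = []
    s = 1.0
    for t in sorted(set(time[event])):
        y = (time >= t).sum()
        d = (event & (time == t)).sum()
        s *= 1 - d / y
        out.append((t, s))
    return out
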