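"""Independent oracles used by the test-suite.

These deliberately avoid the code paths they validate: the dip oracle is an
LP over enumerated mode positions, and the rarefaction oracle is brute-force
Monte-Carlo subsampling.
"""

import numpy as np
from scipy.optimize import linprog


def dip_lp(x):
    """Exact dip via linear programming.

    For each mode index m the nearest unimodal CDF is convex left of x_m
    (left value v1), concave from x_m on (value v2 >= v1; an atom at the
    mode is allowed).  Minimising the sup-distance over the band constraints
    at the data points is an LP; the dip is the minimum over m.
    """
    x = np.sort(np.asarray(x, float))
    n = x.size
    best = np.inf
    for m in range(1, n + 1):
        nv = n + 2
        iL = lambda i: i - 1          # y_i, i = 1..m (y_m = v1)
        iR = lambda i: m + (i - m)    # z_i, i = m..n (z_m = v2)
        ie = n + 1
        c = np.zeros(nv)
        c[ie] = 1.0
        A, b = [], []

        def le(coefs, rhs):
            r = np.zeros(nv)
            for idx, co in coefs:
                r[idx] += co
            A.append(r)
            b.append(rhs)

        for i in range(1, m):
            le([(iL(i), 1), (iL(i + 1), -1)], 0.0)
        le([(iL(m), 1), (iR(m), -1)], 0.0)
        for i in range(m, n):
            le([(iR(i), 1), (iR(i + 1), -1)], 0.0)
        for i in range(1, m):
            le([(iL(i), -1), (ie, -1)], -i / n)
            le([(iL(i), 1), (ie, -1)], (i - 1) / n)
        le([(iL(m), -1), (ie, -1)], -(m - 1) / n)
        le([(iL(m), 1), (ie, -1)], (m - 1) / n)
        le([(iR(m), -1), (ie, -1)], -m / n)
        le([(iR(m), 1), (ie, -1)], m / n)
        for i in range(m + 1, n + 1):
            le([(iR(i), -1), (ie, -1)], -i / n)
            le([(iR(i), 1), (ie, -1)], (i - 1) / n)
        for i in range(2, m):
            dx1, dx2 = x[i - 1] - x[i - 2], x[i] - x[i - 1]
            if dx1 <= 0 or dx2 <= 0:
                continue
            le([(iL(i + 1), -dx1), (iL(i), dx1 + dx2), (iL(i - 1), -dx2)], 0.0)
        for i in range(m + 1, n):
            dx1, dx2 = x[i - 1] - x[i - 2], x[i] - x[i - 1]
            if dx1 <= 0 or dx2 <= 0:
                continue
            le([(iR(i + 1), dx1), (iR(i), -(dx1 + dx2)), (iR(i - 1), dx2)], 0.0)
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(-0.5, 1.5)] * (n + 1) + [(0, 1)], method="highs")
        if res.success:
            best = min(best, res.fun)
    return best


def mc_rarefaction(abund, n=50, draws=100_000, seed=0):
    """Monte-Carlo expected species in a draw of n individuals without
    replacement (mean over seeded draws), plus its standard error."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(abund)), abund)
    N = labels.size
    counts = np.empty(draws)
    block = max(1, int(2e7 // N))
    done = 0
    while done < draws:
        b = min(block, draws - done)
        keys = rng.random((b, N))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        sel = labels[idx]
        sel.sort(axis=1)
        counts[done:done + b] = 1 + (np.diff(sel, axis=1) != 0).sum(axis=1)
        done += b
    return counts.mean(), counts.std(ddof=1) / np.sqrt(draws)
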