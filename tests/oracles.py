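"""Independent brute-force oracles, free of any LP-solver code path.

The envelopment oracle enumerates every candidate vertex of the phase-1
feasible region by choosing which constraints are active and solving the
resulting square linear system directly — exhaustive basis enumeration, the
textbook (exponential) way to solve a tiny LP.
"""

from itertools import combinations

import numpy as np


def oracle_theta(FX, FY, x0, y0, vrs: bool) -> float:
    """min theta of the input-oriented envelopment by vertex enumeration.

    FX, FY: (n_frontier, m) and (n_frontier, s) arrays; x0, y0 the evaluated
    point.  Works for a handful of DMUs and dimensions only.
    """
    FX, FY = np.asarray(FX, float), np.asarray(FY, float)
    x0, y0 = np.asarray(x0, float), np.asarray(y0, float)
    n, m = FX.shape
    s = FY.shape[1]
    nvar = n + 1  # [theta, lambda]
    # constraint rows as (a, b, is_eq) with a @ v <= b or == b
    rows = []
    for k in range(m):
        rows.append((np.concatenate([[-x0[k]], FX[:, k]]), 0.0, False))
    for r in range(s):
        rows.append((np.concatenate([[0.0], -FY[:, r]]), -y0[r], False))
    for j in range(nvar):  # nonnegativity
        a = np.zeros(nvar)
        a[j] = -1.0
        rows.append((a, 0.0, False))
    eq_rows = []
    if vrs:
        eq_rows.append((np.concatenate([[0.0], np.ones(n)]), 1.0))

    ineq_idx = range(len(rows))
    best = np.inf
    need = nvar - len(eq_rows)
    for active in combinations(ineq_idx, need):
        A = np.array([rows[i][0] for i in active] + [a for a, b in eq_rows])
        b = np.array([rows[i][1] for i in active] + [b for a, b in eq_rows])
        try:
            v = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        lhs_ok = all(a @ v <= bb + 1e-8 for a, bb, _ in rows)
        if lhs_ok and v[0] < best:
            best = v[0]
    return float(best)


def oracle_crs_1x1(x, y, x0, y0) -> float:
    """Closed form for single-input single-output CRS: ratio-of-ratios."""
    return (y0 / x0) / max(yj / xj for xj, yj in zip(x, y))
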