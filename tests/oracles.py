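"""Independent brute-force oracles used to validate the fast implementations.

These are deliberately naive: the dip oracle solves the defining sup-norm
minimization as a family of linear programs (one per mode placement), and
the Hampel oracle recomputes every sliding window from scratch.  They share
no code with the implementations they check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def dip_brute_force(sample: np.ndarray) -> float:
    """Exact dip statistic for small samples by linear programming.

    The dip is min over unimodal CDFs G of sup_x |F_n(x) - G(x)|.  The
    optimal G can be taken piecewise linear with knots at the data points
    (plus possibly a jump at the mode), so for each mode placement the inner
    minimization is an LP in the values of G at the data points:

    * sup-norm constraints: at each data point x_i the empirical CDF takes
      the values i/n (left limit) and (i+1)/n, so |i/n - g_i| <= t and
      |(i+1)/n - g_i| <= t;
    * G nondecreasing with 0 <= g <= 1;
    * convexity of G left of the mode and concavity right of it, expressed
      through chord slopes.

    Mode placements enumerated: every inter-point gap (including before the
    first and after the last point) and every data point with a jump allowed
    at the mode (unimodal CDFs may carry an atom at the mode, which splits
    the value at that point into a left limit a and a right value b >= a).
    """
    xs = np.sort(np.asarray(sample, dtype=float))
    n = xs.size
    if n < 2:
        raise ValueError("need at least 2 points")
    best = np.inf
    # mode at a data point, with an atom there
    for m in range(n):
        best = min(best, _jump_mode_lp(xs, m))
    # mode strictly inside a gap: scan the mode position, then refine the
    # best candidate with a bounded scalar minimization
    from scipy.optimize import minimize_scalar

    n_grid = 41
    best_gap = None
    for m in range(n - 1):
        lo, hi = xs[m], xs[m + 1]
        if hi <= lo:
            continue
        for frac in np.linspace(1e-9, 1 - 1e-9, n_grid):
            val = _interior_mode_lp(xs, m, lo + frac * (hi - lo))
            if val < best:
                best = val
                best_gap = m
    if best_gap is not None:
        m = best_gap
        lo, hi = xs[m], xs[m + 1]
        res = minimize_scalar(
            lambda mu: _interior_mode_lp(xs, m, mu),
            bounds=(lo + 1e-12 * (hi - lo), hi - 1e-12 * (hi - lo)),
            method="bounded",
            options={"xatol": 1e-14 * (hi - lo)},
        )
        best = min(best, float(res.fun))
    return best


def _tube_rows(n: int, tcol: int, gcol) -> tuple[list, list]:
    """Constraints g_i <= i + t and g_i >= (i+1) - t for all points.

    Everything is solved in CDF *count* units (n times the CDF) for better
    LP conditioning; callers divide the optimum by n.
    """
    A, b = [], []
    for i in range(n):
        row = np.zeros(tcol + 1)
        row[gcol(i)] = 1.0
        row[tcol] = -1.0
        A.append(row)
        b.append(float(i))
        row = np.zeros(tcol + 1)
        row[gcol(i)] = -1.0
        row[tcol] = -1.0
        A.append(row)
        b.append(-float(i + 1))
    return A, b


def _shape_row(nvar: int, il: int, ic: int, ir: int, xl: float, xc: float, xr: float,
               concave: bool) -> np.ndarray:
    # convex: (g_c - g_l)*(xr - xc) - (g_r - g_c)*(xc - xl) <= 0
    d1 = xc - xl
    d2 = xr - xc
    row = np.zeros(nvar)
    row[il] = -d2
    row[ic] = d2 + d1
    row[ir] = -d1
    if concave:
        row = -row
    return row


def _solve(c, A, b, nvar: int, n: int) -> float:
    bounds = [(0.0, float(n))] * (nvar - 1) + [(0.0, None)]
    res = linprog(
        c, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds, method="highs",
        options={
            "primal_feasibility_tolerance": 1e-10,
            "dual_feasibility_tolerance": 1e-10,
        },
    )
    if not res.success:  # pragma: no cover
        return np.inf
    return float(res.fun) / n


def _interior_mode_lp(xs: np.ndarray, m: int, mu: float) -> float:
    """Mode at a fixed position mu strictly inside (x_m, x_{m+1}).

    The CDF gets an extra knot at mu where an atom is allowed: left limit a
    ends the convex branch, value b >= a starts the concave branch, both
    within t of the empirical CDF's plateau (m+1)/n on that gap.  The
    convex branch must stay convex through its final chord into the mode,
    and the concave branch through its first chord out of it — these
    couplings are what bound how steeply the fit may cross the gap.
    """
    n = xs.size
    # variables: g_0..g_{n-1}, a, b, t
    nvar = n + 3
    acol, bcol, tcol = n, n + 1, n + 2
    c = np.zeros(nvar)
    c[tcol] = 1.0
    A, bb = _tube_rows(n, tcol, lambda i: i)
    plateau = float(m + 1)
    for col in (acol, bcol):
        row = np.zeros(nvar)
        row[col] = 1.0
        row[tcol] = -1.0
        A.append(row)
        bb.append(plateau)
        row = np.zeros(nvar)
        row[col] = -1.0
        row[tcol] = -1.0
        A.append(row)
        bb.append(-plateau)
    # monotone chain ... g_m <= a <= b <= g_{m+1} ...
    chain = list(range(m + 1)) + [acol, bcol] + list(range(m + 1, n))
    for u, v in zip(chain, chain[1:]):
        row = np.zeros(nvar)
        row[u] = 1.0
        row[v] = -1.0
        A.append(row)
        bb.append(0.0)
    # convex branch: data triples, plus the chord into the mode knot
    for i in range(1, m):
        A.append(_shape_row(nvar, i - 1, i, i + 1, xs[i - 1], xs[i], xs[i + 1], False))
        bb.append(0.0)
    if m >= 1:
        A.append(_shape_row(nvar, m - 1, m, acol, xs[m - 1], xs[m], mu, False))
        bb.append(0.0)
    # concave branch: chord out of the mode knot, plus data triples
    if m + 2 <= n - 1:
        A.append(_shape_row(nvar, bcol, m + 1, m + 2, mu, xs[m + 1], xs[m + 2], True))
        bb.append(0.0)
    for i in range(m + 2, n - 1):
        A.append(_shape_row(nvar, i - 1, i, i + 1, xs[i - 1], xs[i], xs[i + 1], True))
        bb.append(0.0)
    return _solve(c, A, bb, nvar, n)


def _jump_mode_lp(xs: np.ndarray, m: int) -> float:
    """Mode with an atom at x_m: the CDF value there splits into a left
    limit a (ending the convex branch, constrained only against i/n) and a
    right value b >= a (starting the concave branch, constrained against
    (i+1)/n)."""
    n = xs.size
    # variables: g_0..g_{n-1} (g_m plays the role of a), b_extra, t
    nvar = n + 2
    bcol, tcol = n, n + 1
    c = np.zeros(nvar)
    c[tcol] = 1.0
    A: list = []
    b: list = []
    for i in range(n):
        if i == m:
            row = np.zeros(nvar)  # a <= m/n + t
            row[m] = 1.0
            row[tcol] = -1.0
            A.append(row)
            b.append(float(m))
            row = np.zeros(nvar)  # a >= m/n - t
            row[m] = -1.0
            row[tcol] = -1.0
            A.append(row)
            b.append(-float(m))
            row = np.zeros(nvar)  # b <= (m+1)/n + t
            row[bcol] = 1.0
            row[tcol] = -1.0
            A.append(row)
            b.append(float(m + 1))
            row = np.zeros(nvar)  # b >= (m+1)/n - t
            row[bcol] = -1.0
            row[tcol] = -1.0
            A.append(row)
            b.append(-float(m + 1))
        else:
            row = np.zeros(nvar)
            row[i] = 1.0
            row[tcol] = -1.0
            A.append(row)
            b.append(float(i))
            row = np.zeros(nvar)
            row[i] = -1.0
            row[tcol] = -1.0
            A.append(row)
            b.append(-float(i + 1))

    def left_col(i: int) -> int:  # column of G's value entering the convex branch
        return i

    def right_col(i: int) -> int:  # value entering the concave branch
        return bcol if i == m else i

    # monotone: ..., g_{m-1} <= a <= b <= g_{m+1}, ...
    chain = [left_col(i) for i in range(m + 1)] + [bcol] + [i for i in range(m + 1, n)]
    for u, v in zip(chain, chain[1:]):
        row = np.zeros(nvar)
        row[u] = 1.0
        row[v] = -1.0
        A.append(row)
        b.append(0.0)
    for i in range(1, m):  # convex branch: triples centered strictly left of m
        A.append(
            _shape_row(nvar, left_col(i - 1), left_col(i), left_col(i + 1),
                       xs[i - 1], xs[i], xs[i + 1], False)
        )
        b.append(0.0)
    for i in range(m + 1, n - 1):  # concave branch includes x_m with value b
        A.append(
            _shape_row(nvar, right_col(i - 1), right_col(i), right_col(i + 1),
                       xs[i - 1], xs[i], xs[i + 1], True)
        )
        b.append(0.0)
    return _solve(c, A, b, nvar, n)


def hampel_brute_force(
    x: np.ndarray, half: int, nsigma: float, mad_scale: float = 1.4826
) -> tuple[np.ndarray, np.ndarray]:
    """Naive O(n*w) sliding median/MAD recomputation, edge-truncated windows."""
    x = np.asarray(x, dtype=float)
    n = x.size
    y = x.copy()
    flags = []
    for i in range(n):
        w = x[max(0, i - half): i + half + 1]
        med = np.median(w)
        mad = np.median(np.abs(w - med))
        if abs(x[i] - med) > nsigma * mad_scale * mad:
            y[i] = med
            flags.append(i)
    return y, np.array(flags, dtype=int)
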