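"""Hartigan's dip statistic of unimodality.

The dip of a sample is the smallest sup-norm distance between its empirical
distribution function and any unimodal distribution function (convex up to
a mode, concave after it, jumps at the mode allowed). It is computed here
exactly: for every candidate mode position (each gap between adjacent data
values, and each data value itself) the best unimodal fit is a small linear
program in the fitted CDF values; the dip is the minimum over mode
positions. Hull-based lower bounds prune almost all candidate modes before
any LP is solved.

Useful closed forms (used as frozen test oracles): an evenly spaced sample
of n distinct values has dip 1/(2n); two equal point masses have dip 1/4,
the maximum possible value.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import coo_matrix


def _collapse(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique sorted values and their cumulative ECDF fractions."""
    v, counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
    c = np.cumsum(counts) / counts.sum()
    return v, c


def _gcm_values(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Greatest convex minorant of points (x, y), evaluated at the x's."""
    hull = [0]
    for i in range(1, len(x)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (y[b] - y[a]) * (x[i] - x[b]) <= (y[i] - y[b]) * (x[b] - x[a]):
                break
            hull.pop()
        hull.append(i)
    out = np.empty_like(y)
    for a, b in zip(hull[:-1], hull[1:]):
        t = (x[a:b + 1] - x[a]) / (x[b] - x[a])
        out[a:b + 1] = y[a] + t * (y[b] - y[a])
    out[hull[-1]] = y[hull[-1]]
    return out


def _side_bound(v: np.ndarray, lower: np.ndarray, upper: np.ndarray, convex: bool):
    """Half of the max violation of the band by the best one-sided fit.

    For the convex side the largest convex function below ``upper`` is its
    greatest convex minorant; feasibility within [lower - t, upper + t]
    requires t >= (lower - gcm(upper))/2. The concave side is the mirror
    image.
    """
    if len(v) == 0:
        return 0.0
    if convex:
        fit = _gcm_values(v, upper)
        gap = lower - fit
    else:
        fit = -_gcm_values(v, -lower)  # least concave majorant
        gap = fit - upper
    return float(max(0.0, gap.max() / 2.0))


def _mode_lp(v, c_lo, c_hi, k: int, split: bool) -> float:
    """Best unimodal sup-norm fit with the mode fixed at one position.

    ``split=False``: mode in the open gap after value k (1-based; k=0 means
    before all data) — fitted values convex over v[:k], concave over v[k:].
    ``split=True``: mode exactly at value k, whose fitted CDF may jump there:
    the value splits into a left limit (end of the convex part, matched
    against the pre-jump ECDF) and a right value (start of the concave part,
    matched against the post-jump ECDF).
    """
    u = len(v)
    nv = u + (1 if split else 0) + 1  # g's plus t
    ti = nv - 1
    rows, cols, data, rhs = [], [], [], []

    def add(coeffs: list[tuple[int, float]], ub: float) -> None:
        r = len(rhs)
        for j, a in coeffs:
            rows.append(r)
            cols.append(j)
            data.append(a)
        rhs.append(ub)

    # variable layout: g_0..g_{k-1} (convex side), [g_split], g_k..g_{u-1}
    def gvar(i: int, side: str) -> int:
        if not split:
            return i
        if side == "left" and i == k - 1:
            return i  # left limit at the mode value
        if side == "right" and i == k - 1:
            return u  # post-jump value at the mode
        return i if i < k - 1 else i + 1

    # band constraints: t >= g_i - c_lo[i], t >= c_hi[i] - g_i
    for i in range(u):
        if split and i == k - 1:
            gl, gr = gvar(i, "left"), gvar(i, "right")
            add([(gl, 1.0), (ti, -1.0)], c_lo[i])
            add([(gl, -1.0), (ti, -1.0)], -c_lo[i])
            add([(gr, 1.0), (ti, -1.0)], c_hi[i])
            add([(gr, -1.0), (ti, -1.0)], -c_hi[i])
            add([(gl, 1.0), (gr, -1.0)], 0.0)  # jump upward only
        else:
            g = gvar(i, "left")
            add([(g, 1.0), (ti, -1.0)], c_lo[i])
            add([(g, -1.0), (ti, -1.0)], -c_hi[i])

    # monotonicity across consecutive fitted values
    order = [gvar(i, "left") for i in range(k)]
    if split:
        order.append(gvar(k - 1, "right"))
    order += [gvar(i, "right") for i in range(k, u)]
    seen = []
    for g in order:
        if not seen or g != seen[-1]:
            seen.append(g)
    for a, b in zip(seen[:-1], seen[1:]):
        add([(a, 1.0), (b, -1.0)], 0.0)

    def curvature(idx: list[int], xs: np.ndarray, sign: float) -> None:
        # sign=+1: convex (slopes nondecreasing); -1: concave
        for j in range(len(idx) - 2):
            a, b, cc = idx[j], idx[j + 1], idx[j + 2]
            d1 = xs[j + 1] - xs[j]
            d2 = xs[j + 2] - xs[j + 1]
            # sign * ((g_b-g_a)/d1 - (g_c-g_b)/d2) <= 0
            add(
                [(a, -sign / d1), (b, sign / d1 + sign / d2), (cc, -sign / d2)],
                0.0,
            )

    left_idx = [gvar(i, "left") for i in range(k)]
    curvature(left_idx, v[:k], +1.0)
    right_idx = [gvar(i, "right") for i in range(k - 1 if split else k, u)]
    curvature(right_idx, v[k - 1 if split else k:], -1.0)

    A = coo_matrix((data, (rows, cols)), shape=(len(rhs), nv))
    cvec = np.zeros(nv)
    cvec[ti] = 1.0
    bounds = [(0.0, 1.0)] * (nv - 1) + [(0.0, None)]
    res = linprog(cvec, A_ub=A.tocsr(), b_ub=np.array(rhs), bounds=bounds,
                  method="highs")
    if not res.success:  # pragma: no cover - LP is always feasible
        raise RuntimeError(f"dip LP failed: {res.message}")
    return float(res.fun)


def dip_statistic(values) -> float:
    """Exact dip statistic of a 1-D sample (requires n >= 4)."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 4:
        raise ValueError(f"dip statistic needs at least 4 points, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise ValueError("dip statistic requires finite values")
    v, c = _collapse(values)
    u = len(v)
    if u == 1:
        return 0.0  # a single point mass is perfectly unimodal
    c_hi = c  # ECDF value at v_i
    c_lo = np.concatenate([[0.0], c[:-1]])  # pre-jump ECDF value

    # decoupled hull lower bounds per mode position, for pruning
    cands: list[tuple[float, int, bool]] = []
    for k in range(u + 1):  # mode in the gap after the k-th value
        lb = max(
            _side_bound(v[:k], c_hi[:k], c_lo[:k], convex=True),
            _side_bound(v[k:], c_hi[k:], c_lo[k:], convex=False),
        )
        cands.append((lb, k, False))
    for k in range(1, u + 1):  # mode exactly at the k-th value
        lb = max(
            _side_bound(v[: k - 1], c_hi[: k - 1], c_lo[: k - 1], convex=True),
            _side_bound(v[k:], c_hi[k:], c_lo[k:], convex=False),
        )
        cands.append((lb, k, True))

    cands.sort(key=lambda item: item[0])
    best = np.inf
    for lb, k, split in cands:
        if lb >= best:
            break
        best = min(best, _mode_lp(v, c_lo, c_hi, k, split))
    return float(best)
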