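"""Hartigan & Hartigan's dip statistic of unimodality, implemented from scratch.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and the set of unimodal CDFs (nondecreasing, convex up to some mode,
concave after it, with at most one atom, at the mode). Large values indicate
multimodality; the statistic lies in [1/(2n), 0.25], the maximum being
attained by two equal point masses.

Algorithm
---------
The dip is computed by bisection on the half-bandwidth ``h = n*b`` (count
units). For a candidate ``h``, a unimodal CDF fits inside the band
``[F_n - b, F_n + b]`` iff there is a mode position (a data point, where the
CDF may jump, or a point inside a gap between data values) such that

* the convex part fits under the pre-step counts and over the post-step
  counts left of the mode (prefix consistency),
* mirror condition right of the mode (suffix consistency),
* the minimal convex extension reaching the mode stays below the band cap
  there and below the maximal admissible start of the concave part (the
  cross condition coupling both sides through the mode).

All three reduce to conditions on one line per data block: the max-slope
line from the block's post-step count to the lower convex hull of earlier
pre-step counts (and its mirror image). Prefix consistency is checked with
a Li Chao tree (max-of-lines envelope over the sorted support); the cross
condition is the minimum of a convex piecewise-linear function of the mode
position, located by derivative-sign bisection with active-line jumps.

The implementation is exhaustively validated against a brute-force
minimizer over unimodal CDFs in the test suite.

P-values are calibrated by Monte Carlo against the uniform null, the
asymptotically least favourable unimodal distribution.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


_EPS = 1e-12
_BIG = 1e300


@njit(cache=True)
def _lichao_insert(xs, node_a, node_s, node_used, a, s, k):
    """Insert line y = a + s*x into a Li Chao max-tree over positions xs[0:k]."""
    node = 1
    lo = 0
    hi = k - 1
    while True:
        if not node_used[node]:
            node_a[node] = a
            node_s[node] = s
            node_used[node] = True
            return
        mid = (lo + hi) // 2
        xm = xs[mid]
        if a + s * xm > node_a[node] + node_s[node] * xm:
            ta = node_a[node]
            ts = node_s[node]
            node_a[node] = a
            node_s[node] = s
            a = ta
            s = ts
        if lo == hi:
            return
        xl = xs[lo]
        if a + s * xl > node_a[node] + node_s[node] * xl:
            node = 2 * node
            hi = mid
        else:
            node = 2 * node + 1
            lo = mid + 1


@njit(cache=True)
def _lichao_query(xs, node_a, node_s, node_used, j, k):
    """Max over inserted lines at position xs[j]."""
    node = 1
    lo = 0
    hi = k - 1
    best = -_BIG
    x = xs[j]
    while True:
        if node_used[node]:
            val = node_a[node] + node_s[node] * x
            if val > best:
                best = val
        if lo == hi:
            return best
        mid = (lo + hi) // 2
        if j <= mid:
            node = 2 * node
            hi = mid
        else:
            node = 2 * node + 1
            lo = mid + 1


@njit(cache=True)
def _best_lines(v, Cpre, C, h, a, s, used, env, na, ns, nu):
    """For each block j, the max-slope line from (v_j, C_j - h) to the lower
    convex hull of the upper points (v_i, Cpre_i + h), i < j; the envelope
    value env[j] = max of those lines at v_j (over j' < j); and the first
    block at which the prefix is internally inconsistent (the horizon)."""
    k = v.shape[0]
    hull = np.empty(k, np.int64)
    hull[0] = 0
    nh = 1
    env[0] = -_BIG
    for j in range(1, k):
        env[j] = _lichao_query(v, na, ns, nu, j, k)
        if env[j] > Cpre[j] + h + _EPS:
            return j
        Lj = C[j] - h
        best = -_BIG
        for ti in range(nh):
            t = hull[ti]
            sl = (Lj - (Cpre[t] + h)) / (v[j] - v[t])
            if sl > best:
                best = sl
        s[j] = best
        a[j] = Lj - best * v[j]
        used[j] = True
        _lichao_insert(v, na, ns, nu, a[j], s[j], k)
        Uj = Cpre[j] + h
        while nh >= 2:
            t1 = hull[nh - 2]
            t2 = hull[nh - 1]
            if ((Cpre[t2] + h) - (Cpre[t1] + h)) * (v[j] - v[t1]) >= (
                Uj - (Cpre[t1] + h)
            ) * (v[t2] - v[t1]):
                nh -= 1
            else:
                break
        hull[nh] = j
        nh += 1
    return k


@njit(cache=True)
def _try_gap_mode(p, k, v, C, h, aL, sL, uL, aR, sR, uR, span):
    Cp = C[p - 1] if p > 0 else 0.0
    lo = v[p - 1] if p > 0 else v[0] - span
    hi = v[p] if p < k else v[k - 1] + span
    # A conditions: left lines stay below the band cap at the mode
    for j in range(1, p):
        if uL[j]:
            rhs = Cp + h + _EPS
            if sL[j] > 0:
                t2 = (rhs - aL[j]) / sL[j]
                if t2 < hi:
                    hi = t2
            elif sL[j] < 0:
                t2 = (rhs - aL[j]) / sL[j]
                if t2 > lo:
                    lo = t2
            elif aL[j] > rhs:
                return False
        if lo > hi:
            return False
    # B conditions: right lines stay above the band floor at the mode
    for j in range(p, k):
        if uR[j]:
            rhs = Cp - h - _EPS
            if sR[j] > 0:
                t2 = (rhs - aR[j]) / sR[j]
                if t2 > lo:
                    lo = t2
            elif sR[j] < 0:
                t2 = (rhs - aR[j]) / sR[j]
                if t2 < hi:
                    hi = t2
            elif aR[j] < rhs:
                return False
        if lo > hi:
            return False
    nl = 0
    for j in range(1, p):
        if uL[j]:
            nl += 1
    nr = 0
    for j in range(p, k):
        if uR[j]:
            nr += 1
    if nl == 0 or nr == 0:
        return True
    # cross condition: min over mu in [lo, hi] of f(mu) = maxL(mu) - minR(mu) <= 0.
    # f is convex piecewise-linear. The difference of the two active lines at
    # any point is a global linear lower bound on f, so a single evaluation
    # can certify infeasibility over the whole window; otherwise bisect on
    # the derivative sign.
    x0 = lo
    x1 = hi
    for _ in range(64):
        xm = 0.5 * (x0 + x1)
        fl = -_BIG
        sl_act = 0.0
        for j in range(1, p):
            if uL[j]:
                val = aL[j] + sL[j] * xm
                if val > fl:
                    fl = val
                    sl_act = sL[j]
        fr = _BIG
        sr_act = 0.0
        for j in range(p, k):
            if uR[j]:
                val = aR[j] + sR[j] * xm
                if val < fr:
                    fr = val
                    sr_act = sR[j]
        fm = fl - fr
        if fm <= _EPS:
            return True
        ds = sl_act - sr_act
        # tangent lower bound over the remaining bracket
        gl = fm + ds * (x0 - xm)
        gr = fm + ds * (x1 - xm)
        if gl > _EPS and gr > _EPS:
            return False
        if ds < 0.0:
            x0 = xm
        else:
            x1 = xm
        if x1 - x0 < 1e-14 * span:
            break
    return False


@njit(cache=True)
def _feasible(v, C, h, warm):
    """Does a unimodal CDF fit in the band of half-width h (count units)?

    Returns (ok, mode) with mode < k a data-point mode, mode >= k a gap
    index (mode - k); ``warm`` is a mode hint tried first.
    """
    k = v.shape[0]
    n = C[k - 1]
    n_over = 0
    over_idx = -1
    for t in range(k):
        c = C[t] - (C[t - 1] if t > 0 else 0.0)
        if c > 2.0 * h + _EPS:
            n_over += 1
            over_idx = t
    if n_over > 1:
        return False, -1
    Cpre = np.empty(k)
    for t in range(k):
        Cpre[t] = C[t - 1] if t > 0 else 0.0
    nseg = 1
    while nseg < k:
        nseg *= 2
    na = np.zeros(4 * nseg)
    ns = np.zeros(4 * nseg)
    nu = np.zeros(4 * nseg, np.bool_)
    aL = np.zeros(k)
    sL = np.zeros(k)
    uL = np.zeros(k, np.bool_)
    envL = np.empty(k)
    LH = _best_lines(v, Cpre, C, h, aL, sL, uL, envL, na, ns, nu)
    # mirror: x -> -x reversed, heights y -> n - y
    v2 = np.empty(k)
    C2 = np.empty(k)
    Cpre2 = np.empty(k)
    for t in range(k):
        v2[t] = -v[k - 1 - t]
    acc = 0.0
    for t in range(k):
        cnt = C[k - 1 - t] - (C[k - 2 - t] if k - 2 - t >= 0 else 0.0)
        acc += cnt
        C2[t] = acc
        Cpre2[t] = acc - cnt
    na[:] = 0.0
    ns[:] = 0.0
    nu[:] = False
    a2 = np.zeros(k)
    s2 = np.zeros(k)
    u2 = np.zeros(k, np.bool_)
    env2 = np.empty(k)
    RH2 = _best_lines(v2, Cpre2, C2, h, a2, s2, u2, env2, na, ns, nu)
    aR = np.zeros(k)
    sR = np.zeros(k)
    uR = np.zeros(k, np.bool_)
    for t in range(k):
        j = k - 1 - t
        if u2[t]:
            uR[j] = True
            aR[j] = n - a2[t]
            sR[j] = s2[t]
    RH = k - RH2
    span = v[k - 1] - v[0] + 1.0
    # point modes: the envelope values computed during the sweeps are exactly
    # the cap conditions at a data-point mode, so each check is O(1).
    # Feasible iff m < LH (prefix + cap), k-1-m < RH2 (suffix + floor, i.e.
    # m >= RH), tie blocks other than m small enough, and the two envelopes
    # are compatible (the cross condition through the jump at the mode).
    m_lo = RH if RH > 0 else 0
    m_hi = min(LH, k) - 1
    if warm >= 0 and warm < k and m_lo <= warm <= m_hi:
        m = warm
        if (n_over == 0 or over_idx == m) and envL[m] + env2[k - 1 - m] <= n + _EPS:
            return True, m
    for m in range(m_lo, m_hi + 1):
        if n_over == 1 and over_idx != m:
            continue
        if envL[m] + env2[k - 1 - m] <= n + _EPS:
            return True, m
    if n_over == 1:
        return False, -1
    if warm >= k:
        p = warm - k
        if RH <= p <= min(LH, k):
            if _try_gap_mode(p, k, v, C, h, aL, sL, uL, aR, sR, uR, span):
                return True, warm
    for p in range(RH, min(LH, k) + 1):
        if _try_gap_mode(p, k, v, C, h, aL, sL, uL, aR, sR, uR, span):
            return True, k + p
    return False, -1


@njit(cache=True)
def _dip_bisect(v, C):
    k = v.shape[0]
    n = C[k - 1]
    if k == 1:
        return 0.5 / n
    lo = 0.0
    hi = n / 4.0 + 1.0
    warm = -1
    for it in range(100):
        if hi - lo < 1e-13 * n and it > 40:
            break
        mid = 0.5 * (lo + hi)
        ok, mode = _feasible(v, C, mid, warm)
        if ok:
            hi = mid
            warm = mode
        else:
            lo = mid
    return hi / n


def dip_statistic(values) -> float:
    """Hartigan's dip statistic of a univariate sample.

    Parameters
    ----------
    values : array-like
        At least 4 finite observations, any order.

    Returns
    -------
    float
        The dip, in ``[1/(2n), 0.25]``. A constant sample is degenerate and
        returns the minimal dip ``1/(2n)`` for its size.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 4:
        raise ValueError(f"dip statistic requires at least 4 observations, got {n}")
    if not np.isfinite(x).all():
        raise ValueError("dip statistic requires finite values")
    v, counts = np.unique(x, return_counts=True)
    C = np.cumsum(counts).astype(float)
    return float(_dip_bisect(v, C))


_NULL_TABLE_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def dip_null_table(n: int, B: int, rng_seed: int) -> np.ndarray:
    """Sorted dip statistics of ``B`` uniform samples of size ``n``.

    The uniform distribution is the asymptotically least favourable unimodal
    null, so these tables calibrate a conservative test of unimodality.
    Tables are cached per (n, B, rng_seed).
    """
    key = (int(n), int(B), int(rng_seed))
    tab = _NULL_TABLE_CACHE.get(key)
    if tab is None:
        rng = np.random.default_rng(rng_seed)
        tab = np.empty(B)
        for b in range(B):
            u = np.sort(rng.random(n))
            C = np.arange(1.0, n + 1.0)
            tab[b] = _dip_bisect(u, C)
        tab.sort()
        _NULL_TABLE_CACHE[key] = tab
    return tab


def dip_pvalue(dip_stat: float, n: int, B: int = 2000, rng_seed: int = 0) -> float:
    """Monte-Carlo p-value of a dip statistic against the uniform null.

    ``p = (1 + #{null dips >= dip_stat}) / (B + 1)``, so p is always in
    ``[1/(B+1), 1]``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    tab = dip_null_table(n, B, rng_seed)
    n_ge = tab.size - np.searchsorted(tab, dip_stat, side="left")
    return float((1 + n_ge) / (B + 1))
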