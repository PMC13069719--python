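"""Brute-force reference for the dip statistic, independent of the package.

Computes min over unimodal CDFs of the sup-norm distance to the empirical
CDF by direct enumeration: for every candidate mode placement (each data
value, or the open gap between adjacent values), it checks whether a
convex-then-concave CDF fits inside the band of half-width b around the
ECDF, enumerating *all* pair/triple chord constraints and minimising the
cross-coupling over the mode position exactly (the coupling is the max of
finitely many lines minus the min of finitely many lines of the mode
position; its minimum is attained at an envelope breakpoint or window
endpoint, all of which are enumerated). Bisection on b gives the dip.

Intended for small n (the exhaustive comparisons use n <= 12); complexity
is cubic in the number of distinct values per feasibility check.
"""

import itertools

import numpy as np

_EPS = 1e-12


def _pair_lines(v, C, h):
    """Lines through (v_i, Cpre_i + h) and (v_j, C_j - h) for all i < j.

    Returns (intercepts a, slopes s, i index, j index) as flat arrays.
    """
    k = len(v)
    Cpre = np.concatenate(([0.0], C[:-1]))
    ii, jj = np.triu_indices(k, 1)
    y1 = Cpre[ii] + h
    y2 = C[jj] - h
    s = (y2 - y1) / (v[jj] - v[ii])
    a = y1 - s * v[ii]
    return a, s, ii, jj


def _prefix_horizon(v, C, h, a, s, ii, jj):
    """Largest p such that blocks 0..p-1 admit a convex band fit."""
    k = len(v)
    for l in range(2, k):
        mask = jj < l
        if not mask.any():
            continue
        vals = a[mask] + s[mask] * v[l]
        cap = (C[l - 1] if l > 0 else 0.0) + h
        if np.any(vals > cap + _EPS):
            return l
    return k


def _feasible(v, C, h):
    k = len(v)
    n = C[-1]
    cnt = np.diff(np.concatenate(([0.0], C)))
    Cpre = np.concatenate(([0.0], C[:-1]))
    a, s, ii, jj = _pair_lines(v, C, h)

    LH = _prefix_horizon(v, C, h, a, s, ii, jj)
    # mirror for the suffix
    vm = -v[::-1]
    cm = cnt[::-1]
    Cm = np.cumsum(cm)
    am, sm, iim, jjm = _pair_lines(vm, Cm, h)
    RH2 = _prefix_horizon(vm, Cm, h, am, sm, iim, jjm)
    RH = k - RH2
    # map mirrored lines back: x -> -x, y -> n - y keeps slope, a -> n - a
    aR = n - am
    sR = sm
    jR = k - 1 - iim   # original left endpoint of the mirrored pair
    iR = k - 1 - jjm   # original lower endpoint

    oversized = np.where(cnt > 2 * h + _EPS)[0]
    if len(oversized) > 1:
        return False

    # point modes (a tie block at the mode is absorbed by the CDF's jump)
    for m in range(RH, min(LH, k - 1) + 1):
        if m >= k:
            break
        if len(oversized) and not (len(oversized) == 1 and oversized[0] == m):
            continue
        maskL = jj <= m - 1
        lvals = a[maskL] + s[maskL] * v[m] if maskL.any() else np.array([])
        if lvals.size and np.any(lvals > Cpre[m] + h + _EPS):
            continue
        maskR = iR >= m + 1
        rvals = aR[maskR] + sR[maskR] * v[m] if maskR.any() else np.array([])
        if rvals.size and np.any(rvals < C[m] - h - _EPS):
            continue
        lmax = lvals.max() if lvals.size else -np.inf
        rmin = rvals.min() if rvals.size else np.inf
        if lmax <= rmin + _EPS:
            return True

    if len(oversized):
        return False

    span = v[-1] - v[0] + 1.0
    for p in range(RH, min(LH, k) + 1):
        Cp = C[p - 1] if p > 0 else 0.0
        lo = v[p - 1] if p > 0 else v[0] - 10 * span
        hi = v[p] if p < k else v[-1] + 10 * span
        maskL = jj <= p - 1
        maskR = iR >= p
        aL_, sL_ = a[maskL], s[maskL]
        aR_, sR_ = aR[maskR], sR[maskR]
        # band cap / floor conditions at the mode restrict the mode window
        for aa, ssx in zip(aL_, sL_):
            rhs = Cp + h + _EPS
            if ssx > 0:
                hi = min(hi, (rhs - aa) / ssx)
            elif ssx < 0:
                lo = max(lo, (rhs - aa) / ssx)
            elif aa > rhs:
                lo = np.inf
        for aa, ssx in zip(aR_, sR_):
            rhs = Cp - h - _EPS
            if ssx > 0:
                lo = max(lo, (rhs - aa) / ssx)
            elif ssx < 0:
                hi = min(hi, (rhs - aa) / ssx)
            elif aa < rhs:
                lo = np.inf
        if lo > hi:
            continue
        if aL_.size == 0 or aR_.size == 0:
            return True
        # minimise f(mu) = max of left lines - min of right lines over [lo, hi]
        cands = [lo, hi]
        for (a1, s1), (a2, s2) in itertools.chain(
            itertools.combinations(zip(aL_, sL_), 2),
            itertools.combinations(zip(aR_, sR_), 2),
        ):
            if s1 != s2:
                x = (a2 - a1) / (s1 - s2)
                if lo <= x <= hi:
                    cands.append(x)
        mus = np.asarray(cands)
        fl = (aL_[:, None] + sL_[:, None] * mus[None, :]).max(axis=0)
        fr = (aR_[:, None] + sR_[:, None] * mus[None, :]).min(axis=0)
        if np.min(fl - fr) <= _EPS:
            return True
    return False


def dip_bruteforce(x) -> float:
    """Reference dip of a sample by bisection + exhaustive feasibility."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    v, counts = np.unique(x, return_counts=True)
    C = np.cumsum(counts).astype(float)
    if len(v) == 1:
        return 1.0 / (2 * n)
    lo, hi = 0.0, n / 4.0 + 1.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _feasible(v, C, mid):
            hi = mid
        else:
            lo = mid
    return hi / n
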