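"""Hartigan & Hartigan dip statistic.

The dip of a sample is the maximum distance between its empirical CDF
and the closest unimodal CDF. It is computed by the classical iteration
on the greatest convex minorant (GCM) and least concave majorant (LCM)
of the ECDF over a shrinking modal interval: find the largest vertical
gap between the two hulls, record the deviation of the ECDF from each
hull outside the gap's modal interval, shrink the interval to the gap
end-points, and stop when the hull gap no longer exceeds the recorded
deviation. All distances are kept in counts (units of 1/n) and halved
at the end.

The core loop is JIT-compiled with numba when available; the pure-Python
fallback is identical code. Correctness is pinned in the test suite
against a brute-force linear-programming oracle that minimizes the
sup-distance over piecewise-linear unimodal CDFs directly.
"""

from __future__ import annotations

import numpy as np


def _diptst(x: np.ndarray) -> float:
    """Dip of a sorted (ascending) 1-D float array. Minimum value 1/(2n)."""
    n = x.shape[0]
    dip = 1.0  # in count units; divided by 2n on return
    if n >= 2 and x[n - 1] != x[0]:
        # 1-based arrays mirroring the classical algorithm
        xx = np.empty(n + 1, dtype=np.float64)
        xx[1:] = x
        mn = np.empty(n + 1, dtype=np.int64)
        mj = np.empty(n + 1, dtype=np.int64)
        gcm = np.empty(n + 2, dtype=np.int64)
        lcm = np.empty(n + 2, dtype=np.int64)

        # mn[j]: previous vertex of the GCM chain ending at j
        mn[1] = 1
        for j in range(2, n + 1):
            mn[j] = j - 1
            while True:
                mnj = mn[j]
                if mnj == 1:
                    break
                mnmnj = mn[mnj]
                if (xx[j] - xx[mnj]) * (mnj - mnmnj) < (xx[mnj] - xx[mnmnj]) * (
                    j - mnj
                ):
                    break
                mn[j] = mnmnj
        # mj[k]: next vertex of the LCM chain starting at k
        mj[n] = n
        for k in range(n - 1, 0, -1):
            mj[k] = k + 1
            while True:
                mjk = mj[k]
                if mjk == n:
                    break
                mjmjk = mj[mjk]
                if (xx[k] - xx[mjk]) * (mjk - mjmjk) < (xx[mjk] - xx[mjmjk]) * (
                    k - mjk
                ):
                    break
                mj[k] = mjmjk

        low = 1
        high = n
        while True:
            # GCM change points from high down to low
            gcm[1] = high
            i = 1
            while gcm[i] > low:
                gcm[i + 1] = mn[gcm[i]]
                i += 1
            l_gcm = i
            ig = i
            ix = l_gcm - 1
            # LCM change points from low up to high
            lcm[1] = low
            i = 1
            while lcm[i] < high:
                lcm[i + 1] = mj[lcm[i]]
                i += 1
            l_lcm = i
            ih = i
            iv = 2

            # largest vertical gap between the hulls, scanning low -> high
            d = 0.0
            if l_gcm != 2 or l_lcm != 2:
                while True:
                    gcmix = gcm[ix]
                    lcmiv = lcm[iv]
                    if gcmix > lcmiv:
                        # next vertex comes from the LCM: gap at that vertex
                        gcmi1 = gcm[ix + 1]
                        dx = (lcmiv - gcmi1 + 1) - (xx[lcmiv] - xx[gcmi1]) * (
                            gcmix - gcmi1
                        ) / (xx[gcmix] - xx[gcmi1])
                        iv += 1
                        if dx >= d:
                            d = dx
                            ig = ix + 1
                            ih = iv - 1
                    else:
                        # next vertex comes from the GCM: gap at that vertex
                        lcmiv1 = lcm[iv - 1]
                        dx = (xx[gcmix] - xx[lcmiv1]) * (lcmiv - lcmiv1) / (
                            xx[lcmiv] - xx[lcmiv1]
                        ) - (gcmix - lcmiv1 - 1)
                        ix -= 1
                        if dx > d:
                            d = dx
                            ig = ix + 1
                            ih = iv
                    if ix < 1:
                        ix = 1
                    if iv > l_lcm:
                        iv = l_lcm
                    if gcm[ix] == lcm[iv]:
                        break
            else:
                d = 1.0
            if d < dip:
                break

            # deviation of the ECDF above the GCM on [low, gcm[ig]]
            dip_l = 0.0
            for j in range(ig, l_gcm):
                max_t = 1.0
                jb = gcm[j + 1]
                je = gcm[j]
                if je - jb > 1 and xx[je] != xx[jb]:
                    c = (je - jb) / (xx[je] - xx[jb])
                    for i2 in range(jb + 1, je + 1):
                        # GCM chord runs through lower corners (height j-1)
                        t = (i2 - jb + 1) - (xx[i2] - xx[jb]) * c
                        if max_t < t:
                            max_t = t
                if dip_l < max_t:
                    dip_l = max_t
            # deviation of the ECDF below the LCM on [lcm[ih], high]
            dip_u = 0.0
            for j in range(ih, l_lcm):
                max_t = 1.0
                jb = lcm[j]
                je = lcm[j + 1]
                if je - jb > 1 and xx[je] != xx[jb]:
                    c = (je - jb) / (xx[je] - xx[jb])
                    for i2 in range(jb + 1, je + 1):
                        t = (xx[i2] - xx[jb]) * c - (i2 - jb - 1)
                        if max_t < t:
                            max_t = t
                if dip_u < max_t:
                    dip_u = max_t

            dipnew = dip_l if dip_l > dip_u else dip_u
            if dip < dipnew:
                dip = dipnew
            if low == gcm[ig] and high == lcm[ih]:
                break
            low = gcm[ig]
            high = lcm[ih]
    return dip / (2.0 * n)


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _diptst_jit = njit(cache=False)(_diptst)

    def dip_sorted(x: np.ndarray) -> float:
        return float(_diptst_jit(np.ascontiguousarray(x, dtype=np.float64)))

except ImportError:  # pragma: no cover

    def dip_sorted(x: np.ndarray) -> float:
        return float(_diptst(np.asarray(x, dtype=np.float64)))
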