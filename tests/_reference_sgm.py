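"""Loop-based brute-force reference for the semi-global matcher.

Implements the same contract as ``kelpyield.stereo_depth`` — SAD block
costs with an out-of-bounds sentinel, per-direction dynamic-programming
path costs, winner-takes-all with uniqueness test and three-point subpixel
refinement — but with direct nested loops and no vectorization, so it can
serve as an independent oracle.  All intermediate quantities are
integer-valued in float64 (images are 8-bit, penalties integer), so the
vectorized implementation must agree pixel-exactly.
"""

import numpy as np

from kelpyield.stereo_depth import _DIRECTION_SETS, OOB_COST_PER_PX, SgmParams


def ref_matching_cost(left, right, params: SgmParams):
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    h, w = left.shape
    d_min, d_max = params.disparity_range
    nd = d_max - d_min + 1
    b = params.block_size
    lo, hi = (b - 1) // 2, b // 2
    ad = np.empty((h, w, nd))
    for y in range(h):
        for x in range(w):
            for k in range(nd):
                d = d_min + k
                if x - d >= 0:
                    ad[y, x, k] = abs(left[y, x] - right[y, x - d])
                else:
                    ad[y, x, k] = OOB_COST_PER_PX
    cost = np.zeros((h, w, nd))
    for y in range(h):
        for x in range(w):
            ys = range(max(0, y - lo), min(h, y + hi + 1))
            xs = range(max(0, x - lo), min(w, x + hi + 1))
            for k in range(nd):
                cost[y, x, k] = sum(ad[yy, xx, k] for yy in ys for xx in xs)
    return cost


def ref_aggregate(cost, params: SgmParams):
    h, w, nd = cost.shape
    p1, p2 = params.p1, params.p2
    agg = np.zeros_like(cost)
    for dy, dx in _DIRECTION_SETS[params.n_paths]:
        L = np.zeros_like(cost)
        if dy == 0:
            order = [(y, x) for x in (range(w) if dx == 1 else range(w - 1, -1, -1))
                     for y in range(h)]
        else:
            order = [(y, x) for y in (range(h) if dy == 1 else range(h - 1, -1, -1))
                     for x in range(w)]
        for y, x in order:
            py, px = y - dy, x - dx
            if not (0 <= py < h and 0 <= px < w):
                L[y, x, :] = cost[y, x, :]
                continue
            prev = L[py, px, :]
            m = prev.min()
            for k in range(nd):
                best = min(
                    prev[k],
                    (prev[k - 1] + p1) if k - 1 >= 0 else np.inf,
                    (prev[k + 1] + p1) if k + 1 < nd else np.inf,
                    m + p2,
                )
                L[y, x, k] = cost[y, x, k] + best - m
        agg += L
    return agg


def ref_select(agg, params: SgmParams, raw_cost=None):
    h, w, nd = agg.shape
    d_min, _ = params.disparity_range
    values = np.zeros((h, w))
    valid = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            costs = agg[y, x, :]
            k = int(np.argmin(costs))  # ties -> lowest disparity
            best = costs[k]
            ok = best < params.oob_cost
            if ok and params.uniqueness_ratio > 0:
                rest = [costs[j] for j in range(nd) if abs(j - k) > 1]
                second = min(rest) if rest else np.inf
                ok = second > best * (1.0 + params.uniqueness_ratio)
            if ok and raw_cost is not None and params.min_data_margin > 0:
                raw = raw_cost[y, x, :]
                lo = (params.block_size - 1) // 2
                subset = [raw[j] for j in range(nd)
                          if d_min + j <= x - lo]
                if not subset or d_min + k > x - lo:
                    ok = False
                else:
                    margin = (np.median(subset) - raw[k]) / params.block_area
                    ok = margin >= params.min_data_margin
            off = 0.0
            if params.subpixel and 0 < k < nd - 1:
                cm, c0, cp = costs[k - 1], costs[k], costs[k + 1]
                if params.subpixel_method == "parabola":
                    denom = cm - 2.0 * c0 + cp
                else:
                    denom = max(cm, cp) - c0
                if denom > 0:
                    off = min(0.5, max(-0.5, (cm - cp) / (2.0 * denom)))
            values[y, x] = d_min + k + off
            valid[y, x] = ok
    return values, valid


def ref_compute_disparity(left, right, params: SgmParams):
    cost = ref_matching_cost(left, right, params)
    return ref_select(ref_aggregate(cost, params), params, raw_cost=cost)
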