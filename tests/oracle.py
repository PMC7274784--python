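"""Independent brute-force reference implementations.

Every function here recomputes a statistic from scratch by explicit,
per-bin filtering with direct comparisons — no shared code with the
package's vectorized engine — so the test suite can check the engine
against a second, independently written route.
"""

from __future__ import annotations

import math

import numpy as np


def bin_key(x: float, y: float, width: float, origin: tuple[float, float]):
    return (
        math.floor((x - origin[0]) / width),
        math.floor((y - origin[1]) / width),
    )


def occupied_bins(xs, ys, width, origin):
    keys = set()
    for x, y in zip(xs, ys):
        keys.add(bin_key(x, y, width, origin))
    return keys


def events_in_bin(xs, ys, key, width, origin):
    """Explicit interval filter for one bin: lower-edge inclusive."""
    i, j = key
    x_lo = origin[0] + i * width
    x_hi = origin[0] + (i + 1) * width
    y_lo = origin[1] + j * width
    y_hi = origin[1] + (j + 1) * width
    rows = []
    for r, (x, y) in enumerate(zip(xs, ys)):
        in_x = x_lo <= x < x_hi
        # an event exactly on a shared edge must land in the higher bin only;
        # recompute membership from the floor rule when rounding makes the
        # interval test disagree
        if in_x != (math.floor((x - origin[0]) / width) == i):
            in_x = math.floor((x - origin[0]) / width) == i
        in_y = y_lo <= y < y_hi
        if in_y != (math.floor((y - origin[1]) / width) == j):
            in_y = math.floor((y - origin[1]) / width) == j
        if in_x and in_y:
            rows.append(r)
    return rows


def stat_in_bin(zs, rows, kind, cutoff=None):
    """(n, n_pos, value-or-None) recomputed from scratch for one bin."""
    vals = [zs[r] for r in rows]
    n = len(vals)
    n_pos = sum(1 for v in vals if cutoff is not None and v > cutoff)
    if kind == "density":
        return n, n_pos, float(n)
    if kind == "freq_pos":
        return n, n_pos, 100.0 * n_pos / n if n else None
    if kind == "mfi_all":
        return n, n_pos, sum(vals) / n if n else None
    if kind == "mfi_pos":
        pos = [v for v in vals if v > cutoff]
        return n, n_pos, sum(pos) / len(pos) if pos else None
    if kind == "rsem":
        if n < 2:
            return n, n_pos, None
        m = sum(vals) / n
        if m <= 0:
            return n, n_pos, None
        var = sum((v - m) ** 2 for v in vals) / (n - 1)
        return n, n_pos, (math.sqrt(var) / math.sqrt(n)) / m
    raise ValueError(kind)


def coproducer_in_bin(event_vals, rows, predicates, cutoffs):
    """n and conjunction-satisfying count for one bin, by direct comparison."""
    n_sat = 0
    for r in rows:
        ok = True
        for marker, sign in predicates:
            v = event_vals[marker][r]
            c = cutoffs[marker]
            if sign == "+" and not v > c:
                ok = False
            if sign == "-" and not v <= c:
                ok = False
        n_sat += ok
    return len(rows), n_sat


def quadrants_by_hand(xs, ys, zs, cx, cy, cz):
    """The four percentage families recomputed with explicit loops."""
    total = len(xs)
    total_pos = sum(1 for z in zs if z > cz)
    out = {}
    for key, fx, fy in [
        ("x-y-", lambda x: x < cx, lambda y: y < cy),
        ("x+y-", lambda x: x >= cx, lambda y: y < cy),
        ("x-y+", lambda x: x < cx, lambda y: y >= cy),
        ("x+y+", lambda x: x >= cx, lambda y: y >= cy),
    ]:
        nq = 0
        np_q = 0
        for x, y, z in zip(xs, ys, zs):
            if fx(x) and fy(y):
                nq += 1
                if z > cz:
                    np_q += 1
        out[key] = {
            "n": nq,
            "n_pos": np_q,
            "black": 100.0 * nq / total,
            "red": 100.0 * np_q / nq if nq else 0.0,
            "green": 100.0 * np_q / total,
            "blue": 100.0 * np_q / total_pos if total_pos else 0.0,
        }
    return out


def categories_by_hand(xs, ys, xt, yt, marker_vals=None, marker_cutoffs=None):
    """3x3 category counts (and per-marker positives) by explicit comparison."""
    counts = np.zeros((3, 3), dtype=int)
    pos = {m: np.zeros((3, 3), dtype=int) for m in (marker_vals or {})}

    def level(v, t1, t2):
        if v < t1:
            return 0
        if v < t2:
            return 1
        return 2

    for r, (x, y) in enumerate(zip(xs, ys)):
        a = level(x, xt[0], xt[1])
        b = level(y, yt[0], yt[1])
        counts[a, b] += 1
        for m, vals in (marker_vals or {}).items():
            if vals[r] > marker_cutoffs[m]:
                pos[m][a, b] += 1
    return counts, pos
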