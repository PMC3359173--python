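"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written as plain sample-by-sample loops, sharing no code with
the package internals.
"""

import math

import numpy as np


def naive_candidates(v, window, stringency, min_intensity):
    """Literal transcription of the windowed wall-candidate rule:
    examine the window centered on each sample, store the min and max
    ignoring the sample itself, and mark the sample when it reaches the
    max, exceeds min * stringency and clears the absolute floor."""
    v = [float(x) for x in v]
    n = len(v)
    half = window // 2
    out = []
    for t in range(n):
        neigh = [v[i] for i in range(max(0, t - half), min(n, t + half + 1)) if i != t]
        i_max = max(neigh)
        i_min = min(neigh)
        out.append(v[t] >= i_max and v[t] >= i_min * stringency and v[t] >= min_intensity)
    return np.array(out, dtype=bool)


def naive_walls(v, window, stringency, min_intensity):
    """Candidates -> merged wall positions (fractional indices), as loops:
    group consecutive candidates, place each group at its intensity-weighted
    centroid, then sweep left to right collapsing walls closer than
    ceil(window/2) samples onto the stronger peak."""
    mask = naive_candidates(v, window, stringency, min_intensity)
    groups = []
    current = []
    for i, m in enumerate(mask):
        if m:
            current.append(i)
        elif current:
            groups.append(current)
            current = []
    if current:
        groups.append(current)
    walls = []
    for g in groups:
        wsum = sum(v[i] for i in g)
        if wsum == 0:
            center = sum(g) / len(g)
        else:
            center = sum(i * v[i] for i in g) / wsum
        walls.append((center, max(v[i] for i in g)))
    min_sep = math.ceil(window / 2)
    merged = []
    for w in walls:
        # gaps within 1e-6 of the threshold count as separated (float guard)
        if merged and w[0] - merged[-1][0] < min_sep - 1e-6:
            if w[1] > merged[-1][1]:
                merged[-1] = w
        else:
            merged.append(w)
    return [w[0] for w in merged]


def exhaustive_break_point(xs, ys):
    """1-based interior index with maximum distance to the first-last
    chord, computed point by point from the two-point line formula; ties go
    to the smallest index."""
    xs = [float(x) for x in xs]
    ys = [float(y) for y in ys]
    x1, y1, x2, y2 = xs[0], ys[0], xs[-1], ys[-1]
    denom = math.hypot(x2 - x1, y2 - y1)
    best_i, best_d = None, -1.0
    for i in range(1, len(xs) - 1):
        d = abs((y2 - y1) * xs[i] - (x2 - x1) * ys[i] + x2 * y1 - y2 * x1) / denom
        if d > best_d + 1e-12:
            best_d = d
            best_i = i
    return best_i + 1
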