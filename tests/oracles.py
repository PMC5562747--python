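"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive (pure-Python loops, elementwise scans) and
share no code with the package internals.
"""

from __future__ import annotations


def brute_force_diff(frame_a, frame_b):
    """Per-pixel absolute difference via explicit loops."""
    h = len(frame_a)
    w = len(frame_a[0])
    return [[abs(float(frame_b[y][x]) - float(frame_a[y][x])) for x in range(w)]
            for y in range(h)]


def brute_force_count(grid, tau):
    """Number of entries strictly above tau."""
    return sum(1 for row in grid for v in row if v > tau)


def brute_force_grayscale(frame):
    """Per-pixel luma sum with the standard 0.299/0.587/0.114 weights."""
    h = len(frame)
    w = len(frame[0])
    return [[0.299 * frame[y][x][0] + 0.587 * frame[y][x][1] + 0.114 * frame[y][x][2]
             for x in range(w)] for y in range(h)]


def brute_force_peaks(x, fps, prominence_frac, refractory_s):
    """Exhaustive peak detection per the prominence/spacing definition.

    A candidate is a strict interior local maximum.  Its prominence is the
    peak height minus the larger of the minima reached while scanning
    outward until a strictly higher sample (or the edge).  Candidates with
    prominence >= prominence_frac * dynamic range are accepted greedily in
    order of decreasing prominence (ties -> earlier index) subject to the
    refractory spacing.  Returns sorted accepted indices.
    """
    x = [float(v) for v in x]
    n = len(x)
    if n < 3:
        return []
    rng = max(x) - min(x)
    if rng == 0:
        return []
    candidates = []
    for i in range(1, n - 1):
        if not (x[i] > x[i - 1] and x[i] > x[i + 1]):
            continue
        lmin = x[i]
        j = i - 1
        while j >= 0 and x[j] <= x[i]:
            lmin = min(lmin, x[j])
            j -= 1
        rmin = x[i]
        j = i + 1
        while j < n and x[j] <= x[i]:
            rmin = min(rmin, x[j])
            j += 1
        prom = x[i] - max(lmin, rmin)
        if prom >= prominence_frac * rng:
            candidates.append((i, prom))
    accepted = []
    for i, prom in sorted(candidates, key=lambda c: (-c[1], c[0])):
        if all(abs(i - j) / fps >= refractory_s - 1e-12 for j, _ in accepted):
            accepted.append((i, prom))
    return sorted(i for i, _ in accepted)
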