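"""Independent brute-force oracles used to verify the implementation.

These deliberately re-derive each quantity by the most literal route
(exhaustive enumeration, double loops, nonlinear fits) so they share no
code with the library paths they check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit


def brute_force_peaks(trace, height, distance, prominence):
    """Exhaustive peak detection: strict local maxima filtered by height,
    then greedy-by-height distance suppression, then topographic prominence."""
    x = np.asarray(trace, dtype=float)
    n = x.size
    cand = [i for i in range(1, n - 1) if x[i - 1] < x[i] > x[i + 1]]
    cand = [i for i in cand if x[i] >= height]

    # distance: process candidates from highest; drop any unkept candidate
    # strictly closer than `distance` frames to a kept one
    removed: set[int] = set()
    kept: list[int] = []
    for i in sorted(cand, key=lambda i: x[i], reverse=True):
        if i in removed:
            continue
        kept.append(i)
        for j in cand:
            if j != i and j not in removed and abs(j - i) < distance:
                removed.add(j)
    kept = sorted(set(kept) - removed)

    out = []
    for i in kept:
        # walk to the nearest strictly-higher sample on each side (or edge);
        # the base on that side is the minimum in between
        lo = i
        left_min = x[i]
        j = i - 1
        while j >= 0 and x[j] <= x[i]:
            left_min = min(left_min, x[j])
            j -= 1
        right_min = x[i]
        j = i + 1
        while j < n and x[j] <= x[i]:
            right_min = min(right_min, x[j])
            j += 1
        prom = x[i] - max(left_min, right_min)
        if prom >= prominence:
            out.append(i)
    return np.array(out, dtype=int)


def pairwise_corr_double_loop(x):
    """Pearson correlation matrix by an explicit double loop."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    m = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            a = x[i] - x[i].mean()
            b = x[j] - x[j].mean()
            m[i, j] = (a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum())
    return m


def fit_decay_nonlinear(segment, dt):
    """Direct nonlinear least-squares fit of A * exp(-t/tau) to a segment."""
    y = np.asarray(segment, dtype=float)
    t = np.arange(y.size) * dt
    (A, tau), _ = curve_fit(
        lambda t, A, tau: A * np.exp(-t / tau), t, y,
        p0=(max(y[0], 1.0), 1.0), maxfev=10000,
    )
    return tau


def circular_resultant(phases):
    """Length and mean direction of the resultant vector of phase samples."""
    z = np.exp(1j * np.asarray(phases))
    m = z.mean()
    return np.abs(m), np.angle(m)
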