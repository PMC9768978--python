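"""Independent brute-force reference implementations used as test oracles.

These are written as straight-line Python over plain lists, deliberately
sharing no code with the package internals.
"""

from __future__ import annotations

import math


def bruteforce_network_bursts(times, isi_join, min_candidate, merge_gap, min_final):
    """Direct nested-scan 4-step burst detector.

    Returns a list of (t_start, t_end, n_spikes) with spikes between merged
    candidates counted into the burst.
    """
    times = sorted(float(t) for t in times)
    if not times:
        return []
    # step 1: chain spikes with gaps <= isi_join
    candidates = []
    current = [times[0]]
    for t in times[1:]:
        if t - current[-1] <= isi_join:
            current.append(t)
        else:
            candidates.append(current)
            current = [t]
    candidates.append(current)
    # step 2: minimum candidate size
    candidates = [c for c in candidates if len(c) >= min_candidate]
    # step 3: merge candidates separated by < merge_gap
    merged = []
    for c in candidates:
        if merged and c[0] - merged[-1][-1] < merge_gap:
            merged[-1] = [merged[-1][0], c[-1]]
        else:
            merged.append([c[0], c[-1]])
    # step 4: final size threshold, counting every pooled spike in the span
    out = []
    for start, end in merged:
        n = sum(1 for t in times if start <= t <= end)
        if n > min_final:
            out.append((start, end, n))
    return out


def bruteforce_threshold_events(v, thr, dead_samples, half_align):
    """Plain-loop |v| >= thr upcrossing counter with extremum-anchored dead time.

    Mirrors the documented detection contract: a crossing is a sample at or
    above threshold whose predecessor is below (sample 0 counts if above);
    a crossing is accepted when it lies >= dead_samples after the previous
    event's extremum; the event is the signed extremum within +/-half_align
    samples of the crossing (first maximal |v| wins).
    """
    events = []
    last_extremum = -math.inf
    prev_above = False
    for i, x in enumerate(v):
        above = abs(x) >= thr
        crossing = above and not prev_above
        prev_above = above
        if not crossing or i - last_extremum < dead_samples:
            continue
        lo = max(i - half_align, 0)
        hi = min(i + half_align + 1, len(v))
        best = lo
        for j in range(lo, hi):
            if abs(v[j]) > abs(v[best]):
                best = j
        events.append((best, v[best]))
        last_extremum = best
    return events


def ols_normal_equations(x, y):
    """Closed-form simple OLS (slope, intercept, r_squared) via sums."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(xi * xi for xi in x)
    sxy = sum(xi * yi for xi, yi in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    ybar = sy / n
    ss_res = sum((yi - slope * xi - intercept) ** 2 for xi, yi in zip(x, y))
    ss_tot = sum((yi - ybar) ** 2 for yi in y)
    return slope, intercept, 1.0 - ss_res / ss_tot


def random_spike_set(rng, max_spikes=10_000):
    """Random pooled spike times mixing Poisson background and dense clusters."""
    duration = rng.uniform(20.0, 60.0)
    times = list(rng.uniform(0.0, duration, size=rng.integers(0, 400)))
    n_clusters = int(rng.integers(0, 8))
    for _ in range(n_clusters):
        onset = rng.uniform(0.0, duration - 2.0)
        width = rng.uniform(0.05, 1.0)
        count = int(rng.integers(20, 1500))
        times.extend(rng.uniform(onset, onset + width, size=count))
    times = sorted(times)[:max_spikes]
    return times, duration
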