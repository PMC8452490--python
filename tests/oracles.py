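"""Independent brute-force oracles used to validate the fast implementations.

These deliberately use naive enumeration (O(n^2) or plain-python scans) so
they share no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def burst_oracle(ts, max_isi: float, min_spikes: int):
    """All maximal runs of >= min_spikes spikes with every ISI <= max_isi,
    found by exhaustive O(n^2) enumeration over (start, end) index pairs."""
    ts = list(ts)
    n = len(ts)
    out = []
    for i in range(n):
        for j in range(i + min_spikes - 1, n):
            if all(ts[k + 1] - ts[k] <= max_isi for k in range(i, j)):
                left_max = i == 0 or ts[i] - ts[i - 1] > max_isi
                right_max = j == n - 1 or ts[j + 1] - ts[j] > max_isi
                if left_max and right_max:
                    out.append((ts[i], ts[j], j - i + 1))
    return out


def correlogram_oracle(ta, tb, window: float, bin_width: float):
    """Cross-correlogram by explicit pair counting over every spike pair."""
    k = int(round(window / bin_width))
    counts = np.zeros(2 * k + 1)
    lo = -(k + 0.5) * bin_width
    for x in ta:
        for y in tb:
            idx = math.floor((y - x - lo) / bin_width)
            if 0 <= idx <= 2 * k:
                counts[idx] += 1
    if len(ta) == 0 or len(tb) == 0:
        return counts
    return np.minimum(counts / math.sqrt(len(ta) * len(tb)), 1.0)


def network_burst_oracle(well, bin_width, rate_threshold, min_channel_fraction,
                         merge_gap, participation_min_spikes):
    """Direct plain-python scan of the binned well-wide rate.

    Mirrors the stated contract: supra-threshold bin runs, tightened to first/
    last spike, merged when gaps < merge_gap, kept when strictly more than
    min_channel_fraction of channels contribute >= participation_min_spikes.
    """
    ts = sorted(float(t) for tr in well.trains for t in tr.timestamps)
    if not ts:
        return []
    n_bins = max(1, math.ceil(well.duration / bin_width))
    counts = [0] * n_bins
    for t in ts:
        counts[min(int(t // bin_width), n_bins - 1)] += 1
    thr = rate_threshold * bin_width
    episodes = []
    i = 0
    while i < n_bins:
        if counts[i] > thr:
            j = i
            while j < n_bins and counts[j] > thr:
                j += 1
            inside = [t for t in ts if i * bin_width <= t < j * bin_width]
            if len(inside) >= 2 and inside[-1] > inside[0]:
                episodes.append([inside[0], inside[-1]])
            i = j
        else:
            i += 1
    merged = []
    for s, e in episodes:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        channels = [
            tr.electrode_id for tr in well.trains
            if sum(1 for t in tr.timestamps if s <= t <= e) >= participation_min_spikes
        ]
        if len(channels) / 12 > min_channel_fraction:
            out.append((s, e, frozenset(channels)))
    return out


def noncentral_t_power(d: float, n: int, alpha: float = 0.05) -> float:
    """Two-sample t-test power from the noncentral-t distribution directly."""
    from scipy import stats

    df = 2 * n - 2
    nc = abs(d) * math.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def wells_required_oracle(d: float, alpha: float = 0.05, power: float = 0.8) -> int:
    n = 2
    while noncentral_t_power(d, n, alpha) < power:
        n += 1
    return n
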