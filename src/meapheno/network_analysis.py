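"""Network-burst detection, rate statistics, and burst-shape timing.

A network burst (NB) is a well-wide synchronous event: the pooled firing rate
across all 12 electrodes exceeds a threshold over contiguous time bins, enough
channels participate, and nearby supra-threshold episodes are merged.  From
the NB train we derive:

- NBR (NB/min), NBD (s): rate and mean duration of network bursts;
- NIBI (s): mean gap from one NB's end to the next NB's start;
- CV_NIBI: coefficient of variation (sample SD / mean) of those gaps —
  the regularity of network bursting;
- the aligned NB shape: per-NB well-summed firing-rate profiles from onset,
  averaged, from which rise time (RT) and decay time (DT) are measured as the
  times between the 10%-of-peak crossings and the peak.

The rate threshold defaults to ``max(baseline, peak_fraction * peak rate)``;
detection settings are explicit inputs because correct NB quantification
requires per-recording tuning — under-detection inflates NIBI and CV_NIBI.
For developmental series, settings should be fixed at the latest DIV and
applied backward (:func:`settings_from_latest_div`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, ParameterError
from .io_peaktrains import N_ELECTRODES, WellRecording

logger = logging.getLogger(__name__)


@dataclass
class NetworkBurstSettings:
    """Settings for well-wide network-burst detection.

    rate_threshold is in well-summed spikes/s; when None it is derived as
    ``max(baseline_spikes_per_bin / bin_width, peak_fraction * peak rate)``.
    The peak-relative term is off by default: an absolute floor keeps an NB's
    low-rate tail attached to its burst, whereas a high relative threshold
    strands the tail sub-threshold and fragments one NB into several.
    """

    bin_width: float = 0.025
    rate_threshold: float | None = None
    min_channel_fraction: float = 0.25
    merge_gap: float = 0.3  # sub-second: reattaches NB tails, never bridges NBs
    baseline_spikes_per_bin: float = 1.5
    participation_min_spikes: int = 3  # spikes a channel must contribute to count
    peak_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ParameterError("bin_width must be > 0")
        if not 0 <= self.min_channel_fraction <= 1:
            raise ParameterError("min_channel_fraction must be in [0, 1]")


@dataclass
class NetworkBurst:
    """One network burst: half-open interval with participating channels."""

    start: float
    end: float
    participating_channels: frozenset[int]
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def participation(self) -> float:
        return len(self.participating_channels) / N_ELECTRODES


@dataclass
class NetworkBurstShape:
    """Averaged onset-aligned well-wide firing-rate profile (spikes/s)."""

    bin_width: float
    profile: np.ndarray
    normalization: str = "none"
    n_bursts: int = 0
    t0: float = 0.0  # time of the first bin edge relative to NB onset

    @property
    def times(self) -> np.ndarray:
        """Bin-center times relative to NB onset (negative in the pre-margin)."""
        return self.t0 + (np.arange(self.profile.size) + 0.5) * self.bin_width


def resolve_rate_threshold(well: WellRecording, settings: NetworkBurstSettings) -> float:
    """Effective well-wide rate threshold (spikes/s) for this recording."""
    if settings.rate_threshold is not None:
        return settings.rate_threshold
    baseline = settings.baseline_spikes_per_bin / settings.bin_width
    ts = well.all_spike_times()
    if ts.size == 0:
        return baseline
    n_bins = max(1, int(math.ceil(well.duration / settings.bin_width)))
    counts, _ = np.histogram(ts, bins=n_bins, range=(0.0, n_bins * settings.bin_width))
    peak_rate = counts.max() / settings.bin_width
    return max(baseline, settings.peak_fraction * peak_rate)


def detect_network_bursts(
    well: WellRecording, settings: NetworkBurstSettings | None = None
) -> list[NetworkBurst]:
    """Detect network bursts from the pooled binned firing rate.

    Contiguous supra-threshold bins form candidate episodes; each episode is
    tightened to its first/last spike, episodes closer than ``merge_gap`` are
    merged, and episodes whose channel participation does not exceed
    ``min_channel_fraction`` are discarded.  A channel participates only if it
    contributes at least ``participation_min_spikes`` spikes to the episode;
    a lone stray spike does not make an electrode part of a network event.
    """
    settings = settings or NetworkBurstSettings()
    ts = well.all_spike_times()
    if ts.size == 0:
        return []
    bw = settings.bin_width
    n_bins = max(1, int(math.ceil(well.duration / bw)))
    counts, edges = np.histogram(ts, bins=n_bins, range=(0.0, n_bins * bw))
    thr_per_bin = resolve_rate_threshold(well, settings) * bw
    supra = counts > thr_per_bin

    # contiguous supra-threshold runs -> (start_time, end_time) tightened to spikes
    episodes: list[tuple[float, float]] = []
    i = 0
    while i < n_bins:
        if not supra[i]:
            i += 1
            continue
        j = i
        while j < n_bins and supra[j]:
            j += 1
        lo = np.searchsorted(ts, edges[i], side="left")
        hi = np.searchsorted(ts, edges[j], side="left")
        if hi - lo >= 2 and ts[hi - 1] > ts[lo]:
            episodes.append((float(ts[lo]), float(ts[hi - 1])))
        i = j

    merged: list[list[float]] = []
    for s, e in episodes:
        if merged and s - merged[-1][1] < settings.merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    nbs: list[NetworkBurst] = []
    for s, e in merged:
        channels = frozenset(
            t.electrode_id for t in well.trains
            if np.searchsorted(t.timestamps, e, side="right")
            - np.searchsorted(t.timestamps, s, side="left")
            >= settings.participation_min_spikes
        )
        # strict inequality: exactly 25% of channels is not enough
        if len(channels) / N_ELECTRODES <= settings.min_channel_fraction:
            continue
        n_spikes = int(np.searchsorted(ts, e, side="right") - np.searchsorted(ts, s, side="left"))
        nbs.append(NetworkBurst(s, e, channels, n_spikes))
    return nbs


def network_burst_statistics(nbs: list[NetworkBurst], duration: float) -> dict:
    """NBR, NBD, NIBI, CV_NIBI; fewer than 2 NBs leaves NIBI/CV_NIBI NaN."""
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    flags: list[str] = []
    out = {
        "NBR": len(nbs) / duration * 60.0,
        "NBD": float("nan"),
        "NIBI": float("nan"),
        "CV_NIBI": float("nan"),
    }
    if nbs:
        out["NBD"] = float(np.mean([nb.duration for nb in nbs]))
    else:
        flags.append("NO_NETWORK_BURSTS")
    if len(nbs) >= 2:
        gaps = np.array([b.start - a.end for a, b in zip(nbs, nbs[1:])])
        out["NIBI"] = float(np.mean(gaps))
        if len(gaps) >= 2 and np.mean(gaps) > 0:
            out["CV_NIBI"] = float(np.std(gaps, ddof=1) / np.mean(gaps))
        else:
            flags.append("CV_NIBI_UNDEFINED")
    else:
        flags.append("NIBI_UNDEFINED")
    out["flags"] = flags
    return out


def network_burst_shape(
    well: WellRecording,
    nbs: list[NetworkBurst],
    bin_width: float = 0.005,
    window: float | None = None,
    normalization: str = "none",
    pre_window: float = 0.1,
) -> NetworkBurstShape:
    """Average onset-aligned well-wide firing-rate profile over network bursts.

    ``window`` (s from onset) defaults to 1.5x the longest NB duration.  The
    profile additionally covers ``pre_window`` seconds before onset so the
    rise from baseline is part of the shape (detection trims an NB's start to
    its first supra-threshold spike, which already sits above baseline).
    """
    if not nbs:
        raise AnalysisError(
            "no network bursts: shape undefined (well likely fails QC)"
        )
    if window is None:
        window = 1.5 * max(nb.duration for nb in nbs)
    n_bins = max(1, int(math.ceil((window + pre_window) / bin_width)))
    t0 = -pre_window
    ts = well.all_spike_times()
    acc = np.zeros(n_bins)
    for nb in nbs:
        start = nb.start + t0
        counts, _ = np.histogram(ts, bins=n_bins, range=(start, start + n_bins * bin_width))
        acc += counts
    profile = acc / len(nbs) / bin_width
    if normalization == "peak":
        peak = profile.max()
        if peak > 0:
            profile = profile / peak
    elif normalization != "none":
        raise ParameterError(f"unknown normalization {normalization!r}")
    return NetworkBurstShape(bin_width, profile, normalization, len(nbs), t0=t0)


def rise_decay_times(shape: NetworkBurstShape, lo_frac: float = 0.1) -> dict:
    """Rise and decay times of an averaged NB profile.

    RT: time from the last upward crossing of ``lo_frac * peak`` to the peak;
    DT: time from the peak to the first downward crossing of the same level.
    Crossings are linearly interpolated between bin centers.  Flat-topped
    profiles use the first/last peak bin for RT/DT and are flagged
    DEGENERATE_PLATEAU; a peak on the window edge leaves both NaN, flagged
    PEAK_AT_EDGE.
    """
    p = shape.profile
    t = shape.times
    flags: list[str] = []
    out = {"RT": float("nan"), "DT": float("nan")}
    if p.size < 3 or p.max() <= 0:
        out["flags"] = ["PEAK_AT_EDGE"]
        return out
    peak = p.max()
    peak_idx = np.flatnonzero(p == peak)
    i_first, i_last = int(peak_idx[0]), int(peak_idx[-1])
    if i_first == 0 or i_last == p.size - 1:
        out["flags"] = ["PEAK_AT_EDGE"]
        return out
    if i_last - i_first > 1:
        flags.append("DEGENERATE_PLATEAU")
    lo = lo_frac * peak

    # last upward crossing before the (first) peak bin
    rt_cross = t[0]
    rt_found = False
    for j in range(i_first - 1, -1, -1):
        if p[j] < lo <= p[j + 1]:
            frac = (lo - p[j]) / (p[j + 1] - p[j])
            rt_cross = t[j] + frac * (t[j + 1] - t[j])
            rt_found = True
            break
    if not rt_found:
        flags.append("RT_CLIPPED")
    out["RT"] = float(t[i_first] - rt_cross)

    # downward crossing after the (last) peak bin: taken at the *last*
    # supra-level bin, which coincides with the first crossing on a clean
    # unimodal profile but is immune to single noisy bins dipping early
    above = np.flatnonzero(p >= lo)
    j = int(above[-1])
    if j >= p.size - 1:
        flags.append("DT_CLIPPED")
        dt_cross = t[-1]
    else:
        frac = (p[j] - lo) / (p[j] - p[j + 1])
        dt_cross = t[j] + frac * (t[j + 1] - t[j])
    out["DT"] = float(dt_cross - t[i_last])
    out["flags"] = flags
    return out


def settings_from_latest_div(
    wells_by_div: dict[int, WellRecording], settings: NetworkBurstSettings
) -> NetworkBurstSettings:
    """Fix NB detection settings at the latest DIV of a developmental series.

    The threshold resolved on the latest-DIV recording is frozen into the
    returned settings so earlier DIVs are analyzed with identical settings.
    """
    if not wells_by_div:
        raise ParameterError("empty developmental series")
    latest = wells_by_div[max(wells_by_div)]
    thr = resolve_rate_threshold(latest, settings)
    return NetworkBurstSettings(
        bin_width=settings.bin_width,
        rate_threshold=thr,
        min_channel_fraction=settings.min_channel_fraction,
        merge_gap=settings.merge_gap,
        baseline_spikes_per_bin=settings.baseline_spikes_per_bin,
        peak_fraction=settings.peak_fraction,
    )


__all__ = [
    "NetworkBurst", "NetworkBurstSettings", "NetworkBurstShape",
    "detect_network_bursts", "network_burst_statistics", "network_burst_shape",
    "rise_decay_times", "resolve_rate_threshold", "settings_from_latest_div",
]
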