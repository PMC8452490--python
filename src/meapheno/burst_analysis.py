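"""Single-channel burst detection and channel-level activity parameters.

Bursts are detected with the max-interval ("string") method: a burst is a
maximal run of at least ``min_spikes`` consecutive spikes on one electrode in
which every inter-spike interval is at most ``max_isi`` (inclusive).  Burst
start/end are the first/last spike times of the run.

Channel-level parameters derived here:

- MFR: mean firing rate, total spikes / duration / 12 electrode slots.
  Silent electrodes count — the all-electrode rule; restricting the analysis
  to active electrodes inflates every rate parameter.
- PRS: percentage of random spikes, i.e. spikes outside every detected
  single-channel burst.
- BR (bursts/min), BD (s), BSR (spikes/s within bursts), IBI (s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .io_peaktrains import N_ELECTRODES, SpikeTrain, WellRecording

logger = logging.getLogger(__name__)


@dataclass
class BurstSettings:
    """Max-interval burst detection settings (explicit, tunable inputs)."""

    max_isi: float = 0.1
    min_spikes: int = 5

    def __post_init__(self) -> None:
        if self.max_isi <= 0:
            raise ParameterError("max_isi must be > 0")
        if self.min_spikes < 2:
            raise ParameterError("min_spikes must be >= 2")


@dataclass
class Burst:
    """One single-channel burst; start/end are first/last spike times."""

    electrode_id: int
    start: float
    end: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def spike_rate(self) -> float:
        return self.n_spikes / self.duration if self.duration > 0 else float("nan")


def detect_bursts(train: SpikeTrain, settings: BurstSettings | None = None) -> list[Burst]:
    """Maximal runs of >= min_spikes spikes with all ISIs <= max_isi."""
    settings = settings or BurstSettings()
    ts = train.timestamps
    if ts.size < settings.min_spikes:
        return []
    ok = np.diff(ts) <= settings.max_isi
    bursts: list[Burst] = []
    i = 0
    n = ok.size
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n and ok[j]:
            j += 1
        count = j - i + 1  # spikes in the run [i, j]
        if count >= settings.min_spikes:
            bursts.append(Burst(train.electrode_id, float(ts[i]), float(ts[j]), count))
        i = j
    return bursts


def burst_spike_count(train: SpikeTrain, bursts: list[Burst]) -> int:
    """Number of spikes of ``train`` lying inside its bursts (ends inclusive)."""
    if not bursts:
        return 0
    ts = train.timestamps
    total = 0
    for b in bursts:
        lo = np.searchsorted(ts, b.start, side="left")
        hi = np.searchsorted(ts, b.end, side="right")
        total += hi - lo
    return int(total)


def channel_burst_statistics(bursts: list[Burst], duration: float) -> dict:
    """BR, BD, BSR, IBI for one electrode's burst list.

    Undefined means (no bursts, or a single burst for IBI) are NaN, with the
    corresponding flag in ``flags``.
    """
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    flags: list[str] = []
    out = {
        "BR": len(bursts) / duration * 60.0,
        "BD": float("nan"),
        "BSR": float("nan"),
        "IBI": float("nan"),
    }
    if bursts:
        out["BD"] = float(np.mean([b.duration for b in bursts]))
        out["BSR"] = float(np.mean([b.spike_rate for b in bursts]))
    else:
        flags += ["NO_BURSTS"]
    if len(bursts) >= 2:
        gaps = [b2.start - b1.end for b1, b2 in zip(bursts, bursts[1:])]
        out["IBI"] = float(np.mean(gaps))
    else:
        flags.append("IBI_UNDEFINED")
    out["flags"] = flags
    return out


def mean_firing_rate(well: WellRecording) -> float:
    """Per-electrode mean firing rate over all 12 slots, silent ones included."""
    return well.total_spikes / well.duration / N_ELECTRODES


def percentage_random_spikes(
    well: WellRecording, bursts_per_channel: dict[int, list[Burst]]
) -> float:
    """Percentage of spikes not inside any single-channel burst; 0 if no spikes."""
    total = well.total_spikes
    if total == 0:
        logger.warning("PRS undefined on a silent well; reporting 0")
        return 0.0
    in_burst = sum(
        burst_spike_count(t, bursts_per_channel.get(t.electrode_id, []))
        for t in well.trains
    )
    return 100.0 * (total - in_burst) / total


def well_burst_statistics(
    well: WellRecording, settings: BurstSettings | None = None
) -> tuple[dict, dict[int, list[Burst]]]:
    """Well-level burst parameters: bursts pooled over all 12 electrode slots.

    BR is the per-electrode mean burst rate (count / duration / 12, in
    bursts/min); BD and BSR average over every burst in the well; IBI averages
    the per-electrode consecutive-burst gaps, pooled.
    """
    settings = settings or BurstSettings()
    per_channel = {t.electrode_id: detect_bursts(t, settings) for t in well.trains}
    all_bursts = [b for bs in per_channel.values() for b in bs]
    flags: list[str] = []
    stats = {
        "BR": len(all_bursts) / well.duration * 60.0 / N_ELECTRODES,
        "BD": float("nan"),
        "BSR": float("nan"),
        "IBI": float("nan"),
    }
    if all_bursts:
        stats["BD"] = float(np.mean([b.duration for b in all_bursts]))
        stats["BSR"] = float(np.mean([b.spike_rate for b in all_bursts]))
    else:
        flags.append("NO_BURSTS")
    gaps: list[float] = []
    for bs in per_channel.values():
        gaps += [b2.start - b1.end for b1, b2 in zip(bs, bs[1:])]
    if gaps:
        stats["IBI"] = float(np.mean(gaps))
    else:
        flags.append("IBI_UNDEFINED")
    stats["PRS"] = percentage_random_spikes(well, per_channel)
    stats["MFR"] = mean_firing_rate(well)
    stats["flags"] = flags
    return stats, per_channel


__all__ = [
    "Burst", "BurstSettings", "detect_bursts", "burst_spike_count",
    "channel_burst_statistics", "mean_firing_rate", "percentage_random_spikes",
    "well_burst_statistics",
]
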