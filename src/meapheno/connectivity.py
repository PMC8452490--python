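"""Pairwise cross-correlation connectivity: C_0, C_peak, and functional links.

For two spike trains a, b the cross-correlogram counts spike-pair lag
differences ``t_b - t_a`` in bins of width ``bin`` over lags in
``[-window, +window]`` (positive lag: b fires after a), normalized by
``sqrt(N_a * N_b)`` so a pair of identical trains scores 1 in the zero-lag
bin; values are clipped at 1 so extreme coincidence multiplicity cannot push
them above the unit bound.  By construction ``C(a,b)(tau) = C(b,a)(-tau)``.

- C_0: value of the zero-lag bin ("synchronization");
- C_peak: maximum over all lag bins ("correlation"), so C_peak >= C_0;
- functional links: electrode pairs whose C_peak exceeds a surrogate-based
  threshold, with surrogates built by uniform spike-time dithering (which
  preserves rates and destroys fine-timescale correlation);
- link weight: mean C_peak over links; n_connections: number of links.

All 66 unordered pairs over the 12 electrode slots are evaluated; pairs
involving silent electrodes score zero (the all-electrode rule).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .io_peaktrains import N_ELECTRODES, SpikeTrain, WellRecording

logger = logging.getLogger(__name__)


@dataclass
class ConnectivitySettings:
    window: float = 0.5
    bin: float = 0.01
    n_surrogates: int = 100
    alpha: float = 0.05
    dither: float = 0.5  # half-width of the uniform spike-time jitter (s)

    def __post_init__(self) -> None:
        if self.window <= 0 or self.bin <= 0 or self.bin > self.window:
            raise ParameterError("need 0 < bin <= window")


@dataclass
class CrossCorrelogram:
    lags: np.ndarray  # bin centers, symmetric around 0
    values: np.ndarray
    pair: tuple[int, int]
    flags: list[str] = field(default_factory=list)

    @property
    def c0(self) -> float:
        return float(self.values[self.values.size // 2])

    @property
    def c_peak(self) -> float:
        return float(self.values.max())


@dataclass
class ConnectivityResult:
    c0_matrix: np.ndarray
    cpeak_matrix: np.ndarray
    links: set[tuple[int, int]] = field(default_factory=set)
    link_weight: float = float("nan")
    n_connections: int = 0
    link_threshold: float = float("nan")

    def mean_c0(self) -> float:
        """Mean C_0 over the 66 unordered electrode pairs."""
        iu = np.triu_indices(N_ELECTRODES, k=1)
        return float(self.c0_matrix[iu].mean())

    def mean_cpeak(self) -> float:
        iu = np.triu_indices(N_ELECTRODES, k=1)
        return float(self.cpeak_matrix[iu].mean())


def _lag_grid(window: float, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    k = int(round(window / bin_width))
    centers = np.arange(-k, k + 1) * bin_width
    edges = np.arange(-k - 0.5, k + 1.5) * bin_width
    return centers, edges


def cross_correlogram(
    a: SpikeTrain,
    b: SpikeTrain,
    window: float = 0.5,
    bin: float = 0.01,  # noqa: A002 - field name mirrors the settings block
) -> CrossCorrelogram:
    """Normalized cross-correlogram of two spike trains from one recording."""
    centers, edges = _lag_grid(window, bin)
    ta, tb = a.timestamps, b.timestamps
    if ta.size == 0 or tb.size == 0:
        logger.warning(
            "correlogram (%d, %d): empty train, all-zero result",
            a.electrode_id, b.electrode_id,
        )
        return CrossCorrelogram(centers, np.zeros(centers.size), (a.electrode_id, b.electrode_id),
                                flags=["EMPTY_TRAIN"])
    lo = np.searchsorted(tb, ta + edges[0], side="left")
    hi = np.searchsorted(tb, ta + edges[-1], side="left")
    counts_per_a = hi - lo
    total = int(counts_per_a.sum())
    if total:
        diffs = np.empty(total)
        pos = 0
        for t0, l, h in zip(ta, lo, hi):
            if h > l:
                diffs[pos:pos + h - l] = tb[l:h] - t0
                pos += h - l
        hist, _ = np.histogram(diffs, bins=edges)
    else:
        hist = np.zeros(centers.size)
    values = np.minimum(hist / np.sqrt(ta.size * tb.size), 1.0)
    return CrossCorrelogram(centers, values, (a.electrode_id, b.electrode_id))


def _pair_cpeaks(
    trains: list[SpikeTrain], settings: ConnectivitySettings
) -> tuple[np.ndarray, np.ndarray]:
    """C_0 and C_peak matrices over all 66 unordered pairs (silent pairs = 0)."""
    c0 = np.zeros((N_ELECTRODES, N_ELECTRODES))
    cpeak = np.zeros((N_ELECTRODES, N_ELECTRODES))
    for i, j in itertools.combinations(range(N_ELECTRODES), 2):
        xc = cross_correlogram(trains[i], trains[j], settings.window, settings.bin)
        c0[i, j] = c0[j, i] = xc.c0
        cpeak[i, j] = cpeak[j, i] = xc.c_peak
    for i in range(N_ELECTRODES):
        active = trains[i].n_spikes > 0
        c0[i, i] = cpeak[i, i] = 1.0 if active else 0.0
    return c0, cpeak


def pairwise_connectivity(
    well: WellRecording, settings: ConnectivitySettings | None = None
) -> ConnectivityResult:
    """C_0 / C_peak matrices for all electrode pairs of one well."""
    settings = settings or ConnectivitySettings()
    if well.total_spikes == 0:
        logger.warning("connectivity on a silent well: zero matrices")
        z = np.zeros((N_ELECTRODES, N_ELECTRODES))
        return ConnectivityResult(z, z.copy())
    c0, cpeak = _pair_cpeaks(well.trains, settings)
    return ConnectivityResult(c0, cpeak)


def functional_links(
    result: ConnectivityResult,
    well: WellRecording,
    n_surrogates: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
    settings: ConnectivitySettings | None = None,
) -> ConnectivityResult:
    """Threshold C_peak against a dithered-surrogate null to define links.

    The null pools C_peak over ``n_surrogates`` surrogate wells in which every
    spike is jittered by an independent uniform offset of +/- ``dither``
    seconds; a pair is a link iff its observed C_peak exceeds the
    ``1 - alpha`` quantile of that pool.
    """
    settings = settings or ConnectivitySettings()
    if n_surrogates < 20:
        warnings.warn(
            f"n_surrogates={n_surrogates} < 20: surrogate null is unstable",
            stacklevel=2,
        )
    if seed is None:
        raise ParameterError("seed is mandatory for the surrogate null")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(N_ELECTRODES, k=1)
    null: list[np.ndarray] = []
    for _ in range(n_surrogates):
        surr = []
        for t in well.trains:
            ts = t.timestamps + rng.uniform(-settings.dither, settings.dither, t.n_spikes)
            ts = np.unique(np.clip(ts, 0.0, well.duration))
            surr.append(SpikeTrain(ts, None, t.electrode_id))
        _, cpeak_s = _pair_cpeaks(surr, settings)
        null.append(cpeak_s[iu])
    thr = float(np.quantile(np.concatenate(null), 1.0 - alpha)) if null else float("inf")
    links = {
        (int(i) + 1, int(j) + 1)
        for i, j in zip(*iu)
        if result.cpeak_matrix[i, j] > thr
    }
    weights = [result.cpeak_matrix[a - 1, b - 1] for a, b in links]
    return ConnectivityResult(
        c0_matrix=result.c0_matrix,
        cpeak_matrix=result.cpeak_matrix,
        links=links,
        link_weight=float(np.mean(weights)) if weights else float("nan"),
        n_connections=len(links),
        link_threshold=thr,
    )


__all__ = [
    "ConnectivitySettings", "CrossCorrelogram", "ConnectivityResult",
    "cross_correlogram", "pairwise_connectivity", "functional_links",
]
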