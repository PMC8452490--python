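"""Synthetic multiwell MEA spike-train generator with known ground truth.

Each simulated well emulates the activity of a mature excitatory
hiPSC-derived network on a 12-electrode MEA well over a 10-minute recording:

- network bursts (NBs): onsets follow a gamma-renewal process with mean
  interval ``60 / nb_rate`` and coefficient of variation ``nb_cv``; within an
  NB, each channel participates with probability ``participation`` and emits
  Poisson spikes whose times follow a gamma-density envelope (shape
  ``1 + rise_tau/decay_tau``, scale ``decay_tau``) truncated at
  ``nb_duration`` — right-skewed, with a fast rise and a slower decay;
- single-channel bursts outside NBs: short stereotyped high-frequency runs at
  ``channel_burst_rate`` per channel;
- background: independent Poisson spikes at ``background_rate`` per channel;
- amplitudes: lognormal in microvolts.

Every spike is attributable to exactly one generator component, recorded in
the ground truth.  ``simulate_experiment`` adds multiplicative lognormal
batch effects (on nb_rate, intra_nb_rate and background_rate — the
rate-generating parameters) and per-well lognormal noise, emulating cohorts
in which astrocyte and MEA batch are dominant technical factors.

Presets: ``control`` is tuned so the analysis pipeline lands near a typical
healthy-network operating point (~3.5 spikes/s, ~4.8 bursts/min,
~3.2 NB/min, NB duration ~1.28 s); ``melas_like`` shifts only toward reduced
spiking/network bursting, a higher share of random spikes, shorter bursts and
weaker participation; ``ks_like`` shifts toward fewer but longer network
bursts with a slower decay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .io_peaktrains import (
    N_ELECTRODES,
    RecordingMetadata,
    SpikeTrain,
    WellRecording,
    write_metadata_table,
    write_peak_trains,
)

logger = logging.getLogger(__name__)

#: parameters that receive batch / well multiplicative noise
BATCH_AFFECTED = ("nb_rate", "intra_nb_rate", "background_rate")

#: stereotyped single-channel burst outside NBs: n spikes at ~12 ms ISI
_CHBURST_SPIKES = 8
_CHBURST_ISI = 0.012


@dataclass
class PhenotypeParams:
    """Generative parameters of one network phenotype."""

    nb_rate: float = 3.2            # network bursts / min
    nb_cv: float = 0.4              # CV of inter-NB onset intervals
    nb_duration: float = 1.28       # s, nominal NB span
    rise_tau: float = 0.256         # s, envelope rise time constant
    decay_tau: float = 0.256        # s, envelope decay time constant (gamma scale)
    participation: float = 0.9      # P(channel participates in an NB)
    intra_nb_rate: float = 52.0     # spikes/s per participating channel in an NB
    channel_burst_rate: float = 1.2  # bursts/min per channel outside NBs
    background_rate: float = 0.15   # spikes/s per channel
    amplitude_mu: float = float(np.log(30.0))  # lognormal location, log-uV
    amplitude_sigma: float = 0.5

    def __post_init__(self) -> None:
        for name in ("nb_rate", "nb_cv", "nb_duration", "rise_tau", "decay_tau",
                     "intra_nb_rate", "channel_burst_rate", "background_rate"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.participation <= 1.0:
            raise ParameterError("participation must be in [0, 1]")

    @property
    def envelope_shape(self) -> float:
        return 1.0 + self.rise_tau / self.decay_tau if self.decay_tau > 0 else 2.0


@dataclass
class LineSpec:
    line_id: str
    params: PhenotypeParams
    disease_status: str = "control"


@dataclass
class ExperimentDesign:
    """A multi-line, multi-batch simulated cohort."""

    lines: list[LineSpec]
    wells_per_line: int = 12
    mea_batches: int = 2
    astro_batches: int = 2
    batch_effect_sd: float = 0.2    # log-scale SD of per-batch multipliers
    well_noise_sd: float = 0.2      # log-scale SD of per-well multipliers
    duration: float = 600.0
    div: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wells_per_line < 1:
            raise ParameterError("wells_per_line must be >= 1")
        if self.duration <= 0:
            raise ParameterError("duration must be > 0")


@dataclass
class GroundTruth:
    """Generative truth for one simulated well."""

    params: PhenotypeParams
    nb_onsets: np.ndarray
    nb_spans: np.ndarray            # realized first-to-last NB spike spans
    nb_channels: list[frozenset]
    component_times: dict           # component -> list of 12 per-channel arrays
    seed: int

    @property
    def true_nbr(self) -> float:
        return float("nan")  # set by simulate_well via duration; kept simple

    def component_counts(self) -> dict:
        return {k: int(sum(a.size for a in v)) for k, v in self.component_times.items()}


def preset_phenotype(name: str) -> PhenotypeParams:
    """Named phenotype presets: control, melas_like, ks_like."""
    if name == "control":
        return PhenotypeParams()
    if name == "melas_like":
        # reduced spiking & network bursting, weaker participation, shorter
        # single-channel bursts, larger random-spike share
        return PhenotypeParams(
            nb_rate=1.6, nb_cv=0.5, nb_duration=1.28,
            rise_tau=0.256, decay_tau=0.256,
            participation=0.55, intra_nb_rate=30.0,
            channel_burst_rate=1.0, background_rate=0.15,
        )
    if name == "ks_like":
        # fewer but longer network bursts with a slower decay
        return PhenotypeParams(
            nb_rate=1.3, nb_cv=0.45, nb_duration=2.2,
            rise_tau=0.44, decay_tau=0.44,
            participation=0.85, intra_nb_rate=35.0,
            channel_burst_rate=1.5, background_rate=0.12,
        )
    raise ParameterError(f"unknown preset {name!r}")


def _truncated_gamma(rng: np.random.Generator, shape: float, scale: float,
                     upper: float, size: int) -> np.ndarray:
    """Draws from a gamma(shape, scale) truncated to [0, upper] (inverse CDF)."""
    mass = stats.gamma.cdf(upper, a=shape, scale=scale)
    u = rng.uniform(0.0, mass, size)
    return stats.gamma.ppf(u, a=shape, scale=scale)


def _strictly_increasing(ts: np.ndarray) -> np.ndarray:
    """Sort and nudge exact ties so downstream invariants hold."""
    ts = np.sort(ts)
    if ts.size > 1:
        dup = np.flatnonzero(np.diff(ts) <= 0)
        for i in dup:
            ts[i + 1] = np.nextafter(ts[i], np.inf)
    return ts


def simulate_well(
    params: PhenotypeParams,
    duration: float = 600.0,
    seed: int = 0,
) -> tuple[WellRecording, GroundTruth]:
    """Simulate one well; identical seed yields identical output."""
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    rng = np.random.default_rng(seed)

    # --- network-burst onsets: gamma renewal -----------------------------
    onsets: list[float] = []
    if params.nb_rate > 0:
        mean_int = 60.0 / params.nb_rate
        min_int = params.nb_duration + 0.3  # keep NBs disjoint
        t = 0.0
        while True:
            if params.nb_cv <= 0:
                interval = mean_int
            else:
                k = 1.0 / params.nb_cv ** 2
                interval = rng.gamma(k, mean_int / k)
            t += max(interval, min_int)
            if t + params.nb_duration >= duration:
                break
            onsets.append(t)
    onsets_arr = np.asarray(onsets)

    nb_times: list[list[np.ndarray]] = [[] for _ in range(N_ELECTRODES)]
    nb_channels: list[frozenset] = []
    nb_spans = np.zeros(len(onsets))
    env_shape, env_scale = params.envelope_shape, params.decay_tau
    for idx, onset in enumerate(onsets):
        participating = np.flatnonzero(rng.random(N_ELECTRODES) < params.participation)
        nb_channels.append(frozenset(int(c) + 1 for c in participating))
        first, last = np.inf, -np.inf
        for c in participating:
            n = rng.poisson(params.intra_nb_rate * params.nb_duration)
            if n == 0:
                continue
            offs = _truncated_gamma(rng, env_shape, env_scale, params.nb_duration, n)
            tt = onset + np.sort(offs)
            nb_times[c].append(tt)
            first, last = min(first, tt[0]), max(last, tt[-1])
        nb_spans[idx] = (last - first) if last > first else 0.0

    # --- single-channel bursts outside NBs -------------------------------
    chburst_times: list[list[np.ndarray]] = [[] for _ in range(N_ELECTRODES)]
    burst_span = (_CHBURST_SPIKES - 1) * _CHBURST_ISI * 1.2
    placed: list[tuple[float, float]] = []  # asynchronous: no cross-channel overlap
    for c in range(N_ELECTRODES):
        n_bursts = rng.poisson(params.channel_burst_rate / 60.0 * duration)
        for _ in range(n_bursts):
            start = rng.uniform(0.0, max(duration - burst_span, 0.0))
            # reject bursts that collide with an NB window ...
            if onsets_arr.size and np.any(
                (start < onsets_arr + params.nb_duration + 0.2)
                & (start + burst_span > onsets_arr - 0.2)
            ):
                continue
            # ... or with another channel's burst (these model isolated events)
            if any(start < e + 0.2 and start + burst_span > s - 0.2 for s, e in placed):
                continue
            placed.append((start, start + burst_span))
            isis = _CHBURST_ISI * rng.uniform(0.8, 1.2, _CHBURST_SPIKES - 1)
            tt = start + np.concatenate([[0.0], np.cumsum(isis)])
            chburst_times[c].append(tt)

    # --- Poisson background ----------------------------------------------
    bg_times: list[np.ndarray] = []
    for c in range(N_ELECTRODES):
        n = rng.poisson(params.background_rate * duration)
        bg_times.append(np.sort(rng.uniform(0.0, duration, n)))

    trains: list[SpikeTrain] = []
    for c in range(N_ELECTRODES):
        parts = nb_times[c] + chburst_times[c] + [bg_times[c]]
        ts = np.concatenate(parts) if parts else np.empty(0)
        ts = _strictly_increasing(ts)
        amps = rng.lognormal(params.amplitude_mu, params.amplitude_sigma, ts.size)
        sign = np.where(rng.random(ts.size) < 0.8, -1.0, 1.0)  # mostly negative lobes
        trains.append(SpikeTrain(ts, amps * sign, c + 1))

    well = WellRecording(trains=trains, duration=duration)
    gt = GroundTruth(
        params=params,
        nb_onsets=onsets_arr,
        nb_spans=nb_spans,
        nb_channels=nb_channels,
        component_times={
            "nb": [np.concatenate(v) if v else np.empty(0) for v in nb_times],
            "channel_burst": [np.concatenate(v) if v else np.empty(0) for v in chburst_times],
            "background": bg_times,
        },
        seed=seed,
    )
    return well, gt


def _apply_multipliers(params: PhenotypeParams, mults: dict[str, float]) -> PhenotypeParams:
    return replace(params, **{k: getattr(params, k) * m for k, m in mults.items()})


def simulate_cohort(design: ExperimentDesign) -> tuple[list, pd.DataFrame]:
    """Simulate a full design in memory.

    Returns ``(wells, ground_truth)`` where ``wells`` is a list of
    ``(well_id, WellRecording, GroundTruth)`` and ``ground_truth`` one row per
    well with realized generative parameters and batch assignments.
    """
    master = np.random.default_rng(design.seed)
    mea_ids = [f"MB{i + 1}" for i in range(design.mea_batches)]
    astro_ids = [f"AB{i + 1}" for i in range(design.astro_batches)]

    # one shared "activity" multiplier per batch: batch quality moves all
    # rate-generating parameters coherently, as in real preparations
    mea_mults = {b: float(np.exp(master.normal(0.0, design.batch_effect_sd)))
                 for b in mea_ids}
    astro_mults = {b: float(np.exp(master.normal(0.0, design.batch_effect_sd)))
                   for b in astro_ids}

    wells = []
    rows = []
    for spec in design.lines:
        for i in range(design.wells_per_line):
            mea_b = mea_ids[i % design.mea_batches]
            astro_b = astro_ids[(i // design.mea_batches) % design.astro_batches]
            well_mult = float(np.exp(master.normal(0.0, design.well_noise_sd)))
            mult = mea_mults[mea_b] * astro_mults[astro_b] * well_mult
            mults = {p: mult for p in BATCH_AFFECTED}
            realized = _apply_multipliers(spec.params, mults)
            seed = int(master.integers(2 ** 31))
            well, gt = simulate_well(realized, design.duration, seed)
            well_id = f"{spec.line_id}_w{i + 1:02d}"
            well.metadata = RecordingMetadata(
                well_id=well_id, line_id=spec.line_id, div=design.div,
                mea_batch=mea_b, astro_batch=astro_b,
                disease_status=spec.disease_status,
            )
            wells.append((well_id, well, gt))
            rows.append({
                "well_id": well_id, "line_id": spec.line_id,
                "mea_batch": mea_b, "astro_batch": astro_b, "div": design.div,
                "seed": seed,
                **{f"true_{p}": getattr(realized, p) for p in (
                    "nb_rate", "nb_cv", "nb_duration", "participation",
                    "intra_nb_rate", "channel_burst_rate", "background_rate")},
                "true_n_nbs": int(gt.nb_onsets.size),
                "true_mean_nb_span": float(np.mean(gt.nb_spans)) if gt.nb_spans.size else float("nan"),
            })
    return wells, pd.DataFrame(rows)


def simulate_experiment(design: ExperimentDesign, out_dir: str | Path) -> Path:
    """Simulate a design and write it as a portable dataset directory.

    Layout: ``<out_dir>/<well_id>.h5`` (portable peak trains), plus
    ``metadata.csv`` and ``ground_truth.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wells, gt = simulate_cohort(design)
    metas = []
    for well_id, well, _ in wells:
        write_peak_trains(well, out / f"{well_id}.h5", "portable_hdf5")
        metas.append(well.metadata)
    write_metadata_table(metas, out / "metadata.csv")
    gt.to_csv(out / "ground_truth.csv", index=False)
    logger.info("simulated %d wells into %s", len(wells), out)
    return out


# ---------------------------------------------------------------------------
# Optional raw-trace rendering (front-end for threshold spike detection)
# ---------------------------------------------------------------------------

def render_raw_trace(
    train: SpikeTrain,
    duration: float,
    sampling_rate: float = 10_000.0,
    noise_sd: float = 3.0,
    amplitude: float | None = None,
    seed: int = 0,
):
    """Render a spike train as a noisy raw voltage trace.

    A biphasic extracellular template (negative main lobe, smaller positive
    rebound, ~1 ms) is superimposed on white Gaussian noise of ``noise_sd``
    microvolts.  ``amplitude`` overrides per-spike amplitudes; the template
    peak equals the (absolute) spike amplitude.
    """
    from .spike_detection import RawTrace  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    x = rng.normal(0.0, noise_sd, n)
    # template: difference of half-sines, normalized to unit negative peak
    w = int(round(1e-3 * sampling_rate))
    tt = np.linspace(0, np.pi, w)
    template = np.concatenate([-np.sin(tt), 0.35 * np.sin(tt)])
    template /= np.abs(template).max()
    peak_off = int(np.argmax(np.abs(template)))  # align spike time to the extremum
    for i, t in enumerate(train.timestamps):
        a = amplitude
        if a is None:
            a = abs(train.amplitudes[i]) if train.amplitudes is not None else 30.0
        s = int(round(t * sampling_rate)) - peak_off
        t_lo, t_hi = max(0, -s), min(template.size, n - s)
        if t_hi > t_lo:
            x[s + t_lo:s + t_hi] += a * template[t_lo:t_hi]
    return RawTrace(x, sampling_rate, train.electrode_id)


__all__ = [
    "PhenotypeParams", "LineSpec", "ExperimentDesign", "GroundTruth",
    "preset_phenotype", "simulate_well", "simulate_cohort",
    "simulate_experiment", "render_raw_trace", "BATCH_AFFECTED",
]
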