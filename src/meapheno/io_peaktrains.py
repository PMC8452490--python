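"""Peak-train I/O: per-electrode spike times/amplitudes for 12-electrode MEA wells.

A "peak train" is the per-electrode list of spike timestamps (seconds from
recording start) and spike amplitudes (microvolts) extracted from one well of
a 24-well micro-electrode-array plate.  Two on-disk dialects are supported:

``mcs_mat``
    A MATLAB .mat file with one ``ptrain_<row><col>`` variable per electrode
    (rows 1-3, columns 1-4 of the electrode grid), each an N x 2 array of
    [sample index at 10 kHz, amplitude in microvolts], plus scalar
    ``sampling_rate`` and ``duration_samples`` variables.  This mirrors the
    conventions of Multichannel Systems peak-train exports; the layout is
    defined by the fixture documented in docs/methods.md.

``portable_hdf5``
    HDF5 with groups ``/well/electrode_<k>/{timestamps,amplitudes}`` (seconds
    and microvolts) and recording/ metadata attributes on ``/well``.

Timestamps are float64 seconds, zero at recording start, strictly increasing;
intervals elsewhere in the package are half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

N_ELECTRODES = 12
#: electrode k (1..12) maps to grid position (row, col) = divmod(k-1, 4) + 1
_GRID_COLS = 4

SEXES = frozenset({"M", "F", "unknown"})
DISEASE_STATUSES = frozenset({"control", "MELAS", "KS", "other"})
COATINGS = frozenset({"human_laminin", "mouse_laminin", "unknown"})

DIALECTS = ("mcs_mat", "portable_hdf5")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SpikeTrain:
    """Spike timestamps (s) and optional amplitudes (uV) for one electrode."""

    timestamps: np.ndarray
    amplitudes: np.ndarray | None = None
    electrode_id: int = 1

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        if self.timestamps.ndim != 1:
            raise ValidationError(f"electrode {self.electrode_id}: timestamps must be 1-D")
        if self.timestamps.size and np.any(np.diff(self.timestamps) <= 0):
            raise ValidationError(
                f"electrode {self.electrode_id}: timestamps not strictly increasing"
            )
        if self.timestamps.size and self.timestamps[0] < 0:
            raise ValidationError(f"electrode {self.electrode_id}: negative timestamp")
        if self.amplitudes is not None:
            self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
            if self.amplitudes.shape != self.timestamps.shape:
                raise ValidationError(
                    f"electrode {self.electrode_id}: amplitudes length mismatch"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.timestamps.size)

    def rate(self, duration: float) -> float:
        """Mean firing rate in spikes/s over ``duration`` seconds."""
        return self.n_spikes / duration if duration > 0 else float("nan")


@dataclass
class RecordingMetadata:
    """Grouping factors for one well: line, age of culture, batches, donor."""

    line_id: str = "unknown"
    div: int = 0
    mea_batch: str = "unknown"
    astro_batch: str = "unknown"
    sex: str = "unknown"
    donor_age: float = float("nan")
    disease_status: str = "other"
    coating: str = "unknown"
    well_id: str = ""
    manual_exclude: bool = False

    def __post_init__(self) -> None:
        if self.div < 0:
            raise ValidationError("DIV must be >= 0")
        if self.sex not in SEXES:
            raise ValidationError(f"sex {self.sex!r} not in {sorted(SEXES)}")
        if self.disease_status not in DISEASE_STATUSES:
            raise ValidationError(
                f"disease_status {self.disease_status!r} not in {sorted(DISEASE_STATUSES)}"
            )
        if self.coating not in COATINGS:
            raise ValidationError(f"coating {self.coating!r} not in {sorted(COATINGS)}")


@dataclass
class WellRecording:
    """One MEA well: 12 electrode slots (empty trains allowed) plus metadata."""

    trains: list[SpikeTrain] = field(default_factory=list)
    duration: float = 600.0
    sampling_rate: float = 10_000.0
    metadata: RecordingMetadata | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("duration must be > 0")
        by_id = {t.electrode_id: t for t in self.trains}
        full = []
        for k in range(1, N_ELECTRODES + 1):
            t = by_id.get(k, SpikeTrain(np.empty(0), None, k))
            if t.timestamps.size and t.timestamps[-1] > self.duration:
                raise ValidationError(
                    f"electrode {k}: timestamp beyond recording duration"
                )
            full.append(t)
        self.trains = full

    @property
    def total_spikes(self) -> int:
        return sum(t.n_spikes for t in self.trains)

    def all_spike_times(self) -> np.ndarray:
        """All spike times in the well, pooled across electrodes, sorted."""
        if self.total_spikes == 0:
            return np.empty(0)
        return np.sort(np.concatenate([t.timestamps for t in self.trains]))

    def equals(self, other: "WellRecording", atol: float = 1e-9) -> bool:
        if abs(self.duration - other.duration) > atol:
            return False
        for a, b in zip(self.trains, other.trains):
            if a.n_spikes != b.n_spikes:
                return False
            if a.n_spikes and not np.allclose(a.timestamps, b.timestamps, atol=atol):
                return False
        return True


# ---------------------------------------------------------------------------
# Peak-train file dialects
# ---------------------------------------------------------------------------

def _electrode_varname(electrode_id: int) -> str:
    row, col = divmod(electrode_id - 1, _GRID_COLS)
    return f"ptrain_{row + 1}{col + 1}"


def read_peak_trains(path: str | Path, dialect: str = "portable_hdf5") -> WellRecording:
    """Read one well's peak trains.

    ``mcs_mat`` stores sample indices at the recorded sampling rate; these are
    converted to seconds on read.  Electrodes absent from the file become empty
    trains at their grid slot, with a warning logged per missing electrode.
    """
    path = Path(path)
    if dialect == "mcs_mat":
        return _read_mat(path)
    if dialect == "portable_hdf5":
        return _read_hdf5(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def write_peak_trains(rec: WellRecording, path: str | Path, dialect: str = "portable_hdf5") -> Path:
    """Write ``rec`` so that :func:`read_peak_trains` restores an equal recording."""
    path = Path(path)
    if dialect == "mcs_mat":
        _write_mat(rec, path)
    elif dialect == "portable_hdf5":
        _write_hdf5(rec, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    return path


def _read_mat(path: Path) -> WellRecording:
    try:
        raw = scipy.io.loadmat(path)
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise FormatError(f"{path}: not readable as mcs_mat: {exc}") from exc
    if "sampling_rate" not in raw or "duration_samples" not in raw:
        raise FormatError(f"{path}: missing sampling_rate/duration_samples (mcs_mat)")
    fs = float(np.squeeze(raw["sampling_rate"]))
    duration = float(np.squeeze(raw["duration_samples"])) / fs
    trains = []
    for k in range(1, N_ELECTRODES + 1):
        name = _electrode_varname(k)
        if name not in raw:
            logger.warning("%s: electrode %d (%s) absent; using empty train", path, k, name)
            trains.append(SpikeTrain(np.empty(0), None, k))
            continue
        arr = np.atleast_2d(np.asarray(raw[name], dtype=np.float64))
        if arr.size == 0:
            trains.append(SpikeTrain(np.empty(0), None, k))
            continue
        if arr.shape[1] != 2:
            raise FormatError(f"{path}: {name} is not an N x 2 array (mcs_mat)")
        ts = arr[:, 0] / fs
        if np.any(np.diff(ts) <= 0):
            raise ValidationError(f"{path}: electrode {k} timestamps not monotonic")
        trains.append(SpikeTrain(ts, arr[:, 1], k))
    return WellRecording(trains=trains, duration=duration, sampling_rate=fs)


def _write_mat(rec: WellRecording, path: Path) -> None:
    out: dict[str, object] = {
        "sampling_rate": float(rec.sampling_rate),
        "duration_samples": float(round(rec.duration * rec.sampling_rate)),
    }
    for t in rec.trains:
        samples = np.round(t.timestamps * rec.sampling_rate)
        # sample indices must be strictly increasing: two spikes cannot share
        # a sample, so sub-sample-separated events are bumped by one sample
        for i in range(1, samples.size):
            if samples[i] <= samples[i - 1]:
                samples[i] = samples[i - 1] + 1
        amps = t.amplitudes if t.amplitudes is not None else np.zeros_like(samples)
        out[_electrode_varname(t.electrode_id)] = np.column_stack([samples, amps])
    scipy.io.savemat(path, out)


_H5_META_FIELDS = (
    "line_id", "div", "mea_batch", "astro_batch", "sex",
    "donor_age", "disease_status", "coating", "well_id", "manual_exclude",
)


def _read_hdf5(path: Path) -> WellRecording:
    try:
        f = h5py.File(path, "r")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: not readable as portable_hdf5: {exc}") from exc
    with f:
        if "well" not in f:
            raise FormatError(f"{path}: missing /well group (portable_hdf5)")
        g = f["well"]
        duration = float(g.attrs["duration"])
        fs = float(g.attrs.get("sampling_rate", 10_000.0))
        meta = None
        if "line_id" in g.attrs:
            kw = {}
            for k in _H5_META_FIELDS:
                if k in g.attrs:
                    v = g.attrs[k]
                    kw[k] = v.item() if hasattr(v, "item") else v
            kw["div"] = int(kw.get("div", 0))
            kw["manual_exclude"] = bool(kw.get("manual_exclude", False))
            meta = RecordingMetadata(**kw)
        trains = []
        for k in range(1, N_ELECTRODES + 1):
            name = f"electrode_{k}"
            if name not in g:
                logger.warning("%s: electrode %d absent; using empty train", path, k)
                trains.append(SpikeTrain(np.empty(0), None, k))
                continue
            eg = g[name]
            ts = np.asarray(eg["timestamps"], dtype=np.float64)
            if ts.size and np.any(np.diff(ts) <= 0):
                raise ValidationError(f"{path}: electrode {k} timestamps not monotonic")
            amps = np.asarray(eg["amplitudes"]) if "amplitudes" in eg else None
            trains.append(SpikeTrain(ts, amps, k))
    return WellRecording(trains=trains, duration=duration, sampling_rate=fs, metadata=meta)


def _write_hdf5(rec: WellRecording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("well")
        g.attrs["duration"] = float(rec.duration)
        g.attrs["sampling_rate"] = float(rec.sampling_rate)
        if rec.metadata is not None:
            m = rec.metadata
            for k in _H5_META_FIELDS:
                g.attrs[k] = getattr(m, k)
        for t in rec.trains:
            eg = g.create_group(f"electrode_{t.electrode_id}")
            eg.create_dataset("timestamps", data=t.timestamps)
            if t.amplitudes is not None:
                eg.create_dataset("amplitudes", data=t.amplitudes)


# ---------------------------------------------------------------------------
# Well-metadata tables and parameter tables
# ---------------------------------------------------------------------------

_META_COLUMNS = {
    "well_id": "well_id",
    "line_id": "line_id",
    "DIV": "div",
    "mea_batch": "mea_batch",
    "astro_batch": "astro_batch",
    "sex": "sex",
    "age": "donor_age",
    "status": "disease_status",
    "coating": "coating",
}

_COATING_ALIASES = {"H": "human_laminin", "M": "mouse_laminin",
                    "human_laminin": "human_laminin",
                    "mouse_laminin": "mouse_laminin", "unknown": "unknown"}


def read_metadata_table(path: str | Path) -> list[RecordingMetadata]:
    """Read a per-well metadata CSV.

    Required columns: well_id, line_id, DIV, mea_batch, astro_batch, sex, age,
    status, coating.  Optional: manual_exclude (0/1).  Coating accepts the
    single-letter codes H (human laminin) and M (mouse laminin).
    """
    df = pd.read_csv(path)
    if df.empty and not set(_META_COLUMNS) <= set(df.columns):
        return []
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        coating = _COATING_ALIASES.get(str(row["coating"]).strip())
        if coating is None:
            raise ValidationError(f"{path}: bad coating {row['coating']!r}")
        records.append(RecordingMetadata(
            well_id=str(row["well_id"]),
            line_id=str(row["line_id"]),
            div=int(row["DIV"]),
            mea_batch=str(row["mea_batch"]),
            astro_batch=str(row["astro_batch"]),
            sex=str(row["sex"]).strip(),
            donor_age=float(row["age"]),
            disease_status=str(row["status"]).strip(),
            coating=coating,
            manual_exclude=bool(row.get("manual_exclude", False)),
        ))
    return records


def write_metadata_table(records: list[RecordingMetadata], path: str | Path) -> Path:
    rows = [{
        "well_id": m.well_id, "line_id": m.line_id, "DIV": m.div,
        "mea_batch": m.mea_batch, "astro_batch": m.astro_batch, "sex": m.sex,
        "age": m.donor_age, "status": m.disease_status, "coating": m.coating,
        "manual_exclude": int(m.manual_exclude),
    } for m in records]
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def metadata_to_frame(records: list[RecordingMetadata]) -> pd.DataFrame:
    """Metadata records as a DataFrame indexed by well_id."""
    df = pd.DataFrame([vars(m) for m in records])
    return df.set_index("well_id", drop=False) if len(df) else df


__all__ = [
    "SpikeTrain", "WellRecording", "RecordingMetadata",
    "read_peak_trains", "write_peak_trains",
    "read_metadata_table", "write_metadata_table", "metadata_to_frame",
    "N_ELECTRODES", "DIALECTS",
]
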