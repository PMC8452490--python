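"""End-to-end orchestration: wells -> 17-parameter table -> QC -> statistics.

The pipeline is a pure function of (input files, configuration, seed): a
rerun with identical inputs produces identical outputs.  Every well's fate
(included or excluded, with machine-readable reason codes) is logged to a
JSON-lines run log, and the effective configuration is serialized verbatim
into the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import qc_pooling
from .burst_analysis import BurstSettings, well_burst_statistics
from .connectivity import ConnectivitySettings, functional_links, pairwise_connectivity
from .errors import MeaPhenoError
from .io_peaktrains import (
    RecordingMetadata,
    WellRecording,
    read_metadata_table,
    read_peak_trains,
)
from .network_analysis import (
    NetworkBurstSettings,
    detect_network_bursts,
    network_burst_shape,
    network_burst_statistics,
    rise_decay_times,
)
from .qc_pooling import QCReport, QCSettings, well_inclusion

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_EMPTY = 3


@dataclass
class RunConfig:
    """Full pipeline configuration; every numeric default is the documented one."""

    input_dir: str = "."
    dialect: str = "portable_hdf5"
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    burst_detection: BurstSettings = field(default_factory=BurstSettings)
    network_burst_detection: NetworkBurstSettings = field(default_factory=NetworkBurstSettings)
    connectivity: ConnectivitySettings = field(default_factory=ConnectivitySettings)
    qc: QCSettings = field(default_factory=QCSettings)
    shape_bin_width: float = 0.005
    div_lo: int = 27
    div_hi: int = 35

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "burst_detection", "network_burst_detection", "connectivity", "qc"
            ):
                sub = {
                    "burst_detection": BurstSettings,
                    "network_burst_detection": NetworkBurstSettings,
                    "connectivity": ConnectivitySettings,
                    "qc": QCSettings,
                }[f.name]
                kw[f.name] = sub(**v)
            else:
                kw[f.name] = v
        return cls(**kw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def extract_parameters(
    well: WellRecording,
    config: RunConfig | None = None,
    seed: int | None = None,
    n_surrogates: int | None = None,
) -> dict:
    """Compute the 17 per-well parameters plus QC metrics for one recording.

    Connectivity links require the surrogate null; ``n_surrogates`` overrides
    the configured count (0 skips links, leaving link_weight/n_connections
    NaN).  Undefined parameters are NaN with a flag in ``flags``.
    """
    config = config or RunConfig()
    seed = config.seed if seed is None else seed
    flags: list[str] = []

    burst_stats, per_channel = well_burst_statistics(well, config.burst_detection)
    flags += burst_stats.pop("flags")

    nbs = detect_network_bursts(well, config.network_burst_detection)
    nb_stats = network_burst_statistics(nbs, well.duration)
    flags += nb_stats.pop("flags")

    rt, dt, shape_peak = float("nan"), float("nan"), float("nan")
    if nbs:
        shape = network_burst_shape(well, nbs, bin_width=config.shape_bin_width)
        shape_peak = float(shape.profile.max())
        timing = rise_decay_times(shape)
        flags += timing.pop("flags", [])
        rt, dt = timing["RT"], timing["DT"]
    else:
        flags.append("SHAPE_UNDEFINED")

    conn = pairwise_connectivity(well, config.connectivity)
    n_surr = config.connectivity.n_surrogates if n_surrogates is None else n_surrogates
    link_weight, n_connections = float("nan"), float("nan")
    if n_surr > 0 and well.total_spikes > 0:
        linked = functional_links(
            conn, well, n_surrogates=n_surr,
            alpha=config.connectivity.alpha, seed=seed,
            settings=config.connectivity,
        )
        link_weight, n_connections = linked.link_weight, float(linked.n_connections)
        if not linked.links:
            flags.append("NO_LINKS")
    else:
        flags.append("LINKS_SKIPPED")

    nb_participation = (
        float(np.mean([nb.participation for nb in nbs])) if nbs else 0.0
    )
    params = {
        "MFR": burst_stats["MFR"], "PRS": burst_stats["PRS"],
        "BR": burst_stats["BR"], "BD": burst_stats["BD"],
        "BSR": burst_stats["BSR"], "IBI": burst_stats["IBI"],
        "NBR": nb_stats["NBR"], "NBD": nb_stats["NBD"],
        "NIBI": nb_stats["NIBI"], "CV_NIBI": nb_stats["CV_NIBI"],
        "RT": rt, "DT": dt,
        "C_0": conn.mean_c0(), "C_peak": conn.mean_cpeak(),
        "link_weight": link_weight, "n_connections": n_connections,
        "shape_peak_rate": shape_peak,
        # QC metrics (not part of the 17)
        "active_fraction": qc_pooling.active_electrode_fraction(
            well, config.qc.active_rate_threshold),
        "nb_channel_fraction": nb_participation,
        "n_network_bursts": len(nbs),
        "flags": flags,
    }
    return params


def analyze_wells(
    wells: list[tuple[str, WellRecording]],
    config: RunConfig | None = None,
    metadata: dict[str, RecordingMetadata] | None = None,
    n_surrogates: int | None = None,
) -> tuple[pd.DataFrame, list[QCReport]]:
    """Parameter table + QC reports for a list of (well_id, recording).

    The table contains all wells; the ``included`` column and the QC reports
    record each well's fate.  Metadata comes from ``metadata`` or from the
    recordings themselves.
    """
    config = config or RunConfig()
    rows, reports = [], []
    for well_id, well in wells:
        meta = (metadata or {}).get(well_id) or well.metadata or RecordingMetadata(well_id=well_id)
        params = extract_parameters(well, config, n_surrogates=n_surrogates)
        flags = params.pop("flags")
        qc_input = {
            **params,
            "div": meta.div,
            "disease_status": meta.disease_status,
            "manual_exclude": meta.manual_exclude,
            "well_id": well_id,
        }
        report = well_inclusion(qc_input, config.qc, well_id=well_id)
        reports.append(report)
        rows.append({
            "well_id": well_id, "line_id": meta.line_id, "div": meta.div,
            "mea_batch": meta.mea_batch, "astro_batch": meta.astro_batch,
            "sex": meta.sex, "donor_age": meta.donor_age,
            "disease_status": meta.disease_status, "coating": meta.coating,
            **params,
            "included": report.included,
            "exclusion_reasons": ";".join(report.reasons),
            "flags": ";".join(flags),
        })
    return pd.DataFrame(rows), reports


def run_analyze(config: RunConfig) -> dict:
    """File-level pipeline: read wells, analyze, QC, write outputs.

    Writes ``parameter_table.csv`` (all wells), ``parameter_table_included.csv``
    (QC-passing wells only), ``qc_report.csv``, ``run_log.jsonl`` and
    ``config.yaml`` into the output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    in_dir = Path(config.input_dir)
    suffix = ".mat" if config.dialect == "mcs_mat" else ".h5"
    paths = sorted(in_dir.glob(f"*{suffix}"))
    if not paths:
        raise MeaPhenoError(f"no readable {config.dialect} wells in {in_dir}")
    meta_path = in_dir / "metadata.csv"
    metadata = {}
    if meta_path.exists():
        metadata = {m.well_id: m for m in read_metadata_table(meta_path)}

    wells = [(p.stem, read_peak_trains(p, config.dialect)) for p in paths]
    table, reports = analyze_wells(wells, config, metadata)

    log_path = out / "run_log.jsonl"
    with log_path.open("w") as fh:
        for r in reports:
            fh.write(json.dumps({
                "well_id": r.well_id, "included": r.included,
                "reasons": r.reasons, "metrics": r.metrics,
            }, sort_keys=True) + "\n")

    included = table[table["included"]].drop(columns=["included", "exclusion_reasons"])
    if included.empty:
        logger.warning("ALL %d wells excluded by QC: empty parameter table", len(table))
    table.to_csv(out / "parameter_table.csv", index=False)
    included.to_csv(out / "parameter_table_included.csv", index=False)
    pd.DataFrame([{
        "well_id": r.well_id, "included": r.included,
        "reasons": ";".join(r.reasons), **r.metrics,
    } for r in reports]).to_csv(out / "qc_report.csv", index=False)
    config.to_yaml(out / "config.yaml")
    return {
        "table": table, "included": included, "qc_reports": reports,
        "output_dir": out, "run_log": log_path,
    }


def run_report(table: pd.DataFrame, params=None) -> str:
    """Human-readable per-line summary: mean +/- SEM for each parameter."""
    from .cohort_stats import PARAMETERS, parameter_cv

    params = params or [p for p in PARAMETERS if p in table.columns]
    lines = []
    if table.empty:
        return "Report: zero wells after quality control.\n"
    lines.append(f"Report: {len(table)} wells, {table['line_id'].nunique()} line(s)\n")
    for line_id, grp in table.groupby("line_id"):
        lines.append(f"Line {line_id} (n = {len(grp)} wells)")
        for p in params:
            v = grp[p].dropna().to_numpy(dtype=float)
            if v.size == 0:
                lines.append(f"  {p:>16}: undefined")
            elif v.size == 1:
                lines.append(f"  {p:>16}: {v[0]:.4g} (single well; SEM undefined)")
            else:
                sem = v.std(ddof=1) / np.sqrt(v.size)
                lines.append(f"  {p:>16}: {v.mean():.4g} ± {sem:.2g} (SEM)")
        lines.append("")
    if table["line_id"].nunique() >= 2:
        cv = parameter_cv(table, params=params)
        lines.append("Parameter stability (CV% across wells, mean over lines):")
        for p, row in cv.iterrows():
            tag = "stable" if row["stable"] else "variable"
            lines.append(f"  {p:>16}: {row['mean_cv_pct']:.1f}% ({tag})")
    return "\n".join(lines) + "\n"


__all__ = [
    "RunConfig", "extract_parameters", "analyze_wells", "run_analyze",
    "run_report", "EXIT_OK", "EXIT_VALIDATION", "EXIT_EMPTY",
]
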