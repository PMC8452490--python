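"""Quality control, inclusion criteria, and developmental-window pooling.

Inclusion criteria for a well (defaults; all configurable):

- MFR  > 0.1 spikes/s            (LOW_MFR)
- BR   > 0.4 bursts/min          (LOW_BR)
- NBR  > 1 NB/min                (LOW_NBR)
- active electrodes > 80%        (LOW_ACTIVE_FRACTION)
- mean NB channel participation > 25%   (LOW_NB_PARTICIPATION)
- network bursts present at DIV 27      (NO_NB_AT_DIV27)
- manual exclusion honored from metadata (MANUAL_EXCLUSION) — visual culture
  quality (density, clumping) cannot be judged from spike data, so it enters
  as a curator-provided column rather than a pretend-automated score.

Values exactly at a threshold are kept.  "Channel participation" is the mean
fraction of participating channels across a well's network bursts.  Wells are
pooled over the stable developmental window DIV 27-35; mixing earlier DIVs or
different coating substrates degrades comparability and is warned about.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io_peaktrains import N_ELECTRODES, WellRecording

logger = logging.getLogger(__name__)


@dataclass
class QCSettings:
    min_mfr: float = 0.1            # spikes/s
    min_br: float = 0.4             # bursts/min
    min_nbr: float = 1.0            # NB/min
    min_active_fraction: float = 0.8
    min_nb_channel_fraction: float = 0.25
    active_rate_threshold: float = 1.0 / 60.0  # spikes/s (~1 spike/min)
    div27_nb_required: bool = True
    #: the five activity criteria are stated for control networks; a patient
    #: well must not be dropped for expressing its (hypoactive) phenotype
    control_only_activity_criteria: bool = True


@dataclass
class QCReport:
    well_id: str
    included: bool
    reasons: list[str] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)
    settings: QCSettings = field(default_factory=QCSettings)


class QCWarning(NamedTuple):
    line_id: str
    code: str
    message: str


def active_electrode_fraction(
    well: WellRecording, min_rate: float = 1.0 / 60.0
) -> float:
    """Fraction of the 12 electrode slots with firing rate >= min_rate."""
    active = sum(1 for t in well.trains if t.rate(well.duration) >= min_rate)
    return active / N_ELECTRODES


def well_inclusion(
    params: dict,
    qc_settings: QCSettings | None = None,
    well_id: str = "",
) -> QCReport:
    """Evaluate all inclusion criteria on one well's parameter/metric dict.

    ``params`` must provide MFR, BR, NBR, active_fraction and
    nb_channel_fraction; optionally div, n_network_bursts and manual_exclude.
    Every failed criterion contributes a machine-readable reason code.
    """
    qc = qc_settings or QCSettings()
    reasons: list[str] = []

    def _get(key: str) -> float:
        v = params.get(key, float("nan"))
        return float(v) if v is not None else float("nan")

    mfr, br, nbr = _get("MFR"), _get("BR"), _get("NBR")
    active = _get("active_fraction")
    nb_part = _get("nb_channel_fraction")
    is_control = str(params.get("disease_status", "control")) == "control"
    if is_control or not qc.control_only_activity_criteria:
        if not mfr >= qc.min_mfr:
            reasons.append("LOW_MFR")
        if not br >= qc.min_br:
            reasons.append("LOW_BR")
        if not nbr >= qc.min_nbr:
            reasons.append("LOW_NBR")
        if not active >= qc.min_active_fraction:
            reasons.append("LOW_ACTIVE_FRACTION")
        if not nb_part >= qc.min_nb_channel_fraction:
            reasons.append("LOW_NB_PARTICIPATION")
    if (
        qc.div27_nb_required
        and int(params.get("div", -1)) == 27
        and int(params.get("n_network_bursts", 1)) == 0
    ):
        reasons.append("NO_NB_AT_DIV27")
    if params.get("manual_exclude", False):
        reasons.append("MANUAL_EXCLUSION")

    report = QCReport(
        well_id=well_id or str(params.get("well_id", "")),
        included=not reasons,
        reasons=reasons,
        metrics={
            "MFR": mfr, "BR": br, "NBR": nbr,
            "active_fraction": active, "nb_channel_fraction": nb_part,
        },
        settings=qc,
    )
    if reasons:
        logger.info("well %s excluded: %s", report.well_id, ",".join(reasons))
    return report


def pool_development_window(
    table: pd.DataFrame, div_lo: int = 27, div_hi: int = 35
) -> pd.DataFrame:
    """Keep rows within the stable developmental window [div_lo, div_hi].

    Warns (log) about discarded out-of-window rows and about coating mixtures
    among the retained rows; mixed-coating rows are retained.
    """
    if "div" not in table.columns:
        raise KeyError("parameter table lacks a 'div' column")
    keep = table[(table["div"] >= div_lo) & (table["div"] <= div_hi)]
    n_dropped = len(table) - len(keep)
    if n_dropped:
        logger.warning(
            "pool_development_window: discarded %d wells outside DIV %d-%d",
            n_dropped, div_lo, div_hi,
        )
    if "coating" in keep.columns:
        coatings = set(keep["coating"].dropna()) - {"unknown"}
        if len(coatings) > 1:
            logger.warning(
                "pool_development_window: mixed coatings %s in pooled data; "
                "comparability across substrates is not guaranteed",
                sorted(coatings),
            )
    return keep.copy()


def batch_sufficiency_check(
    table: pd.DataFrame,
    min_wells: int = 12,
    min_batches: int = 2,
) -> list[QCWarning]:
    """Warn when a line has too few wells or too few MEA batches.

    The recommended design is >= 12 wells per line spread over >= 2
    independent MEA batches so batch variance can be told apart from line
    effects.
    """
    out: list[QCWarning] = []
    if "line_id" not in table.columns:
        raise KeyError("parameter table lacks a 'line_id' column")
    for line, grp in table.groupby("line_id"):
        if len(grp) < min_wells:
            out.append(QCWarning(str(line), "LOW_N",
                                 f"{line}: {len(grp)} wells < {min_wells}"))
        n_batches = grp["mea_batch"].nunique() if "mea_batch" in grp.columns else 1
        if n_batches < min_batches:
            out.append(QCWarning(str(line), "SINGLE_BATCH",
                                 f"{line}: {n_batches} MEA batch(es) < {min_batches}"))
    for w in out:
        logger.warning("%s", w.message)
    return out


def flag_development_reduction(
    table: pd.DataFrame,
    parameters: tuple[str, ...] = ("NBR", "MFR"),
    drop_fraction: float = 0.5,
) -> list[QCWarning]:
    """Optional screen for wells whose network parameters fall across DIVs.

    Flags (never auto-excludes) wells where a parameter drops by more than
    ``drop_fraction`` of its value between consecutive recorded DIVs; the
    quantitative criterion for the exclusion rule is a curator decision.
    """
    out: list[QCWarning] = []
    if "well_id" not in table.columns or "div" not in table.columns:
        return out
    for well, grp in table.groupby("well_id"):
        grp = grp.sort_values("div")
        for p in parameters:
            if p not in grp.columns or len(grp) < 2:
                continue
            v = grp[p].to_numpy(dtype=float)
            prev, cur = v[:-1], v[1:]
            with np.errstate(divide="ignore", invalid="ignore"):
                drop = (prev - cur) / prev
            if np.any(drop > drop_fraction):
                out.append(QCWarning(str(well), "DEVELOPMENT_REDUCTION",
                                     f"{well}: {p} drops >{drop_fraction:.0%} across DIVs"))
                break
    return out


__all__ = [
    "QCSettings", "QCReport", "QCWarning",
    "active_electrode_fraction", "well_inclusion",
    "pool_development_window", "batch_sufficiency_check",
    "flag_development_reduction",
]
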