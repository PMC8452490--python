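"""Shared fixtures: simulated wells and cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import meapheno as mp
from meapheno.pipeline import RunConfig, analyze_wells


@pytest.fixture(scope="session")
def control_well():
    """One 10-minute control-preset well with its ground truth."""
    return mp.simulate_well(mp.preset_phenotype("control"), 600.0, seed=1)


@pytest.fixture(scope="session")
def control_recovery_wells():
    """20 independent control-preset wells for parameter-recovery checks."""
    return [mp.simulate_well(mp.preset_phenotype("control"), 600.0, seed=100 + i)
            for i in range(20)]


@pytest.fixture(scope="session")
def three_line_cohort():
    """Control / MELAS-like / KS-like cohort (12 wells each) plus its
    parameter table computed by the full pipeline (links skipped)."""
    design = mp.ExperimentDesign(
        lines=[
            mp.LineSpec("C_sim", mp.preset_phenotype("control"), "control"),
            mp.LineSpec("M_sim", mp.preset_phenotype("melas_like"), "MELAS"),
            mp.LineSpec("K_sim", mp.preset_phenotype("ks_like"), "KS"),
        ],
        wells_per_line=12, mea_batches=2, astro_batches=2,
        batch_effect_sd=0.2, well_noise_sd=0.2, duration=600.0, seed=11,
    )
    wells, gt = mp.simulate_cohort(design)
    table, reports = analyze_wells(
        [(wid, w) for wid, w, _ in wells], RunConfig(), n_surrogates=0
    )
    return {"wells": wells, "ground_truth": gt, "table": table, "reports": reports}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_poisson_well(rate: float, duration: float, seed: int,
                      n_channels: int = 12) -> mp.WellRecording:
    """Independent Poisson trains on every electrode (no correlation)."""
    r = np.random.default_rng(seed)
    trains = [
        mp.SpikeTrain(np.unique(np.sort(r.uniform(0, duration, r.poisson(rate * duration)))),
                      None, k + 1)
        for k in range(n_channels)
    ]
    return mp.WellRecording(trains=trains, duration=duration)
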