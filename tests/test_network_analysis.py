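"""Network-burst detection, statistics, shapes and rise/decay timing."""

import numpy as np
import pytest
from scipy import stats as sps

import meapheno as mp
from meapheno.errors import AnalysisError
from meapheno.network_analysis import (
    NetworkBurstSettings,
    NetworkBurstShape,
    resolve_rate_threshold,
    settings_from_latest_div,
)
from oracles import network_burst_oracle


def _well_with_events(event_times, n_channels=12, spikes_per_channel=10,
                      event_len=0.1, duration=60.0):
    trains = []
    for k in range(1, 13):
        ts = []
        if k <= n_channels:
            for t0 in event_times:
                ts.append(t0 + np.linspace(0, event_len, spikes_per_channel))
        tt = np.sort(np.concatenate(ts)) if ts else np.empty(0)
        tt += np.linspace(0, 1e-6, tt.size)  # break exact cross-channel ties
        trains.append(mp.SpikeTrain(tt, None, k))
    return mp.WellRecording(trains=trains, duration=duration)


def test_three_synchronous_events_are_three_network_bursts():
    well = _well_with_events([10.0, 20.0, 30.0])
    nbs = mp.detect_network_bursts(well)
    assert len(nbs) == 3
    for nb, t0 in zip(nbs, (10.0, 20.0, 30.0)):
        assert len(nb.participating_channels) == 12
        assert nb.start == pytest.approx(t0, abs=1e-3)
        assert nb.n_spikes == 120


def test_two_channel_events_fail_participation():
    well = _well_with_events([10.0, 20.0, 30.0], n_channels=2)
    assert mp.detect_network_bursts(well) == []


def test_exactly_25pct_participation_is_not_enough():
    """Table-style strict criterion: 3 of 12 channels is not > 25%."""
    assert mp.detect_network_bursts(_well_with_events([10.0], n_channels=3)) == []
    assert len(mp.detect_network_bursts(_well_with_events([10.0], n_channels=4))) == 1


def test_empty_well_has_no_network_bursts():
    assert mp.detect_network_bursts(mp.WellRecording(trains=[], duration=60.0)) == []


def test_network_burst_oracle_equivalence_on_random_wells():
    settings = NetworkBurstSettings(
        bin_width=0.05, rate_threshold=100.0, min_channel_fraction=0.25,
        merge_gap=0.15, participation_min_spikes=2,
    )
    for seed in range(30):
        r = np.random.default_rng(seed)
        trains = []
        for k in range(1, 13):
            n = r.integers(0, 60)
            base = np.sort(r.uniform(0, 20, n))
            # add synchronized clumps on some channels
            if k <= 8:
                for t0 in (5.0, 12.0):
                    base = np.r_[base, t0 + r.uniform(0, 0.1, 6)]
            trains.append(mp.SpikeTrain(np.unique(np.sort(base)), None, k))
        well = mp.WellRecording(trains=trains, duration=20.0)
        got = mp.detect_network_bursts(well, settings)
        expected = network_burst_oracle(
            well, settings.bin_width, settings.rate_threshold,
            settings.min_channel_fraction, settings.merge_gap,
            settings.participation_min_spikes,
        )
        assert len(got) == len(expected)
        for nb, (s, e, ch) in zip(got, expected):
            assert nb.start == pytest.approx(s) and nb.end == pytest.approx(e)
            assert nb.participating_channels == ch


def test_raising_threshold_never_adds_network_bursts(control_well):
    well, _ = control_well
    counts = []
    for thr in (60.0, 120.0, 300.0, 800.0):
        s = NetworkBurstSettings(rate_threshold=thr)
        counts.append(len(mp.detect_network_bursts(well, s)))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_network_bursts_do_not_overlap(control_well):
    well, _ = control_well
    nbs = mp.detect_network_bursts(well)
    assert all(b.start > a.end for a, b in zip(nbs, nbs[1:]))


def test_network_burst_statistics_hand_computed():
    nbs = [mp.NetworkBurst(t, t + 1.0, frozenset(range(1, 13)), 100)
           for t in (0.0, 10.0, 20.0, 30.0)]
    out = mp.network_burst_statistics(nbs, 600.0)
    assert out["NBR"] == pytest.approx(0.4)
    assert out["NBD"] == pytest.approx(1.0)
    assert out["NIBI"] == pytest.approx(9.0)
    assert out["CV_NIBI"] == pytest.approx(0.0, abs=1e-12)

    gaps_5_10 = [mp.NetworkBurst(0, 1, frozenset(range(1, 13)), 10),
                 mp.NetworkBurst(6, 7, frozenset(range(1, 13)), 10),
                 mp.NetworkBurst(17, 18, frozenset(range(1, 13)), 10)]
    out = mp.network_burst_statistics(gaps_5_10, 600.0)
    assert out["NIBI"] == pytest.approx(7.5)
    assert out["CV_NIBI"] == pytest.approx(np.std([5, 10], ddof=1) / 7.5)

    nineteen = [mp.NetworkBurst(i * 30.0, i * 30.0 + 1, frozenset(range(1, 13)), 10)
                for i in range(19)]
    assert mp.network_burst_statistics(nineteen, 600.0)["NBR"] == pytest.approx(1.9)

    single = mp.network_burst_statistics(nineteen[:1], 600.0)
    assert np.isnan(single["NIBI"]) and "NIBI_UNDEFINED" in single["flags"]


def test_boxcar_shape_flat_top_and_peak_normalization():
    well = _well_with_events([10.0], spikes_per_channel=200, event_len=0.5)
    nbs = mp.detect_network_bursts(well)
    shape = mp.network_burst_shape(well, nbs, bin_width=0.025, window=0.6,
                                   normalization="peak", pre_window=0.0)
    assert shape.profile.max() == pytest.approx(1.0)
    interior = shape.profile[2:18]
    assert interior.min() > 0.8  # flat top

    with_rise = mp.network_burst_shape(well, nbs, bin_width=0.025, window=0.6,
                                       pre_window=0.05)
    rd = mp.rise_decay_times(with_rise)
    assert "DEGENERATE_PLATEAU" in rd["flags"]
    assert rd["RT"] <= 2 * with_rise.bin_width


def test_single_nb_shape_equals_its_binned_rate():
    well = _well_with_events([10.0], spikes_per_channel=50, event_len=0.4)
    nbs = mp.detect_network_bursts(well)
    assert len(nbs) == 1
    shape = mp.network_burst_shape(well, nbs, bin_width=0.05, window=0.5,
                                   pre_window=0.0)
    ts = well.all_spike_times()
    counts, _ = np.histogram(ts, bins=10, range=(nbs[0].start, nbs[0].start + 0.5))
    np.testing.assert_allclose(shape.profile, counts / 0.05)


def test_no_network_bursts_is_an_error_for_shapes():
    well = mp.WellRecording(trains=[], duration=10.0)
    with pytest.raises(AnalysisError):
        mp.network_burst_shape(well, [])


def test_gamma_envelope_recovered_in_mean_shape():
    """200 NBs with a gamma(k=2, theta=0.1 s) envelope: the mean profile
    matches the analytic (truncated) density within 5% RMS of its peak."""
    rng = np.random.default_rng(9)
    k_shape, theta, upper, n_nb, per_nb = 2.0, 0.1, 1.0, 200, 600
    onsets = 10.0 + np.arange(n_nb) * 3.0
    mass = sps.gamma.cdf(upper, a=k_shape, scale=theta)
    trains = [[] for _ in range(12)]
    for t0 in onsets:
        offs = sps.gamma.ppf(rng.uniform(0, mass, per_nb), a=k_shape, scale=theta)
        for i, o in enumerate(offs):
            trains[i % 12].append(t0 + o)
    well = mp.WellRecording(
        trains=[mp.SpikeTrain(np.unique(np.sort(t)), None, i + 1)
                for i, t in enumerate(trains)],
        duration=float(onsets[-1] + 5),
    )
    nbs = [mp.NetworkBurst(t0, t0 + upper, frozenset(range(1, 13)), per_nb)
           for t0 in onsets]
    shape = mp.network_burst_shape(well, nbs, bin_width=0.01, window=upper,
                                   pre_window=0.0)
    t = shape.times
    analytic = per_nb * sps.gamma.pdf(t, a=k_shape, scale=theta) / mass
    rms = np.sqrt(np.mean((shape.profile - analytic) ** 2))
    assert rms < 0.05 * analytic.max()
    rd = mp.rise_decay_times(shape)
    assert rd["DT"] > rd["RT"]  # right-skewed envelope decays slower than it rises


def test_triangular_profile_is_symmetric():
    prof = np.concatenate([np.linspace(0, 1, 101)[1:], np.linspace(1, 0, 101)[1:-1]])
    shape = NetworkBurstShape(0.005, prof)
    rd = mp.rise_decay_times(shape, lo_frac=1e-9)
    assert rd["RT"] == pytest.approx(rd["DT"], abs=0.02)
    assert rd["RT"] == pytest.approx(0.5, abs=0.02)


def test_peak_at_edge_is_flagged_undefined():
    shape = NetworkBurstShape(0.005, np.linspace(0, 1, 50))  # peak at last bin
    rd = mp.rise_decay_times(shape)
    assert np.isnan(rd["RT"]) and np.isnan(rd["DT"])
    assert "PEAK_AT_EDGE" in rd["flags"]


def test_settings_frozen_at_latest_div(control_well):
    well, _ = control_well
    base = NetworkBurstSettings()
    frozen = settings_from_latest_div({27: well, 35: well}, base)
    assert frozen.rate_threshold == pytest.approx(resolve_rate_threshold(well, base))
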