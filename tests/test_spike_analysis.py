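"""Spike detection and derived rebound/excitability measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modvar.spike_analysis import (
    SpikeTrain,
    SweepSet,
    align_to_releases,
    cumulative_spike_histogram,
    detect_spikes,
    latency_time_constant,
    rebound_latency,
    steady_state_selection,
    step_mean_frequency,
)


def _spiky_trace(spike_times, t_end=1000.0, dt=0.1, width=1.0, v_rest=-60.0):
    t = np.arange(0.0, t_end, dt)
    v = np.full_like(t, v_rest)
    for ts in spike_times:
        v[(t >= ts) & (t < ts + width)] = 10.0
    return t, v


def test_detect_spikes_flat_and_constructed():
    t = np.arange(0.0, 500.0, 0.1)
    assert len(detect_spikes(t, np.full_like(t, -60.0))) == 0
    t, v = _spiky_trace([100.0, 200.0])
    train = detect_spikes(t, v, threshold=-20.0)
    assert train.times == pytest.approx([100.0, 200.0], abs=0.2)


def test_detect_spikes_counts_seeded_events_with_refractory():
    rng = np.random.default_rng(42)
    spike_times = np.sort(rng.uniform(10.0, 4990.0, size=50))
    # enforce generator-side separation > refractory
    while np.any(np.diff(spike_times) < 5.0):
        spike_times = np.sort(rng.uniform(10.0, 4990.0, size=50))
    t, v = _spiky_trace(spike_times, t_end=5000.0)
    v += rng.normal(0.0, 1.5, size=v.size)  # subthreshold noise
    train = detect_spikes(t, v, threshold=-20.0, refractory=2.0)
    assert len(train) == 50


def test_detect_spikes_ignores_downward_crossings():
    t, v = _spiky_trace([100.0, 300.0])
    inverted = -120.0 - v  # mirror far below threshold
    assert len(detect_spikes(t, inverted, threshold=-20.0)) == 0


def test_detect_spikes_requires_uniform_grid():
    t = np.array([0.0, 1.0, 3.0, 4.0])
    with pytest.raises(ValueError):
        detect_spikes(t, np.zeros_like(t))


def test_step_mean_frequency_examples():
    train = SpikeTrain(np.arange(100.0, 1000.0, 100.0))
    assert step_mean_frequency(train, (0.0, 1000.0)) == pytest.approx(10.0)
    assert step_mean_frequency(SpikeTrain(np.array([500.0])), (0.0, 1000.0)) == 0.0
    train2 = SpikeTrain(np.array([0.0, 100.0, 150.0, 200.0]))
    assert step_mean_frequency(train2, (0.0, 250.0)) == pytest.approx(
        np.mean([10.0, 20.0, 20.0])
    )


@given(shift=st.floats(-5000.0, 5000.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_step_mean_frequency_shift_invariance(shift):
    times = np.array([10.0, 30.0, 70.0, 150.0]) + 6000.0
    train = SpikeTrain(times + shift)
    epoch = (6000.0 + shift, 6200.0 + shift)
    ref = step_mean_frequency(SpikeTrain(times), (6000.0, 6200.0))
    assert step_mean_frequency(train, epoch) == pytest.approx(ref)


def test_rebound_latency_definition_and_missing():
    train = SpikeTrain(np.array([10_230.0, 10_500.0]))
    assert rebound_latency(train, 10_000.0) == pytest.approx(0.23)
    assert rebound_latency(SpikeTrain(np.empty(0)), 10_000.0) is None
    lat = [0.2, 0.25, 0.22, 0.21, 0.22]
    assert np.mean(lat) == pytest.approx(0.22)


def test_cumulative_histogram_conservation():
    sweeps = SweepSet([SpikeTrain(np.array([10.0, 20.0, 30.0, 40.0, 50.0]))])
    edges, counts, cum = cumulative_spike_histogram(sweeps, 200.0, 10_000.0)
    assert counts[0] == 5 and counts[1:].sum() == 0
    assert cum[-1] == 5
    assert np.all(cum == 5)  # jumps to 5 and stays
    # empty sweeps -> all-zero histogram
    _, counts0, cum0 = cumulative_spike_histogram(SweepSet([SpikeTrain(np.empty(0))]), 200.0, 10_000.0)
    assert counts0.sum() == 0 and cum0[-1] == 0


def test_cumulative_histogram_counts_equal_detected_spikes_exactly():
    rng = np.random.default_rng(3)
    sweeps = SweepSet(
        [SpikeTrain(np.unique(rng.uniform(0.0, 9999.0, size=40))) for _ in range(5)]
    )
    total = sum(len(s) for s in sweeps)
    _, counts, cum = cumulative_spike_histogram(sweeps, 100.0, 10_000.0)
    assert counts.sum() == total == cum[-1]


def test_cumulative_histogram_bin_must_divide_horizon():
    with pytest.raises(ValueError):
        cumulative_spike_histogram(SweepSet([]), 300.0, 10_000.0)


def test_steady_state_selection():
    sweeps = SweepSet([SpikeTrain(np.array([float(i)]), sweep_id=i) for i in range(20)])
    last10 = steady_state_selection(sweeps, 10)
    assert [s.sweep_id for s in last10] == list(range(10, 20))
    assert [s.sweep_id for s in steady_state_selection(sweeps, 20)] == list(range(20))
    assert len(steady_state_selection(sweeps, 0)) == 0
    with pytest.raises(ValueError):
        steady_state_selection(sweeps, 21)


def test_latency_time_constant_rule():
    # threshold = 1.0 − 0.63·(1.0−0.25) = 0.5275 -> first pulse at/below is #3
    assert latency_time_constant([1.0, 0.6, 0.4, 0.3, 0.26, 0.25]) == 3
    assert latency_time_constant([0.4, 0.4, 0.4]) == 1  # zero-drop convention
    linear = np.linspace(1.0, 0.1, 10)
    assert latency_time_constant(linear) == 7


def test_align_to_releases_slices_and_rebases():
    train = SpikeTrain(np.array([100.0, 10_200.0, 10_900.0, 30_050.0]))
    sweeps = align_to_releases(train, [10_000.0, 30_000.0], 10_000.0)
    assert sweeps.sweeps[0].times == pytest.approx([200.0, 900.0])
    assert sweeps.sweeps[1].times == pytest.approx([50.0])
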