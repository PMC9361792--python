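"""Spike detection and the derived excitability / rebound measures.

Turns voltage traces into spike trains and computes per-step mean
instantaneous frequency, rebound latency, release-aligned spike
histograms with cumulative curves, steady-state sweep selection and the
63%-drop latency time constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SpikeTrain",
    "SweepSet",
    "detect_spikes",
    "step_mean_frequency",
    "rebound_latency",
    "align_to_releases",
    "cumulative_spike_histogram",
    "steady_state_selection",
    "latency_time_constant",
]


@dataclass
class SpikeTrain:
    """Sorted spike times (ms) relative to sweep start."""

    times: np.ndarray
    sweep_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class SweepSet:
    """Release-aligned spike trains, one per sweep/pulse."""

    sweeps: List[SpikeTrain] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)


def detect_spikes(
    t: np.ndarray,
    v: np.ndarray,
    threshold: float = -20.0,
    refractory: float = 2.0,
) -> SpikeTrain:
    """One spike per upward threshold crossing, separated by >= refractory.

    ``t`` must be a uniform grid (ms).  Deterministic; the spike time is
    the time of the first suprathreshold sample of each crossing.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.shape != v.shape:
        raise ValueError("t and v must have the same shape")
    if t.size >= 3:
        dts = np.diff(t)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform")
    idx = np.nonzero((v[1:] >= threshold) & (v[:-1] < threshold))[0] + 1
    if idx.size == 0:
        return SpikeTrain(np.empty(0))
    times = t[idx]
    kept = [times[0]]
    for tt in times[1:]:
        if tt - kept[-1] >= refractory:
            kept.append(tt)
    return SpikeTrain(np.asarray(kept))


def step_mean_frequency(
    train: SpikeTrain, epoch: Tuple[float, float]
) -> float:
    """Mean instantaneous frequency (Hz) of spikes inside [t0, t1) ms.

    The mean of reciprocal interspike intervals; 0 Hz for fewer than two
    spikes (subthreshold steps count as zero for f–I fitting).
    """
    t0, t1 = epoch
    if t1 <= t0:
        raise ValueError("epoch must have positive duration")
    inside = train.times[(train.times >= t0) & (train.times < t1)]
    if inside.size < 2:
        return 0.0
    return float(np.mean(1000.0 / np.diff(inside)))


def rebound_latency(
    train: SpikeTrain, release_ms: float, window_ms: float = 10_000.0
) -> Optional[float]:
    """Latency (s) from release of hyperpolarization to the first spike.

    Returns None ("missing") when no spike falls inside the window; the
    caller excludes such sweeps from group statistics.
    """
    if window_ms <= 0:
        raise ValueError("window must be > 0")
    after = train.times[(train.times >= release_ms) & (train.times < release_ms + window_ms)]
    if after.size == 0:
        return None
    return float((after[0] - release_ms) / 1000.0)


def align_to_releases(
    train: SpikeTrain, release_times_ms: Sequence[float], horizon_ms: float
) -> SweepSet:
    """Slice one long spike train into release-aligned sweeps.

    Each sweep holds the spike times (ms, relative to its release) falling
    in [0, horizon) after that release.
    """
    sweeps = []
    for k, rel in enumerate(release_times_ms):
        sel = train.times[(train.times >= rel) & (train.times < rel + horizon_ms)]
        sweeps.append(SpikeTrain(sel - rel, sweep_id=k))
    return SweepSet(sweeps)


def cumulative_spike_histogram(
    sweeps: SweepSet, bin_ms: float, horizon_ms: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled release-aligned spike histogram and its cumulative curve.

    Returns (bin_edges ms, counts per bin, cumulative counts).  The final
    cumulative value equals the total number of spikes in [0, horizon)
    exactly (conservation).  ``bin_ms`` must divide the horizon.
    """
    n_bins = horizon_ms / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin size must divide the horizon")
    edges = np.arange(0.0, horizon_ms + bin_ms / 2, bin_ms)
    all_times = np.concatenate([s.times for s in sweeps]) if len(sweeps) else np.empty(0)
    all_times = all_times[(all_times >= 0) & (all_times < horizon_ms)]
    counts, _ = np.histogram(all_times, bins=edges)
    return edges, counts, np.cumsum(counts)


def steady_state_selection(sweeps: SweepSet, keep_last: int) -> SweepSet:
    """Trailing ``keep_last`` sweeps, original sweep ids retained."""
    if keep_last < 0 or keep_last > len(sweeps):
        raise ValueError("keep_last must lie in [0, n_sweeps]")
    if keep_last == 0:
        return SweepSet([])
    return SweepSet(list(sweeps.sweeps[-keep_last:]))


def latency_time_constant(latencies: Sequence[float]) -> int:
    """Pulse number (1-based) at which latency has dropped by 63% of its
    total drop from the first pulse to the minimum.

    With zero total drop the convention is pulse 1.
    """
    lat = np.asarray(latencies, dtype=float)
    if lat.size < 2:
        raise ValueError("need at least two latencies")
    first = lat[0]
    drop = first - lat.min()
    if drop <= 0:
        return 1
    threshold = first - 0.63 * drop
    below = np.nonzero(lat <= threshold)[0]
    return int(below[0]) + 1
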