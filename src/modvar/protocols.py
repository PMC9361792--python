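"""Current-injection protocols as explicit time–amplitude programs.

A waveform is an ordered list of segments (duration ms, amplitude nA,
epoch label); epochs tile the waveform without gaps or overlap.  Both the
conductance-based and the integrate-and-fire simulators consume these, as
do the synthetic-data generators.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["Segment", "InjectionWaveform", "make_fi_protocol", "make_pulse_protocol"]


@dataclass(frozen=True)
class Segment:
    duration: float  # ms
    amplitude: float  # nA
    label: str

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be > 0")


@dataclass
class InjectionWaveform:
    """Piecewise-constant injected-current program."""

    segments: List[Segment] = field(default_factory=list)
    name: str = ""

    @property
    def total_duration(self) -> float:
        """Total length in ms."""
        return sum(s.duration for s in self.segments)

    def epochs(self) -> List[Tuple[str, float, float, float]]:
        """(label, t_start ms, t_end ms, amplitude) for every segment."""
        out, t = [], 0.0
        for s in self.segments:
            out.append((s.label, t, t + s.duration, s.amplitude))
            t += s.duration
        return out

    def epoch(self, label: str) -> Tuple[str, float, float, float]:
        for e in self.epochs():
            if e[0] == label:
                return e
        raise KeyError(f"no epoch labeled {label!r}")

    def release_times(self) -> List[float]:
        """End times (ms) of every segment labeled as an 'on' pulse.

        A release is the transition out of a segment whose label ends in
        ':on' — the moment the hyperpolarizing current is removed.
        """
        out = []
        for label, t0, t1, _amp in self.epochs():
            if label.endswith(":on"):
                out.append(t1)
        return out

    def to_samples(self, dt: float) -> np.ndarray:
        """Sample the waveform on a uniform grid of step dt (ms).

        Returns the amplitude at the *start* of each of
        round(total/dt) steps.
        """
        if dt <= 0:
            raise ValueError("dt must be > 0")
        n_total = int(round(self.total_duration / dt))
        out = np.empty(n_total, dtype=np.float64)
        i = 0
        t_acc = 0.0
        for s in self.segments:
            t_acc += s.duration
            j = int(round(t_acc / dt))
            out[i:j] = s.amplitude
            i = j
        out[i:] = self.segments[-1].amplitude if self.segments else 0.0
        return out

    # -- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"t_start": t0, "duration": t1 - t0, "amplitude": amp, "epoch_label": lab}
            for lab, t0, t1, amp in self.epochs()
        ]
        return pd.DataFrame(rows, columns=["t_start", "duration", "amplitude", "epoch_label"])

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "") -> "InjectionWaveform":
        segs = [
            Segment(float(r.duration), float(r.amplitude), str(r.epoch_label))
            for r in df.itertuples()
        ]
        return cls(segments=segs, name=name)

    @classmethod
    def from_csv(cls, path_or_buf, name: str = "") -> "InjectionWaveform":
        return cls.from_frame(pd.read_csv(path_or_buf), name=name)


def make_fi_protocol(
    kind: str = "experimental",
    step_s: float = 5.0,
    repeat_apex: bool = False,
    rest_s: float = 0.0,
) -> InjectionWaveform:
    """Current-step program for f–I measurement.

    ``experimental``: 0 → 5 nA in 0.5 nA increments (11 steps) followed by
    the descending limb back to 0; by default the 5 nA apex is not
    repeated (21 steps total).  ``model``: −10 → 5.5 nA in 0.5 nA
    increments (32 ascending steps only).  Step duration defaults to 5 s.
    ``rest_s`` inserts a zero-current rest between steps if nonzero.
    """
    if step_s <= 0:
        raise ValueError("step_s must be > 0")
    step_ms = step_s * 1000.0
    if kind == "experimental":
        up = np.round(np.arange(0.0, 5.0 + 1e-9, 0.5), 10)
        down = up[::-1] if repeat_apex else up[-2::-1]
        amps = list(up) + list(down)
        dirs = ["up"] * len(up) + ["down"] * len(down)
    elif kind == "model":
        amps = list(np.round(np.arange(-10.0, 5.5 + 1e-9, 0.5), 10))
        dirs = ["up"] * len(amps)
    else:
        raise ValueError(f"unknown f-I protocol kind {kind!r}")
    segs: List[Segment] = []
    for i, (a, d) in enumerate(zip(amps, dirs)):
        segs.append(Segment(step_ms, float(a), f"step{i}:{d}:{a:g}nA"))
        if rest_s > 0 and i < len(amps) - 1:
            segs.append(Segment(rest_s * 1000.0, 0.0, f"rest{i}"))
    return InjectionWaveform(segs, name=f"fi_{kind}")


def make_pulse_protocol(kind: str = "rebound_dc") -> InjectionWaveform:
    """Hyperpolarization/release programs for rebound measurement.

    ``rebound_dc``: five sweeps of −5 nA for 10 s followed by 10 s at rest.
    ``periodic``: twenty pulses of −5 nA, 1 s on / 1 s off.
    """
    if kind == "rebound_dc":
        n, on_ms, off_ms = 5, 10_000.0, 10_000.0
    elif kind == "periodic":
        n, on_ms, off_ms = 20, 1_000.0, 1_000.0
    else:
        raise ValueError(f"unknown pulse protocol kind {kind!r}")
    segs: List[Segment] = []
    for i in range(n):
        segs.append(Segment(on_ms, -5.0, f"pulse{i}:on"))
        segs.append(Segment(off_ms, 0.0, f"pulse{i}:off"))
    return InjectionWaveform(segs, name=kind)
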