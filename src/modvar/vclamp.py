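"""Feature extraction from voltage-clamp current recordings.

Implements the virtual versions of the current measurements: maxima of
the total and high-threshold potassium currents at the +20 mV step
(transient and persistent portions for the latter), the A-current as the
pointwise difference of the two, the h-current amplitude over a long
hyperpolarizing step, the synaptic I–V sigmoid scale, and the modulator
current obtained as a Proc − control difference current on the
descending limb of a voltage ramp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fitting import IMIFit, SigmoidFit, fit_imi_iv, fit_sigmoid

__all__ = [
    "VCRecording",
    "KFeatures",
    "extract_k_features",
    "extract_ih_amplitude",
    "extract_syn_strength",
    "imi_difference_current",
]


@dataclass
class VCRecording:
    """Per-step voltage-clamp current traces on a uniform grid.

    ``command`` holds one command-voltage trace per step (mV); for step
    protocols it is constant per row, for ramps it carries the ramp.
    """

    dt: float  # ms
    command: np.ndarray  # (n_steps, n_samples) mV
    current: np.ndarray  # (n_steps, n_samples) nA
    step_mv: np.ndarray  # nominal step level per row (mV)
    condition: str = "control"
    kind: str = ""

    def __post_init__(self) -> None:
        self.command = np.atleast_2d(np.asarray(self.command, dtype=float))
        self.current = np.atleast_2d(np.asarray(self.current, dtype=float))
        self.step_mv = np.asarray(self.step_mv, dtype=float)
        if self.command.shape != self.current.shape:
            raise ValueError("command and current must have identical shape")
        if self.step_mv.shape[0] != self.current.shape[0]:
            raise ValueError("one step level per trace row required")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.current.shape[1]) * self.dt

    def trace_at(self, step_mv: float) -> np.ndarray:
        idx = np.nonzero(np.isclose(self.step_mv, step_mv))[0]
        if idx.size == 0:
            raise KeyError(f"no step at {step_mv} mV")
        return self.current[idx[0]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        t = self.t
        for r in range(self.current.shape[0]):
            rows.append(
                pd.DataFrame(
                    {
                        "time_ms": t,
                        "command_mv": self.command[r],
                        "current_na": self.current[r],
                        "step_id": r,
                        "step_mv": self.step_mv[r],
                        "condition": self.condition,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class KFeatures:
    ik_max: float  # nA, total potassium current maximum at +20 mV
    ihtk_transient: float  # nA
    ihtk_persistent: float  # nA
    ia_max: float  # nA, max of the I_K − I_HTK difference trace


def extract_k_features(
    ik_rec: VCRecording,
    ihtk_rec: VCRecording,
    step_mv: float = 20.0,
    persistent_ms: float = 50.0,
) -> KFeatures:
    """Potassium-current features at the designated voltage step.

    transient = maximum during the step; persistent = mean over the final
    ``persistent_ms``; the A-current trace is the pointwise I_K − I_HTK
    difference, reported as its maximum.
    """
    ik = ik_rec.trace_at(step_mv)
    ihtk = ihtk_rec.trace_at(step_mv)
    if ik.shape != ihtk.shape or not np.isclose(ik_rec.dt, ihtk_rec.dt):
        raise ValueError("I_K and I_HTK step grids must match")
    n_tail = int(round(persistent_ms / ik_rec.dt))
    if n_tail < 1 or n_tail > ik.size:
        raise ValueError("persistent window does not fit inside the step")
    return KFeatures(
        ik_max=float(ik.max()),
        ihtk_transient=float(ihtk.max()),
        ihtk_persistent=float(ihtk[-n_tail:].mean()),
        ia_max=float((ik - ihtk).max()),
    )


def extract_ih_amplitude(rec: VCRecording, settle_ms: float = 20.0) -> float:
    """|current at step end − current after capacitive settling| (nA).

    The single-row recording must span the long hyperpolarizing step; the
    first ``settle_ms`` are excluded as capacitive transient.
    """
    if rec.current.shape[0] != 1:
        raise ValueError("expected a single long hyperpolarizing step")
    trace = rec.current[0]
    i_settle = int(round(settle_ms / rec.dt))
    if i_settle >= trace.size - 1:
        raise ValueError("step shorter than the settling window")
    return float(abs(trace[-1] - trace[i_settle]))


def extract_syn_strength(
    presyn_mv: Sequence[float],
    postsyn_na: Sequence[float],
    baseline_subtract: bool = True,
    seed: int = 0,
) -> SigmoidFit:
    """Sigmoid fit of the synaptic I–V curve; ``a`` is the maximum
    postsynaptic current.

    With ``baseline_subtract`` the current at the most hyperpolarized
    presynaptic step is subtracted, making the scale estimate invariant
    to a constant offset.
    """
    v = np.asarray(presyn_mv, dtype=float)
    i = np.asarray(postsyn_na, dtype=float)
    if v.size != i.size:
        raise ValueError("presyn and postsyn arrays must align")
    if baseline_subtract:
        i = i - i[np.argmin(v)]
    return fit_sigmoid(list(zip(v, i)), mode="synaptic_IV", seed=seed)


def imi_difference_current(
    proc_ramp: VCRecording,
    ctrl_ramp: VCRecording,
    v_range: Tuple[float, float] = (-80.0, 20.0),
    seed: int = 0,
) -> IMIFit:
    """Fit the modulator current from the Proc − control ramp difference.

    Only the descending limb of the ramp is used (the ascending limb
    recruits an additional transient component that is out of scope);
    time is mapped to command voltage before fitting.
    """
    if proc_ramp.command.shape != ctrl_ramp.command.shape or not np.allclose(
        proc_ramp.command, ctrl_ramp.command
    ):
        raise ValueError("ramps are not aligned on an identical command")
    cmd = proc_ramp.command[0]
    diff = proc_ramp.current[0] - ctrl_ramp.current[0]
    apex = int(np.argmax(cmd))
    v_down = cmd[apex:]
    d_down = diff[apex:]
    lo, hi = v_range
    sel = (v_down >= lo) & (v_down <= hi)
    return fit_imi_iv(list(zip(v_down[sel], d_down[sel])), seed=seed)
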