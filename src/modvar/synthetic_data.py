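"""Seeded generators for every input the pipeline consumes.

Each generator embeds its ground truth and seed in the returned metadata
so the analysis stages can be tested closed-loop: at zero noise every
extraction/fit recovers its generator's truth to optimizer tolerance.
These generators stand in for the study's recordings; they produce the
*statistical* structure the analyses assume (power-law f–I points,
logistic cumulative rebound histograms, transient/persistent clamp
currents, normally distributed per-animal parameter tables), not
biophysically realistic noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fitting import imi_iv_curve, power_law, sigmoid
from .spike_analysis import SpikeTrain, SweepSet
from .vclamp import VCRecording

__all__ = [
    "GeneratorSpec",
    "gen_fi_observations",
    "gen_rebound_sweeps",
    "gen_vclamp_recordings",
    "gen_condition_table",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Provenance record attached to every synthetic artifact."""

    seed: int
    noise_sd: float
    truth: Dict[str, object] = field(default_factory=dict)


def gen_fi_observations(
    truth: Tuple[float, float, float],
    grid: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    down_factor: float = 1.0,
) -> Tuple[pd.DataFrame, GeneratorSpec]:
    """(I, f) observations from a power law, ascending and descending limbs.

    ``truth`` is (a, I0, b).  The descending limb is the ascending curve
    multiplied by ``down_factor`` (< 1 emulates hysteresis with ratio
    1/down_factor).  Gaussian noise of SD ``noise_sd`` Hz is added to
    suprathreshold frequencies, clipped at 0.
    """
    a, i0, b = truth
    if grid is None:
        grid = np.round(np.arange(0.0, 5.0 + 1e-9, 0.5), 10)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for limb, factor in (("up", 1.0), ("down", down_factor)):
        f = power_law(grid, a, i0, b) * factor
        noisy = np.where(
            f > 0, np.clip(f + rng.normal(0.0, noise_sd, size=f.size), 0.0, None), 0.0
        )
        for i_val, f_val in zip(grid, noisy):
            rows.append(dict(i=i_val, f=float(f_val), limb=limb))
    spec = GeneratorSpec(seed, noise_sd, {"a": a, "i0": i0, "b": b, "down_factor": down_factor})
    return pd.DataFrame(rows), spec


def gen_rebound_sweeps(
    truth: Tuple[float, float, float],
    latency_s: float = 0.2,
    n_sweeps: int = 5,
    seed: int = 0,
    horizon_s: float = 10.0,
) -> Tuple[SweepSet, GeneratorSpec]:
    """Release-aligned spike sweeps whose expected per-sweep cumulative
    count follows the logistic sigmoid.

    ``truth`` is (a, t_half s, k s) with ``a`` the expected number of
    spikes per sweep.  Spike times are drawn by inverse-transform
    sampling from the logistic density truncated to
    [latency, horizon]; per-sweep counts are Poisson with mean equal to
    the truncated mass, so no spike precedes the latency and the
    cumulative histogram matches the sigmoid up to the (small) truncated
    tails.  Times are returned in ms.
    """
    a, t_half, k = truth
    if a < 0:
        raise ValueError("truth plateau a must be >= 0")
    rng = np.random.default_rng(seed)
    s_lo = 1.0 / (1.0 + math.exp(-(latency_s - t_half) / k))
    s_hi = 1.0 / (1.0 + math.exp(-(horizon_s - t_half) / k))
    sweeps = []
    for sid in range(n_sweeps):
        n_spk = rng.poisson(a * (s_hi - s_lo)) if a > 0 else 0
        u = rng.uniform(s_lo, s_hi, size=n_spk)
        t = t_half + k * np.log(u / (1.0 - u))
        t = np.unique(t)
        sweeps.append(SpikeTrain(np.sort(t) * 1000.0, sweep_id=sid))
    spec = GeneratorSpec(
        seed, 0.0,
        {"a": a, "t_half": t_half, "k": k, "latency_s": latency_s, "horizon_s": horizon_s},
    )
    return SweepSet(sweeps), spec


def gen_vclamp_recordings(
    kind: str,
    truth: Optional[dict] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Synthetic voltage-clamp recordings with known feature structure.

    Kinds and their truth keys (all currents nA, times ms):

    * ``IK`` / ``IHTK`` — steps −50…+20 mV (500 ms): ``transient``,
      ``persistent``, ``tau_inact``, activation ``v_half``/``k_act``
      scale the per-step amplitudes; for ``IK`` transient==persistent
      unless given.
    * ``Ih`` — one 10 s step to −120 mV: ``amplitude``, ``tau``,
      ``leak_jump``.
    * ``Isyn`` — returns (presyn_mv, postsyn_na, spec): logistic with
      ``a``, ``v_half``, ``k``.
    * ``IMI_ramp`` — returns (ctrl_rec, proc_rec, spec): triangular ramp
      −80→20→−80 mV at 75 mV/s; Proc adds the modulator I–V curve
      (``a``, ``b``, ``v_half``, ``k``) to a linear control leak.
    """
    rng = np.random.default_rng(seed)
    truth = dict(truth or {})

    if kind in ("IK", "IHTK"):
        truth.setdefault("transient", 80.0 if kind == "IHTK" else 100.0)
        truth.setdefault("persistent", 40.0 if kind == "IHTK" else truth["transient"])
        truth.setdefault("tau_inact", 60.0)
        truth.setdefault("v_half", -10.0)
        truth.setdefault("k_act", 10.0)
        dt, dur = 1.0, 500.0
        steps = np.arange(-50.0, 20.0 + 1e-9, 10.0)
        t = np.arange(int(dur / dt)) * dt
        act20 = sigmoid(np.array([20.0]), 1.0, truth["v_half"], truth["k_act"])[0]
        cur, cmd = [], []
        for v in steps:
            act = sigmoid(np.array([v]), 1.0, truth["v_half"], truth["k_act"])[0] / act20
            tr = act * (
                truth["persistent"]
                + (truth["transient"] - truth["persistent"]) * np.exp(-t / truth["tau_inact"])
            )
            cur.append(tr + rng.normal(0.0, noise_sd, size=t.size))
            cmd.append(np.full_like(t, v))
        rec = VCRecording(dt, np.array(cmd), np.array(cur), steps, kind=kind)
        return rec, GeneratorSpec(seed, noise_sd, truth)

    if kind == "Ih":
        truth.setdefault("amplitude", 4.0)
        truth.setdefault("tau", 2000.0)
        truth.setdefault("leak_jump", -2.0)
        dt, dur = 10.0, 10_000.0
        t = np.arange(int(dur / dt)) * dt
        tr = truth["leak_jump"] - truth["amplitude"] * (1.0 - np.exp(-t / truth["tau"]))
        # make the settled→end relaxation amplitude exact despite finite tau
        tr = truth["leak_jump"] - truth["amplitude"] * (
            (1.0 - np.exp(-t / truth["tau"])) / (1.0 - np.exp(-t[-1] / truth["tau"]))
        )
        tr = tr + rng.normal(0.0, noise_sd, size=t.size)
        rec = VCRecording(
            dt, np.full((1, t.size), -120.0), tr[None, :], np.array([-120.0]), kind="Ih"
        )
        return rec, GeneratorSpec(seed, noise_sd, truth)

    if kind == "Isyn":
        truth.setdefault("a", -4.0)
        truth.setdefault("v_half", -35.0)
        truth.setdefault("k", 8.0)
        presyn = np.arange(-70.0, 0.0 + 1e-9, 10.0)
        post = sigmoid(presyn, truth["a"], truth["v_half"], truth["k"])
        post = post + rng.normal(0.0, noise_sd, size=post.size)
        return presyn, post, GeneratorSpec(seed, noise_sd, truth)

    if kind == "IMI_ramp":
        truth.setdefault("a", 0.05)
        truth.setdefault("b", 10.0)
        truth.setdefault("v_half", -20.0)
        truth.setdefault("k", 6.0)
        truth.setdefault("leak_g", 0.02)  # µS, linear control response
        truth.setdefault("leak_e", -60.0)
        dt = 1.0
        rate = 75.0 / 1000.0  # mV per ms
        n_half = int(round(100.0 / rate / dt))
        up = -80.0 + rate * dt * np.arange(n_half + 1)
        down = 20.0 - rate * dt * np.arange(1, n_half + 1)
        cmd = np.concatenate([up, down])
        ctrl = truth["leak_g"] * (cmd - truth["leak_e"])
        imi = imi_iv_curve(cmd, truth["a"], truth["b"], truth["v_half"], truth["k"])
        ctrl_tr = ctrl + rng.normal(0.0, noise_sd, size=cmd.size)
        proc_tr = ctrl + imi + rng.normal(0.0, noise_sd, size=cmd.size)
        ctrl_rec = VCRecording(
            dt, cmd[None, :], ctrl_tr[None, :], np.array([0.0]),
            condition="control", kind="IMI_ramp",
        )
        proc_rec = VCRecording(
            dt, cmd[None, :], proc_tr[None, :], np.array([0.0]),
            condition="Proc", kind="IMI_ramp",
        )
        return ctrl_rec, proc_rec, GeneratorSpec(seed, noise_sd, truth)

    raise ValueError(f"unknown voltage-clamp generator kind {kind!r}")


def gen_condition_table(
    means: Dict[str, Dict[str, float]],
    sds: Dict[str, Dict[str, float]],
    n_rows: int = 16,
    seed: int = 0,
) -> Tuple[pd.DataFrame, GeneratorSpec]:
    """Per-animal × condition parameter table with known cell means/SDs.

    ``means[param][cond]`` and ``sds[param][cond]`` give the generative
    normal law of each cell group; draws are independent across
    conditions (the comparisons are unpaired).  Returns a DataFrame with
    (parameter, condition) MultiIndex columns.
    """
    rng = np.random.default_rng(seed)
    cols, data = [], []
    for param, conds in means.items():
        for cond, mu in conds.items():
            sd = sds[param][cond]
            if sd < 0:
                raise ValueError("SDs must be >= 0")
            cols.append((param, cond))
            data.append(rng.normal(mu, sd, size=n_rows))
    df = pd.DataFrame(np.column_stack(data), columns=pd.MultiIndex.from_tuples(cols))
    return df, GeneratorSpec(seed, 0.0, {"means": means, "sds": sds, "n_rows": n_rows})
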