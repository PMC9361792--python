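"""Families of LP-like models and the modulation-variability sweeps.

A family is generated by seeded rejection sampling: candidate parameter
vectors are drawn from a uniform prior over maximal conductances,
simulated under the relevant protocol, summarized (rebound latency and
cumulative-histogram sigmoid parameters, or f–I power-law parameters),
and kept when they satisfy the selection criteria — rebound latency
inside (0.1, 1.5) s for rebound families; power-fit scale a >= 6 and no
depolarization block over the tested Δg_MI range for f–I families —
plus optional tolerance windows around target summary statistics.

The modulation experiments then add g_MI to every member, either a fixed
increment Δg_MI or a per-member increment drawn from a normal law with
fixed mean and chosen variance (truncated so total g_MI stays
non-negative), and measure how the spread of the output parameters
across the family changes with the increment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fitting import FitFailure, fit_fi_power, fit_sigmoid
from .lp_model import IntegrationError, LPParameters, simulate_lp
from .protocols import InjectionWaveform, Segment, make_fi_protocol
from .spike_analysis import (
    SpikeTrain,
    SweepSet,
    align_to_releases,
    cumulative_spike_histogram,
    detect_spikes,
    rebound_latency,
)
from .variability_stats import adjusted_cv, sample_sd

__all__ = [
    "REBOUND_PRIOR_NAMES",
    "FI_PRIOR_NAMES",
    "rebound_prior",
    "fi_prior",
    "FamilyMember",
    "FamilyBuildResult",
    "detect_depolarization_block",
    "rebound_summary",
    "fi_summary",
    "build_family",
    "apply_modulation",
    "modulation_variability_sweep",
]

SPIKE_THRESHOLD = -20.0  # mV, axonal detection threshold
REFRACTORY_MS = 2.0

#: parameters estimated for rebound families (somatic conductances +
#: calcium permeability)
REBOUND_PRIOR_NAMES = ("g_leak_s", "g_a", "g_h", "g_kca", "g_mi", "p_ca")
#: f–I families additionally vary the axonal conductances and the sodium
#: inactivation time-constant scale
FI_PRIOR_NAMES = REBOUND_PRIOR_NAMES + ("g_leak_a", "g_na", "g_k", "tau_h_na_scale")


def rebound_prior(
    ref: Optional[LPParameters] = None, lo: float = 0.25, hi: float = 4.0
) -> Dict[str, Tuple[float, float]]:
    """Uniform prior ranges [lo×, hi×] around a reference conductance set."""
    ref = ref or LPParameters()
    return {n: (lo * getattr(ref, n), hi * getattr(ref, n)) for n in REBOUND_PRIOR_NAMES}


def fi_prior(
    ref: Optional[LPParameters] = None,
    lo: float = 0.25,
    hi: float = 4.0,
    tau_scale_range: Tuple[float, float] = (0.5, 2.0),
) -> Dict[str, Tuple[float, float]]:
    ref = ref or LPParameters()
    prior = {n: (lo * getattr(ref, n), hi * getattr(ref, n)) for n in FI_PRIOR_NAMES[:-1]}
    prior["tau_h_na_scale"] = tau_scale_range
    return prior


@dataclass
class FamilyMember:
    params: LPParameters
    summary: Dict[str, float]
    increment: float = 0.0  # g_MI added on top of the sampled baseline


@dataclass
class FamilyBuildResult:
    members: List[FamilyMember]
    n_candidates: int
    rejections: Dict[str, int]
    seed: int

    @property
    def acceptance_rate(self) -> float:
        return len(self.members) / self.n_candidates if self.n_candidates else 0.0


def detect_depolarization_block(
    t: np.ndarray,
    v: np.ndarray,
    epoch: Tuple[float, float],
    threshold: float = SPIKE_THRESHOLD,
) -> bool:
    """True when the final half of the epoch sits above the spike
    threshold on average yet contains no spikes (silence by sustained
    depolarization, not by hyperpolarization)."""
    t0, t1 = epoch
    half = ((t0 + t1) / 2.0, t1)
    sel = (t >= half[0]) & (t < half[1])
    if not np.any(sel):
        raise ValueError("epoch outside trace")
    train = detect_spikes(t[sel], v[sel], threshold, REFRACTORY_MS)
    return bool(len(train) == 0 and v[sel].mean() > threshold)


def _rebound_protocol(n_cycles: int) -> InjectionWaveform:
    segs = []
    for i in range(n_cycles):
        segs.append(Segment(10_000.0, -5.0, f"pulse{i}:on"))
        segs.append(Segment(10_000.0, 0.0, f"pulse{i}:off"))
    return InjectionWaveform(segs, name="rebound_dc")


def rebound_summary(
    params: LPParameters,
    dt: float = 0.05,
    n_cycles: int = 2,
    bin_ms: float = 200.0,
    horizon_ms: float = 10_000.0,
    record_stride: int = 4,
) -> Dict[str, float]:
    """Latency and cumulative-histogram sigmoid parameters of the model's
    rebound response.

    The deterministic model needs no repeated sweeps; the first cycle
    conditions the slow states and the last cycle is analyzed.  Returns
    latency_s (NaN when the model does not rebound), the per-sweep
    sigmoid parameters a, t_half_s, k_s (NaN when unfittable) and the
    rebound spike count.
    """
    proto = _rebound_protocol(n_cycles)
    res = simulate_lp(params, proto, dt=dt, record_stride=record_stride)
    train = detect_spikes(res.t, res.v_axon, SPIKE_THRESHOLD, REFRACTORY_MS)
    release = proto.release_times()[-1]
    sweeps = align_to_releases(train, [release], horizon_ms)
    lat = rebound_latency(train, release, horizon_ms)
    out = {
        "latency_s": float("nan") if lat is None else lat,
        "a": float("nan"),
        "t_half_s": float("nan"),
        "k_s": float("nan"),
        "n_spikes": float(len(sweeps.sweeps[0])),
    }
    edges, counts, cum = cumulative_spike_histogram(sweeps, bin_ms, horizon_ms)
    if counts.sum() >= 4:
        x_s = edges[1:] / 1000.0  # right bin edges, seconds after release
        per_sweep = cum / len(sweeps)
        try:
            fit = fit_sigmoid(list(zip(x_s, per_sweep)), mode="cumulative_time")
            out.update(a=fit.a, t_half_s=fit.x_half, k_s=fit.k)
        except FitFailure:
            pass
    return out


def fi_summary(
    params: LPParameters,
    dt: float = 0.05,
    step_s: float = 5.0,
    record_stride: int = 4,
) -> Dict[str, float]:
    """f–I power-law parameters of the model under the current-step
    program (−10 → 5.5 nA, 0.5 nA increments).

    Mean instantaneous frequency is computed per step from all interspike
    intervals inside the step; the (I, f) points are fitted with
    f = a·(I−I0)^b.  Also reports whether any step showed depolarization
    block.  Fit parameters are NaN when the model never reaches three
    spiking steps or the fit fails.
    """
    proto = make_fi_protocol("model", step_s=step_s)
    res = simulate_lp(params, proto, dt=dt, record_stride=record_stride)
    train = detect_spikes(res.t, res.v_axon, SPIKE_THRESHOLD, REFRACTORY_MS)
    pts = []
    blocked = False
    for label, t0, t1, amp in proto.epochs():
        inside = train.times[(train.times >= t0) & (train.times < t1)]
        if inside.size >= 2:
            f = float(np.mean(1000.0 / np.diff(inside)))
        else:
            f = 0.0
            sel = (res.t >= (t0 + t1) / 2.0) & (res.t < t1)
            if np.any(sel) and res.v_axon[sel].mean() > SPIKE_THRESHOLD:
                blocked = True
        pts.append((amp, f))
    out = {
        "a": float("nan"), "b": float("nan"), "i0": float("nan"),
        "blocked": float(blocked),
    }
    try:
        fit = fit_fi_power(pts)
        out.update(a=fit.a, b=fit.b, i0=fit.i0)
    except FitFailure:
        pass
    return out


def _passes_windows(
    summary: Dict[str, float],
    windows: Optional[Dict[str, Tuple[float, float]]],
) -> bool:
    if not windows:
        return True
    for key, (target, tol) in windows.items():
        val = summary.get(key, float("nan"))
        if not np.isfinite(val) or abs(val - target) > tol:
            return False
    return True


def build_family(
    prior: Dict[str, Tuple[float, float]],
    kind: str = "rebound",
    n_target: int = 30,
    budget: int = 300,
    seed: int = 0,
    ref: Optional[LPParameters] = None,
    windows: Optional[Dict[str, Tuple[float, float]]] = None,
    latency_window: Tuple[float, float] = (0.1, 1.5),
    min_fit_a: float = 6.0,
    block_check_delta: float = 0.1,
    dt: float = 0.05,
) -> FamilyBuildResult:
    """Seeded rejection sampling of a model family.

    Draws parameter vectors uniformly from ``prior`` (other parameters
    from ``ref``), simulates the protocol for ``kind`` and applies the
    selection criteria; ``windows`` optionally adds
    {summary key: (target, tolerance)} constraints.  For f–I families,
    candidates are re-simulated with ``block_check_delta`` of extra g_MI
    and rejected if they enter depolarization block there.  Stops at
    ``n_target`` members or after ``budget`` candidates, whichever comes
    first; determinstic for fixed (prior, seed, config).
    """
    if budget < n_target:
        raise ValueError("budget must be >= n_target")
    if kind not in ("rebound", "fi"):
        raise ValueError(f"unknown family kind {kind!r}")
    ref = ref or LPParameters()
    rng = np.random.default_rng(seed)
    names = list(prior)
    members: List[FamilyMember] = []
    rejections: Dict[str, int] = {
        "integration_failure": 0, "criterion": 0, "window": 0, "block": 0,
    }
    n_cand = 0
    for _ in range(budget):
        if len(members) >= n_target:
            break
        n_cand += 1
        draw = {n: float(rng.uniform(*prior[n])) for n in names}
        params = ref.with_(**draw)
        try:
            if kind == "rebound":
                summary = rebound_summary(params, dt=dt)
                lat = summary["latency_s"]
                ok = np.isfinite(lat) and latency_window[0] < lat < latency_window[1]
                ok = ok and np.isfinite(summary["a"])
            else:
                summary = fi_summary(params, dt=dt)
                ok = np.isfinite(summary["a"]) and summary["a"] >= min_fit_a
                ok = ok and not summary["blocked"]
        except IntegrationError:
            rejections["integration_failure"] += 1
            continue
        if not ok:
            rejections["criterion"] += 1
            continue
        if not _passes_windows(summary, windows):
            rejections["window"] += 1
            continue
        if kind == "fi" and block_check_delta > 0:
            try:
                high = fi_summary(
                    params.with_(g_mi=params.g_mi + block_check_delta), dt=dt
                )
            except IntegrationError:
                rejections["integration_failure"] += 1
                continue
            if high["blocked"]:
                rejections["block"] += 1
                continue
        members.append(FamilyMember(params=params, summary=summary))
    return FamilyBuildResult(members, n_cand, rejections, seed)


def apply_modulation(
    family: Sequence[FamilyMember],
    mode: str = "fixed",
    delta: float = 0.0,
    sigma2: float = 0.0,
    seed: int = 0,
) -> List[FamilyMember]:
    """Add modulator conductance to every member.

    ``fixed``: g_MI += delta for all members.  ``distributed``: each
    member gets an increment drawn from Normal(delta, sqrt(sigma2)),
    truncated so total g_MI stays non-negative.  Increments are recorded
    on the returned members; the input family is left untouched.
    """
    if delta < 0 or sigma2 < 0:
        raise ValueError("delta and sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for mem in family:
        if mode == "fixed":
            inc = delta
        elif mode == "distributed":
            inc = float(rng.normal(delta, np.sqrt(sigma2)))
            inc = max(inc, -mem.params.g_mi)
        else:
            raise ValueError(f"unknown modulation mode {mode!r}")
        out.append(
            FamilyMember(
                params=mem.params.with_(g_mi=mem.params.g_mi + inc),
                summary=dict(mem.summary),
                increment=inc,
            )
        )
    return out


#: variability metric used per summary parameter, mirroring the
#: experimental analysis (CV for ratio-scale, SD also reported).
_REBOUND_PARAMS = ("latency_s", "a", "t_half_s", "k_s")
_FI_PARAMS = ("a", "b", "i0")


def modulation_variability_sweep(
    family: Sequence[FamilyMember],
    kind: str = "rebound",
    levels: Sequence[float] = (0.0, 0.01, 0.025, 0.05, 0.1),
    mode: str = "fixed",
    mean_delta: float = 0.025,
    seed: int = 0,
    dt: float = 0.05,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Re-simulate the family at each modulation level and summarize the
    across-member spread of the output parameters.

    In ``fixed`` mode ``levels`` are Δg_MI increments added identically
    to every member.  In ``distributed`` mode ``levels`` are the
    variances σ² of the per-member increment law, whose mean is the
    fixed ``mean_delta``.

    Returns (per_member, per_level): ``per_member`` has one row per
    (member, level) with the summary parameters; ``per_level`` has the
    across-family mean, SD and adjusted CV per parameter and level, with
    exclusion counts (members missing a rebound / in depolarization
    block at that level).
    """
    if not family:
        raise ValueError("family is empty")
    params_list = _REBOUND_PARAMS if kind == "rebound" else _FI_PARAMS
    rows = []
    for li, level in enumerate(levels):
        if mode == "fixed":
            delta, sigma2 = level, 0.0
        else:
            delta, sigma2 = mean_delta, level
        modulated = apply_modulation(
            family, mode=mode, delta=delta, sigma2=sigma2,
            seed=seed + 1000 * li,
        )
        for mi, mem in enumerate(modulated):
            row = dict(member=mi, level=level, increment=mem.increment)
            try:
                if kind == "rebound":
                    s = rebound_summary(mem.params, dt=dt)
                    row.update({k: s[k] for k in _REBOUND_PARAMS})
                    row["excluded"] = not np.isfinite(s["latency_s"])
                else:
                    s = fi_summary(mem.params, dt=dt)
                    row.update({k: s[k] for k in _FI_PARAMS})
                    row["excluded"] = bool(s["blocked"]) or not np.isfinite(s["a"])
            except IntegrationError:
                row.update({k: float("nan") for k in params_list})
                row["excluded"] = True
            rows.append(row)
    per_member = pd.DataFrame(rows)

    agg_rows = []
    for level, grp in per_member.groupby("level", sort=True):
        ok = grp[~grp["excluded"]]
        entry = dict(
            level=level, n=int(len(ok)), n_excluded=int(grp["excluded"].sum())
        )
        for p in params_list:
            vals = ok[p].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            entry[f"{p}_mean"] = float(vals.mean()) if vals.size else float("nan")
            entry[f"{p}_sd"] = sample_sd(vals)
            entry[f"{p}_cv"] = adjusted_cv(vals)
        agg_rows.append(entry)
    per_level = pd.DataFrame(agg_rows)
    if (per_level["n_excluded"] > per_level["n"]).any():
        import warnings

        warnings.warn("more than half the family excluded at some level")
    return per_member, per_level
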