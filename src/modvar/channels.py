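"""Hodgkin–Huxley channel primitives in a consistent unit system.

Units throughout: mV, ms, nA, µS, nF, mM (so τ = C/g is in ms and
I = g·(V−E) is in nA).  These are the generic, readable building blocks;
the production integrator in :mod:`modvar.lp_model` inlines the same
arithmetic for speed and is held to these functions by tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .gates import GATES, REVERSALS, logistic

__all__ = [
    "ChannelSpec",
    "CalciumChannelSpec",
    "CalciumDynamicsSpec",
    "eval_gating",
    "hh_current",
    "gate_step",
    "ghk_calcium_current",
    "calcium_step",
    "build_channel_specs",
    "ZETA_SCALE_MV",
]

# R*T/(z_Ca*F) at T = 283.15 K for a divalent ion, in mV.
_R = 8.31446  # J/(mol K)
_F = 96485.33  # C/mol
_TEMP_K = 283.15
ZETA_SCALE_MV = 1000.0 * _R * _TEMP_K / (2.0 * _F)  # ≈ 12.20 mV

GateFunc = Callable[[float, float], float]  # (v mV, ca mM) -> value


@dataclass
class ChannelSpec:
    """One ionic current: exponents, conductance, reversal, gating functions.

    ``m_inf``/``h_inf`` must return values in [0, 1] and ``tau_m``/``tau_h``
    strictly positive times (ms) for all physiological inputs.
    """

    name: str
    p: int
    q: int
    gbar: float  # µS
    E: float  # mV
    m_inf: Optional[GateFunc] = None
    tau_m: Optional[GateFunc] = None
    h_inf: Optional[GateFunc] = None
    tau_h: Optional[GateFunc] = None

    def __post_init__(self) -> None:
        if self.gbar < 0:
            raise ValueError(f"{self.name}: gbar must be >= 0, got {self.gbar}")
        if self.p < 0 or self.q < 0:
            raise ValueError(f"{self.name}: gate exponents must be non-negative")


@dataclass
class CalciumChannelSpec:
    """GHK calcium current parameters.

    ``P`` plays the role of a maximal permeability scaled so the current
    comes out in nA; the physical prefactors of the flux equation are
    absorbed into it.
    """

    P: float  # scaled permeability (nA/mM at unit zeta)
    ca_out: float = 13.0  # mM
    p: int = 3
    q: int = 1
    zeta_scale: float = ZETA_SCALE_MV  # mV per unit zeta
    m_inf: Optional[GateFunc] = None
    tau_m: Optional[GateFunc] = None
    h_inf: Optional[GateFunc] = None
    tau_h: Optional[GateFunc] = None

    def __post_init__(self) -> None:
        if self.P < 0:
            raise ValueError("calcium permeability must be >= 0")
        if self.ca_out <= 0:
            raise ValueError("external calcium must be > 0")


@dataclass
class CalciumDynamicsSpec:
    """First-order intracellular calcium relaxation plus flux from I_Ca.

    d[Ca]/dt = ([Ca]_inf − [Ca])/τ_Ca − flux·I_Ca, with flux in
    mM·ms⁻¹·nA⁻¹ lumping the per-cluster permeability, valence, Faraday
    constant and microdomain volume.
    """

    ca_inf: float = 0.02  # mM
    tau_ca: float = 25.0  # ms
    flux: float = 0.015  # mM/(ms·nA)

    def __post_init__(self) -> None:
        if self.ca_inf <= 0 or self.tau_ca <= 0:
            raise ValueError("ca_inf and tau_ca must be > 0")


def eval_gating(spec, v: float, ca: float = 0.02):
    """Evaluate (m_inf, tau_m, h_inf, tau_h) of a channel at (v, ca).

    Gates the channel does not have are reported as (1.0, inf).
    """
    if not math.isfinite(v):
        raise ValueError("v must be finite")
    if ca <= 0 or not math.isfinite(ca):
        raise ValueError("ca must be finite and > 0")
    m_inf = spec.m_inf(v, ca) if spec.m_inf is not None else 1.0
    tau_m = spec.tau_m(v, ca) if spec.tau_m is not None else math.inf
    h_inf = spec.h_inf(v, ca) if spec.h_inf is not None else 1.0
    tau_h = spec.tau_h(v, ca) if spec.tau_h is not None else math.inf
    return m_inf, tau_m, h_inf, tau_h


def hh_current(spec: ChannelSpec, m: float, h: float, v: float) -> float:
    """Ohmic HH current g̅·m^p·h^q·(v − E) in nA."""
    if not (0.0 <= m <= 1.0) or not (0.0 <= h <= 1.0):
        raise ValueError("gating variables must lie in [0, 1]")
    return spec.gbar * m**spec.p * h**spec.q * (v - spec.E)


def gate_step(z: float, z_inf: float, tau: float, dt: float) -> float:
    """Advance dz/dt = (z_inf − z)/τ by one exponential-Euler step.

    Exact for constant z_inf, unconditionally stable, preserves [0, 1].
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return z_inf + (z - z_inf) * math.exp(-dt / tau)


def _ghk_driving(v: float, ca_in: float, ca_out: float, zeta_scale: float) -> float:
    """GHK driving term ζ·(ca_out·e^(−ζ) − ca_in)/(e^(−ζ) − 1), mM·(ζ units).

    The v = 0 singularity is removable; near zero the series
    −(ca_out − ca_in) + ζ·(ca_out + ca_in)/2 is used.
    """
    zeta = v / zeta_scale
    if abs(zeta) < 1e-4:
        return -(ca_out - ca_in) + zeta * (ca_out + ca_in) / 2.0
    em = math.exp(-zeta)
    return zeta * (ca_out * em - ca_in) / (em - 1.0)


def ghk_calcium_current(
    spec: CalciumChannelSpec, m: float, h: float, v: float, ca_in: float
) -> float:
    """Calcium current via the GHK flux form, in nA (negative = inward)."""
    if ca_in <= 0:
        raise ValueError("ca_in must be > 0")
    if not (0.0 <= m <= 1.0) or not (0.0 <= h <= 1.0):
        raise ValueError("gating variables must lie in [0, 1]")
    drive = _ghk_driving(v, ca_in, spec.ca_out, spec.zeta_scale)
    return spec.P * m**spec.p * h**spec.q * drive


def calcium_step(
    ca_in: float, i_ca: float, spec: CalciumDynamicsSpec, dt: float
) -> float:
    """Advance intracellular calcium one exponential-Euler step.

    The ODE is linear in [Ca] given I_Ca, so the step relaxes toward the
    instantaneous steady state ca_inf − τ·flux·I_Ca.
    """
    if ca_in <= 0:
        raise ValueError("ca_in must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    target = spec.ca_inf - spec.tau_ca * spec.flux * i_ca
    new = target + (ca_in - target) * math.exp(-dt / spec.tau_ca)
    if new <= 0:
        raise ArithmeticError(
            "calcium went non-positive; reduce dt or the flux factor"
        )
    return new


def _sig_gate(vhalf: float, k: float) -> GateFunc:
    return lambda v, ca, vh=vhalf, kk=k: logistic((v - vh) / kk)


def _sig_tau(base: float, amp: float, vhalf: float, k: float) -> GateFunc:
    return lambda v, ca, b=base, a=amp, vh=vhalf, kk=k: b + a * logistic((v - vh) / kk)


def _const(x: float) -> GateFunc:
    return lambda v, ca, c=x: c


def build_channel_specs(gbars: Optional[dict] = None) -> dict:
    """Construct ChannelSpec objects for every LP-like channel from the
    transcription table in :mod:`modvar.gates`.

    ``gbars`` optionally maps channel names to maximal conductances (µS);
    unspecified channels get gbar 0 (the gating functions are what matter
    for most uses of this constructor).
    """
    gb = gbars or {}
    g = GATES
    specs: dict = {}

    specs["A"] = ChannelSpec(
        "A", g["A"]["p"], g["A"]["q"], gb.get("A", 0.0), REVERSALS["A"],
        m_inf=_sig_gate(*g["A"]["m_vk"]), tau_m=_const(g["A"]["tau_m"]),
        h_inf=_sig_gate(*g["A"]["h_vk"]), tau_h=_const(g["A"]["tau_h"]),
    )
    specs["h"] = ChannelSpec(
        "h", g["h"]["p"], g["h"]["q"], gb.get("h", 0.0), REVERSALS["h"],
        m_inf=_sig_gate(*g["h"]["m_vk"]), tau_m=_sig_tau(*g["h"]["tau_m"]),
    )
    specs["MI"] = ChannelSpec(
        "MI", g["MI"]["p"], g["MI"]["q"], gb.get("MI", 0.0), REVERSALS["MI"],
        m_inf=_sig_gate(*g["MI"]["m_vk"]), tau_m=_const(g["MI"]["tau_m"]),
    )

    kca = g["KCa"]
    ca_half, hill_n = kca["ca_half"], kca["hill_n"]
    vm, km = kca["m_vk"]
    tm_a, tm_b, tm_shift, tm_k = kca["tau_m_coeffs"]

    def kca_minf(v, ca):
        hill = 1.0 / (1.0 + (ca_half / ca) ** hill_n)
        return hill * logistic((v - vm) / km)

    def kca_taum(v, ca):
        return tm_a - tm_b * logistic(
            (v + tm_shift * math.log10(ca / 1e-3)) / tm_k
        )

    kca_scale = kca["h_ca_scale"]
    specs["KCa"] = ChannelSpec(
        "KCa", kca["p"], kca["q"], gb.get("KCa", 0.0), REVERSALS["KCa"],
        m_inf=kca_minf, tau_m=kca_taum,
        h_inf=lambda v, ca, s=kca_scale: logistic(-ca / s),
        tau_h=_const(kca["tau_h"]),
    )

    cat = g["Ca"]
    ca_scale = cat["h_ca_scale"]
    specs["Ca"] = CalciumChannelSpec(
        P=gb.get("Ca", 0.0), p=cat["p"], q=cat["q"],
        m_inf=_sig_gate(*cat["m_vk"]), tau_m=_sig_tau(*cat["tau_m"]),
        h_inf=lambda v, ca, s=ca_scale: logistic(-ca / s),
        tau_h=_sig_tau(*cat["tau_h"]),
    )

    specs["Na"] = ChannelSpec(
        "Na", g["Na"]["p"], g["Na"]["q"], gb.get("Na", 0.0), REVERSALS["Na"],
        m_inf=_sig_gate(*g["Na"]["m_vk"]), tau_m=_const(g["Na"]["tau_m"]),
        h_inf=_sig_gate(*g["Na"]["h_vk"]), tau_h=_const(g["Na"]["tau_h"]),
    )
    specs["K"] = ChannelSpec(
        "K", g["K"]["p"], g["K"]["q"], gb.get("K", 0.0), REVERSALS["K"],
        m_inf=_sig_gate(*g["K"]["m_vk"]), tau_m=_sig_tau(*g["K"]["tau_m"]),
    )
    specs["soma_leak"] = ChannelSpec(
        "soma_leak", 0, 0, gb.get("soma_leak", 0.0), REVERSALS["soma_leak"]
    )
    specs["axon_leak"] = ChannelSpec(
        "axon_leak", 0, 0, gb.get("axon_leak", 0.0), REVERSALS["axon_leak"]
    )
    return specs
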