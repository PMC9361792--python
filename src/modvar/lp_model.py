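"""Two-compartment conductance-based LP-like neuron.

The soma/neurite compartment carries leak, A-type potassium, GHK calcium,
calcium-activated potassium, hyperpolarization-activated (h) and
modulator-activated (MI) currents plus first-order intracellular calcium
dynamics; the axon compartment carries leak, fast sodium and delayed
rectifier currents and generates the spikes, which appear at the soma as
small spikelets through the axial coupling conductance.

Integration is exponential Euler for gating variables and calcium (both
linear given the instantaneous voltage) and semi-implicit Euler for the
two voltages, at a default step of 0.05 ms.  The compiled kernel lives
behind :func:`simulate_lp`; its arithmetic is pinned to the readable
primitives in :mod:`modvar.channels` by tests.

Units: mV, ms, nA, µS, nF, mM.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np
from numba import njit

from .channels import ZETA_SCALE_MV
from .gates import pack_gate_vector
from .protocols import InjectionWaveform

__all__ = ["LPParameters", "SimulationResult", "IntegrationError", "simulate_lp"]


class IntegrationError(RuntimeError):
    """Numerical blow-up during integration; carries the failure time."""

    def __init__(self, t_ms: float):
        super().__init__(f"voltage left [-200, 200] mV at t = {t_ms:.3f} ms")
        self.t_ms = t_ms


@dataclass(frozen=True)
class LPParameters:
    """Maximal conductances, geometry and calcium handling of one model.

    The somatic calcium permeability ``p_ca`` is a scaled permeability
    (current in nA per unit GHK driving term).  ``tau_h_na_scale``
    multiplies the axonal sodium inactivation time constant; it is one of
    the parameters varied when building f–I model families.

    Capacitances and the axial conductance are not constrained by the
    published description; the defaults here were hand-tuned so that
    axonal spikes appear at the soma as spikelets of a few mV and the
    rebound latency of the reference set falls inside the selection
    window (see docs/methods.md).
    """

    # geometry / coupling
    c_soma: float = 1.0  # nF
    c_axon: float = 0.5  # nF
    g_axial: float = 0.3  # µS
    # somatic maximal conductances (µS) and calcium permeability
    g_leak_s: float = 0.1
    g_a: float = 2.0
    p_ca: float = 0.15
    g_kca: float = 3.0
    g_h: float = 0.45
    g_mi: float = 0.02
    # axonal maximal conductances (µS)
    g_leak_a: float = 0.05
    g_na: float = 6.0
    g_k: float = 4.0
    # calcium dynamics
    ca_inf: float = 0.02  # mM
    tau_ca: float = 25.0  # ms
    ca_flux: float = 0.015  # mM/(ms·nA)
    ca_out: float = 13.0  # mM
    # kinetic scale factors
    tau_h_na_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "c_soma", "c_axon", "g_axial", "g_leak_s", "g_a", "p_ca",
            "g_kca", "g_h", "g_mi", "g_leak_a", "g_na", "g_k",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.c_soma <= 0 or self.c_axon <= 0:
            raise ValueError("capacitances must be > 0")
        if self.ca_inf <= 0 or self.tau_ca <= 0 or self.ca_out <= 0:
            raise ValueError("calcium parameters must be > 0")

    def with_(self, **kw) -> "LPParameters":
        return replace(self, **kw)

    # -- kernel packing / serialization --------------------------------
    def to_vector(self) -> np.ndarray:
        from .gates import REVERSALS as R

        return np.array(
            [
                self.c_soma, self.c_axon, self.g_axial,
                self.g_leak_s, R["soma_leak"],
                self.g_a, R["A"],
                self.p_ca,
                self.g_kca, R["KCa"],
                self.g_h, R["h"],
                self.g_mi, R["MI"],
                self.g_leak_a, R["axon_leak"],
                self.g_na, R["Na"],
                self.g_k, R["K"],
                self.ca_inf, self.tau_ca, self.ca_flux, self.ca_out,
                ZETA_SCALE_MV,
                self.tau_h_na_scale,
            ],
            dtype=np.float64,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "LPParameters":
        return cls(**json.loads(s))


@dataclass
class SimulationResult:
    """Recorded traces on a uniform grid (time step = dt·stride, ms)."""

    t: np.ndarray  # ms
    v_soma: np.ndarray  # mV
    v_axon: np.ndarray  # mV
    ca: np.ndarray  # mM
    i_inj: np.ndarray  # nA
    dt: float  # recorded grid step, ms

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_ms": self.t,
                "v_soma_mv": self.v_soma,
                "v_axon_mv": self.v_axon,
                "ca_mm": self.ca,
                "i_inj_na": self.i_inj,
            }
        )


_GP = np.array(pack_gate_vector(), dtype=np.float64)


@njit(cache=True)
def _sig(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


@njit(cache=True)
def _ghk(v, ca_in, ca_out, zeta_scale):
    zeta = v / zeta_scale
    if abs(zeta) < 1e-4:
        return -(ca_out - ca_in) + zeta * (ca_out + ca_in) / 2.0
    em = math.exp(-zeta)
    return zeta * (ca_out * em - ca_in) / (em - 1.0)


@njit(cache=True)
def _integrate(pv, gp, i_inj, dt, v0, stride, vs_out, va_out, ca_out_tr):
    """Advance the full model over len(i_inj) steps; returns (-1.0 on
    success, else the failure time in ms)."""
    c_s, c_a, g_ax = pv[0], pv[1], pv[2]
    gl_s, el_s = pv[3], pv[4]
    g_a_, e_a = pv[5], pv[6]
    p_ca_ = pv[7]
    g_kca, e_kca = pv[8], pv[9]
    g_h_, e_h = pv[10], pv[11]
    g_mi_, e_mi = pv[12], pv[13]
    gl_a, el_a = pv[14], pv[15]
    g_na, e_na = pv[16], pv[17]
    g_k_, e_k = pv[18], pv[19]
    ca_inf, tau_ca, flux, ca_o, zscale = pv[20], pv[21], pv[22], pv[23], pv[24]
    tauh_na_scale = pv[25]

    vs = v0
    va = v0
    ca = ca_inf

    # initialize gates at steady state for (v0, ca)
    mA = _sig((vs - gp[0]) / gp[1])
    hA = _sig((vs - gp[3]) / gp[4])
    mCa = _sig((vs - gp[6]) / gp[7])
    hCa = _sig(-ca / gp[12])
    mh = _sig((vs - gp[17]) / gp[18])
    mMI = _sig((vs - gp[33]) / gp[34])
    hill = 1.0 / (1.0 + (gp[23] / ca) ** gp[24])
    mKCa = hill * _sig((vs - gp[25]) / gp[26])
    hKCa = _sig(-ca / gp[31])
    mNa = _sig((va - gp[36]) / gp[37])
    hNa = _sig((va - gp[39]) / gp[40])
    mK = _sig((va - gp[42]) / gp[43])

    n = i_inj.shape[0]
    for i in range(n):
        if i % stride == 0:
            k = i // stride
            vs_out[k] = vs
            va_out[k] = va
            ca_out_tr[k] = ca

        # --- gate updates (exponential Euler) at current voltages -----
        mA += (_sig((vs - gp[0]) / gp[1]) - mA) * (1.0 - math.exp(-dt / gp[2]))
        hA += (_sig((vs - gp[3]) / gp[4]) - hA) * (1.0 - math.exp(-dt / gp[5]))

        tau_mca = gp[8] + gp[9] * _sig((vs - gp[10]) / gp[11])
        mCa += (_sig((vs - gp[6]) / gp[7]) - mCa) * (1.0 - math.exp(-dt / tau_mca))
        tau_hca = gp[13] + gp[14] * _sig((vs - gp[15]) / gp[16])
        hCa += (_sig(-ca / gp[12]) - hCa) * (1.0 - math.exp(-dt / tau_hca))

        tau_mh = gp[19] + gp[20] * _sig((vs - gp[21]) / gp[22])
        mh += (_sig((vs - gp[17]) / gp[18]) - mh) * (1.0 - math.exp(-dt / tau_mh))

        mMI += (_sig((vs - gp[33]) / gp[34]) - mMI) * (1.0 - math.exp(-dt / gp[35]))

        hill = 1.0 / (1.0 + (gp[23] / ca) ** gp[24])
        minf_kca = hill * _sig((vs - gp[25]) / gp[26])
        tau_mkca = gp[27] - gp[28] * _sig(
            (vs + gp[29] * math.log10(ca / 1e-3)) / gp[30]
        )
        mKCa += (minf_kca - mKCa) * (1.0 - math.exp(-dt / tau_mkca))
        hKCa += (_sig(-ca / gp[31]) - hKCa) * (1.0 - math.exp(-dt / gp[32]))

        mNa += (_sig((va - gp[36]) / gp[37]) - mNa) * (1.0 - math.exp(-dt / gp[38]))
        hNa += (_sig((va - gp[39]) / gp[40]) - hNa) * (
            1.0 - math.exp(-dt / (gp[41] * tauh_na_scale))
        )
        tau_mk = gp[44] + gp[45] * _sig((va - gp[46]) / gp[47])
        mK += (_sig((va - gp[42]) / gp[43]) - mK) * (1.0 - math.exp(-dt / tau_mk))

        # --- calcium current and concentration ------------------------
        i_ca = p_ca_ * mCa * mCa * mCa * hCa * _ghk(vs, ca, ca_o, zscale)
        target = ca_inf - tau_ca * flux * i_ca
        ca = target + (ca - target) * math.exp(-dt / tau_ca)
        if ca < 1e-9:
            ca = 1e-9

        # --- voltages (semi-implicit Euler) ---------------------------
        g_lin_s = (
            gl_s
            + g_a_ * mA * mA * hA
            + g_kca * mKCa * hKCa
            + g_h_ * mh
            + g_mi_ * mMI
        )
        num_s = (
            gl_s * el_s
            + g_a_ * mA * mA * hA * e_a
            + g_kca * mKCa * hKCa * e_kca
            + g_h_ * mh * e_h
            + g_mi_ * mMI * e_mi
        )
        g_lin_a = gl_a + g_na * mNa * mNa * mNa * hNa + g_k_ * mK * mK * mK * mK
        num_a = (
            gl_a * el_a
            + g_na * mNa * mNa * mNa * hNa * e_na
            + g_k_ * mK * mK * mK * mK * e_k
        )

        vs_new = (vs + dt / c_s * (num_s + g_ax * va + i_inj[i] - i_ca)) / (
            1.0 + dt / c_s * (g_lin_s + g_ax)
        )
        va_new = (va + dt / c_a * (num_a + g_ax * vs)) / (
            1.0 + dt / c_a * (g_lin_a + g_ax)
        )
        vs, va = vs_new, va_new

        if abs(vs) > 200.0 or abs(va) > 200.0 or vs != vs or va != va:
            return (i + 1) * dt
    return -1.0


def simulate_lp(
    params: LPParameters,
    protocol: InjectionWaveform,
    dt: float = 0.05,
    v0: float = -55.0,
    record_stride: int = 1,
) -> SimulationResult:
    """Integrate the two-compartment model under a current program.

    ``dt`` must lie in (0, 0.1] ms; ``record_stride`` subsamples the
    stored traces (the integration always runs at ``dt``).  Deterministic
    for fixed inputs.  Raises :class:`IntegrationError` on blow-up.
    """
    if not (0.0 < dt <= 0.1):
        raise ValueError("dt must lie in (0, 0.1] ms")
    if record_stride < 1:
        raise ValueError("record_stride must be >= 1")
    i_inj = protocol.to_samples(dt)
    if i_inj.size == 0:
        raise ValueError("protocol has zero duration")
    n_rec = (i_inj.shape[0] + record_stride - 1) // record_stride
    vs = np.empty(n_rec)
    va = np.empty(n_rec)
    ca = np.empty(n_rec)
    fail_t = _integrate(
        params.to_vector(), _GP, i_inj, dt, v0, record_stride, vs, va, ca
    )
    if fail_t >= 0.0:
        raise IntegrationError(fail_t)
    t = np.arange(n_rec) * (dt * record_stride)
    return SimulationResult(
        t=t, v_soma=vs, v_axon=va, ca=ca,
        i_inj=i_inj[::record_stride].copy(), dt=dt * record_stride,
    )
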