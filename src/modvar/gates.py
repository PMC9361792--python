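"""Gating parameterization of the LP-like model — the single source of truth.

Every voltage- and calcium-dependent gate of the two-compartment LP-like
neuron is defined here as numbers (midpoints, slopes, time-constant
coefficients), consumed both by the fast integration kernel
(:mod:`modvar.lp_model`) and by the generic :class:`modvar.channels.ChannelSpec`
objects that tests and exploratory code use.

Conventions
-----------
``S(x) = 1/(1 + exp(-x))`` is the logistic sigmoid.  Voltage sigmoids are
written ``S((v - vhalf)/k)`` with a *signed* slope ``k`` (mV): ``k > 0`` means
the gate opens with depolarization.  Time constants are in ms, voltages in mV,
calcium in mM.

Transcription notes
-------------------
The published gating table is typeset with stacked fractions that do not
survive plain-text extraction, and the original simulation source was not
reachable from this environment, so the numbers below are a documented
best-effort transcription.  Ambiguities and the choices made:

* ``I_h`` activation must increase with *hyper*polarization for the sag and
  rebound to exist; the slope sign is therefore negative although the flat
  rendering shows none.
* ``I_A`` inactivation slope is read as 7.5 mV (a 75 mV slope would make the
  gate voltage-independent over the physiological range).
* Calcium-dependent gate scales as printed are dimensionally inconsistent
  with [Ca] in mM (e.g. an inactivation scale of 5e-4 mM would pin the gate
  at zero); the scales below (0.5 mM for I_Ca inactivation, 0.03 mM for
  I_KCa inactivation, 1.43e-3 mM half-saturation for the KCa Hill term) keep
  each gate dynamically meaningful.  A stray factor "1.25" attached to the
  KCa inactivation cell could not be resolved and is dropped.
* The KCa activation time constant uses a base-10 logarithm of [Ca]/1e-3.
* The Na activation cell flattens to "1812.25" and admits several readings;
  midpoint −22 mV with slope 8 mV is the choice, within the plausible
  readings, at which the axon supports sustained tonic spiking over the whole
  conductance range the model families sample (rather than entering
  depolarization block at moderate drive) and at which the somatic rebound
  plateau is suprathreshold.
"""

from __future__ import annotations

import math
from typing import Dict

__all__ = ["GATES", "REVERSALS", "logistic", "GATE_VECTOR_LAYOUT", "pack_gate_vector"]


def logistic(x: float) -> float:
    """Numerically safe logistic sigmoid 1/(1+exp(-x))."""
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


#: Reversal potentials (mV).  The calcium current has no reversal parameter;
#: its driving force comes from the GHK flux form.
REVERSALS: Dict[str, float] = {
    "soma_leak": -50.0,
    "A": -80.0,
    "KCa": -80.0,
    "h": -20.0,
    "MI": -10.0,
    "axon_leak": -55.0,
    "Na": 70.0,
    "K": -80.0,
}

#: Gating table.  ``p``/``q`` are activation/inactivation exponents.
#: Sigmoidal entries are (vhalf, k); time-constant entries are either a
#: constant or (base, amp, vhalf, k) meaning ``base + amp*S((v-vhalf)/k)``.
GATES: Dict[str, dict] = {
    "A": {  # transient potassium current, soma
        "p": 2, "q": 1,
        "m_vk": (-10.0, 20.0), "tau_m": 2.0,
        "h_vk": (-60.0, -7.5), "tau_h": 50.0,
    },
    "Ca": {  # GHK calcium current, soma; inactivation is calcium-dependent
        "p": 3, "q": 1,
        "m_vk": (-45.0, 15.0),
        "tau_m": (100.0, 2500.0, -40.0, 20.0),
        "h_ca_scale": 0.5,          # h_inf = S(-ca/scale), scale in mM
        "tau_h": (500.0, 2500.0, -70.0, -5.0),
    },
    "h": {  # hyperpolarization-activated inward current, soma
        "p": 1, "q": 0,
        "m_vk": (-70.0, -3.0),
        "tau_m": (2500.0, 1500.0, -60.0, 4.0),
    },
    "KCa": {  # calcium-activated potassium current, soma
        "p": 1, "q": 1,
        "ca_half": 1.43e-3,         # mM, Hill half-saturation
        "hill_n": 5.0,
        "m_vk": (-5.5, 8.0),
        # tau_m = a - b*S((v + shift*log10(ca/1e-3))/k)
        "tau_m_coeffs": (499.0, 494.0, 54.6, 10.0),
        "h_ca_scale": 0.03,         # h_inf = S(-ca/scale)
        "tau_h": 25.0,
    },
    "MI": {  # modulator-activated inward current, soma
        "p": 1, "q": 0,
        "m_vk": (-48.0, 5.0), "tau_m": 5.0,
    },
    "Na": {  # fast sodium current, axon
        "p": 3, "q": 1,
        "m_vk": (-22.0, 8.0), "tau_m": 1.0,
        "h_vk": (-28.0, -7.7), "tau_h": 2.5,
    },
    "K": {  # delayed-rectifier potassium current, axon
        "p": 4, "q": 0,
        "m_vk": (-23.0, 5.0),
        "tau_m": (2.0, 7.0, -23.0, -5.0),
    },
}

#: Order of entries in the flat vector handed to the numba kernel.
GATE_VECTOR_LAYOUT = (
    "A_vm", "A_km", "A_taum", "A_vh", "A_kh", "A_tauh",
    "Ca_vm", "Ca_km", "Ca_tm_base", "Ca_tm_amp", "Ca_tm_v", "Ca_tm_k",
    "Ca_h_scale", "Ca_th_base", "Ca_th_amp", "Ca_th_v", "Ca_th_k",
    "h_vm", "h_km", "h_tm_base", "h_tm_amp", "h_tm_v", "h_tm_k",
    "KCa_ca_half", "KCa_hill_n", "KCa_vm", "KCa_km",
    "KCa_tm_a", "KCa_tm_b", "KCa_tm_shift", "KCa_tm_k",
    "KCa_h_scale", "KCa_tauh",
    "MI_vm", "MI_km", "MI_taum",
    "Na_vm", "Na_km", "Na_taum", "Na_vh", "Na_kh", "Na_tauh",
    "K_vm", "K_km", "K_tm_base", "K_tm_amp", "K_tm_v", "K_tm_k",
)


def pack_gate_vector() -> "list[float]":
    """Flatten :data:`GATES` into the kernel's parameter vector."""
    g = GATES
    vals = {
        "A_vm": g["A"]["m_vk"][0], "A_km": g["A"]["m_vk"][1],
        "A_taum": g["A"]["tau_m"],
        "A_vh": g["A"]["h_vk"][0], "A_kh": g["A"]["h_vk"][1],
        "A_tauh": g["A"]["tau_h"],
        "Ca_vm": g["Ca"]["m_vk"][0], "Ca_km": g["Ca"]["m_vk"][1],
        "Ca_tm_base": g["Ca"]["tau_m"][0], "Ca_tm_amp": g["Ca"]["tau_m"][1],
        "Ca_tm_v": g["Ca"]["tau_m"][2], "Ca_tm_k": g["Ca"]["tau_m"][3],
        "Ca_h_scale": g["Ca"]["h_ca_scale"],
        "Ca_th_base": g["Ca"]["tau_h"][0], "Ca_th_amp": g["Ca"]["tau_h"][1],
        "Ca_th_v": g["Ca"]["tau_h"][2], "Ca_th_k": g["Ca"]["tau_h"][3],
        "h_vm": g["h"]["m_vk"][0], "h_km": g["h"]["m_vk"][1],
        "h_tm_base": g["h"]["tau_m"][0], "h_tm_amp": g["h"]["tau_m"][1],
        "h_tm_v": g["h"]["tau_m"][2], "h_tm_k": g["h"]["tau_m"][3],
        "KCa_ca_half": g["KCa"]["ca_half"], "KCa_hill_n": g["KCa"]["hill_n"],
        "KCa_vm": g["KCa"]["m_vk"][0], "KCa_km": g["KCa"]["m_vk"][1],
        "KCa_tm_a": g["KCa"]["tau_m_coeffs"][0],
        "KCa_tm_b": g["KCa"]["tau_m_coeffs"][1],
        "KCa_tm_shift": g["KCa"]["tau_m_coeffs"][2],
        "KCa_tm_k": g["KCa"]["tau_m_coeffs"][3],
        "KCa_h_scale": g["KCa"]["h_ca_scale"], "KCa_tauh": g["KCa"]["tau_h"],
        "MI_vm": g["MI"]["m_vk"][0], "MI_km": g["MI"]["m_vk"][1],
        "MI_taum": g["MI"]["tau_m"],
        "Na_vm": g["Na"]["m_vk"][0], "Na_km": g["Na"]["m_vk"][1],
        "Na_taum": g["Na"]["tau_m"],
        "Na_vh": g["Na"]["h_vk"][0], "Na_kh": g["Na"]["h_vk"][1],
        "Na_tauh": g["Na"]["tau_h"],
        "K_vm": g["K"]["m_vk"][0], "K_km": g["K"]["m_vk"][1],
        "K_tm_base": g["K"]["tau_m"][0], "K_tm_amp": g["K"]["tau_m"][1],
        "K_tm_v": g["K"]["tau_m"][2], "K_tm_k": g["K"]["tau_m"][3],
    }
    return [float(vals[name]) for name in GATE_VECTOR_LAYOUT]
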