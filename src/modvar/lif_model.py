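"""Leaky integrate-and-fire neuron with a linearized modulator conductance.

The membrane obeys

    C_m dv/dt = I_app − g_leak (v − E_leak) − g_MI-L (v − E_MI),

with a spike whenever v crosses v_th followed by an instant reset to
v_reset.  At steady drive the firing rate has the closed form

    f = 1 / (τ_m · ln[(v_ss − v_reset)/(v_ss − v_th)]),

with τ_m = C_m/(g_leak + g_MI-L) and v_ss the conductance-weighted
equilibrium.  A family of such models, differing only in g_leak, is the
first-principles test of whether raising excitability (adding g_MI-L)
compresses the between-model spread of f–I power-law fit parameters.

Units: mV, ms, nA, µS, nF; rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numba import njit

from .fitting import FitFailure, PowerFit, fit_fi_power

__all__ = [
    "LIFParameters",
    "lif_steady_state",
    "lif_frequency",
    "simulate_lif",
    "lif_family_experiment",
]


@dataclass(frozen=True)
class LIFParameters:
    """Membrane and threshold parameters; defaults follow the published
    simulation table (0.1 µF = 100 nF, E_leak −60 mV, E_MI 10 mV,
    v_th −40 mV, v_reset −80 mV)."""

    c_m: float = 100.0  # nF
    g_leak: float = 0.1  # µS
    e_leak: float = -60.0  # mV
    g_mi_l: float = 0.0  # µS
    e_mi: float = 10.0  # mV
    v_th: float = -40.0  # mV
    v_reset: float = -80.0  # mV
    i_app: float = 0.0  # nA

    def __post_init__(self) -> None:
        if self.c_m <= 0 or self.g_leak <= 0:
            raise ValueError("c_m and g_leak must be > 0")
        if self.g_mi_l < 0:
            raise ValueError("g_mi_l must be >= 0")
        if self.v_reset >= self.v_th:
            raise ValueError("v_reset must lie below v_th")

    def with_(self, **kw) -> "LIFParameters":
        return replace(self, **kw)


def lif_steady_state(params: LIFParameters) -> Tuple[float, float]:
    """(v_ss mV, τ_m ms): conductance-weighted equilibrium and membrane
    time constant."""
    g_tot = params.g_leak + params.g_mi_l
    if g_tot <= 0:
        raise ValueError("total conductance must be > 0")
    v_ss = (
        params.i_app + params.g_leak * params.e_leak + params.g_mi_l * params.e_mi
    ) / g_tot
    tau_m = params.c_m / g_tot
    return v_ss, tau_m


def lif_frequency(params: LIFParameters) -> float:
    """Closed-form steady-state firing rate (Hz); 0 at or below rheobase."""
    v_ss, tau_m = lif_steady_state(params)
    if v_ss <= params.v_th:
        return 0.0
    isi_ms = tau_m * np.log((v_ss - params.v_reset) / (v_ss - params.v_th))
    return 1000.0 / isi_ms


def simulate_lif(
    params: LIFParameters, t_total: float, dt: float = 0.01, v0: Optional[float] = None
) -> np.ndarray:
    """Forward-Euler threshold/reset integration; returns spike times (ms).

    This is the brute-force oracle for the closed-form rate; it starts at
    v_reset by default so the first interspike interval is already the
    steady-state one.
    """
    if dt <= 0 or t_total <= 0:
        raise ValueError("dt and t_total must be > 0")
    v = params.v_reset if v0 is None else v0
    g_tot = params.g_leak + params.g_mi_l
    drive = (
        params.i_app + params.g_leak * params.e_leak + params.g_mi_l * params.e_mi
    )
    n = int(round(t_total / dt))
    return _euler_threshold_reset(
        float(v), drive, g_tot, params.c_m, params.v_th, params.v_reset, dt, n
    )


@njit(cache=True)
def _euler_threshold_reset(v, drive, g_tot, c_m, v_th, v_reset, dt, n):
    spikes = []
    for i in range(n):
        v += dt / c_m * (drive - g_tot * v)
        if v >= v_th:
            spikes.append((i + 1) * dt)
            v = v_reset
    return np.asarray(spikes)


def lif_family_experiment(
    n: int = 500,
    g_mi_levels: Sequence[float] = (0.0, 0.2, 0.36),
    i_grid: Optional[np.ndarray] = None,
    f_cap: float = 20.0,
    seed: int = 0,
    g_leak_range: Tuple[float, float] = (0.05, 0.2),
) -> pd.DataFrame:
    """Power-law f–I fits for a family of LIF models at each g_MI-L level.

    g_leak is sampled once from Uniform[0.05, 0.2) µS (fixed seed) and the
    same draw is reused at every level.  Analytic rates are computed on the
    current grid (default −50…100 nA in 1 nA steps), rates above ``f_cap``
    are dropped (the f–I curves of these models do not saturate, so all
    fits see the same frequency range), and the suprathreshold points are
    fitted with f = a·(I−I0)^b, 0 ≤ b ≤ 1.

    The threshold current I0 is pinned at the largest silent current
    level (the step just below the one that first elicited spikes):
    for these analytic curves the threshold is directly observed rather
    than extrapolated, so it is measured, not fitted.

    Returns a tidy frame with one row per (model, level): columns
    ``model``, ``g_leak``, ``g_mi_l``, ``a``, ``i0``, ``b``, ``n_points``.
    Models whose truncated curve has fewer than three suprathreshold
    points at some level are recorded with NaN fit parameters.
    """
    if n < 2:
        raise ValueError("need at least two models")
    if any(g < 0 for g in g_mi_levels):
        raise ValueError("g_MI-L levels must be non-negative")
    if i_grid is None:
        i_grid = np.arange(-50.0, 100.0 + 0.5, 1.0)
    rng = np.random.default_rng(seed)
    g_leaks = rng.uniform(*g_leak_range, size=n)

    rows = []
    for level in g_mi_levels:
        for m, gl in enumerate(g_leaks):
            base = LIFParameters(g_leak=float(gl), g_mi_l=float(level))
            f = np.array(
                [lif_frequency(base.with_(i_app=float(i))) for i in i_grid]
            )
            keep = f <= f_cap
            pts = list(zip(i_grid[keep], f[keep]))
            try:
                fit = fit_fi_power(pts, seed=seed, fix_i0=True)
                rows.append(
                    dict(model=m, g_leak=gl, g_mi_l=level, a=fit.a,
                         i0=fit.i0, b=fit.b, n_points=fit.n_points)
                )
            except FitFailure:
                rows.append(
                    dict(model=m, g_leak=gl, g_mi_l=level, a=np.nan,
                         i0=np.nan, b=np.nan, n_points=0)
                )
    return pd.DataFrame(rows)
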