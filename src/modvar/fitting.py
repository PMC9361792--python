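"""Bounded nonlinear fits of the three parametric forms and hysteresis.

* power law  f(I) = a·(I − I0)^b  with 0 ≤ b ≤ 1 (sublinear f–I curves);
* logistic sigmoid  f(x) = a / (1 + exp(−(x − x_half)/k))  for synaptic
  I–V curves and cumulative rebound spike histograms;
* modulator-current I–V  f(V) = a·(V − b) / (1 + exp(−(V − V_half)/k))
  whose minimum over the ramp span is the peak inward current.

All fits are bounded least squares with a small set of seeded multistarts,
deterministic for a fixed seed and invariant to point ordering; ties are
broken by lowest residual then lowest b (power fits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PowerFit",
    "SigmoidFit",
    "IMIFit",
    "FitFailure",
    "power_law",
    "sigmoid",
    "imi_iv_curve",
    "fit_fi_power",
    "fit_sigmoid",
    "fit_imi_iv",
    "hysteresis_ratio",
]

_N_STARTS = 5
_TOL = 1e-10


class FitFailure(RuntimeError):
    """Raised when a fit has too few usable points or degenerate input."""


@dataclass(frozen=True)
class PowerFit:
    a: float  # Hz·nA^−b
    i0: float  # nA, threshold current
    b: float  # exponent in [0, 1]
    residual: float
    n_points: int
    bound_hit: bool = False  # b pinned at 0 or 1

    def __call__(self, i):
        return power_law(np.asarray(i, dtype=float), self.a, self.i0, self.b)


@dataclass(frozen=True)
class SigmoidFit:
    a: float  # plateau
    x_half: float  # midpoint (mV or s)
    k: float  # slope factor
    residual: float
    n_points: int

    def __call__(self, x):
        return sigmoid(np.asarray(x, dtype=float), self.a, self.x_half, self.k)


@dataclass(frozen=True)
class IMIFit:
    a: float
    b: float  # reversal, mV in [0, 40]
    v_half: float  # mV in [−40, 0]
    k: float  # mV in [0.1, 20]
    peak: float  # minimum (most negative) fitted current over the span, nA
    residual: float
    n_points: int
    flagged: bool = False  # optimizer stuck at an all-bounds corner

    def __call__(self, v):
        return imi_iv_curve(np.asarray(v, dtype=float), self.a, self.b, self.v_half, self.k)


def power_law(i, a, i0, b):
    """f = a·(I−I0)^b above threshold, 0 below."""
    x = np.maximum(np.asarray(i, dtype=float) - i0, 0.0)
    return a * x**b


def sigmoid(x, a, x_half, k):
    """Logistic a/(1+exp(−(x−x_half)/k)); rising with x when k > 0."""
    return a / (1.0 + np.exp(-(np.asarray(x, dtype=float) - x_half) / k))


def imi_iv_curve(v, a, b, v_half, k):
    """Modulator-current I–V: linear driving force times logistic activation."""
    v = np.asarray(v, dtype=float)
    z = np.clip(-(v - v_half) / k, -700.0, 700.0)
    return a * (v - b) / (1.0 + np.exp(z))


def _multistart(residual_fn, starts, bounds):
    best = None
    for x0 in starts:
        x0c = np.clip(x0, bounds[0], bounds[1])
        try:
            sol = least_squares(
                residual_fn, x0c, bounds=bounds, xtol=_TOL, ftol=_TOL, gtol=_TOL
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
        elif best is not None and abs(sol.cost - best.cost) <= 1e-15:
            # deterministic tie-break: prefer the smaller last parameter
            if sol.x[-1] < best.x[-1]:
                best = sol
    if best is None:
        raise FitFailure("optimizer failed from every start")
    return best


def fit_fi_power(
    points: Sequence[Tuple[float, float]],
    seed: int = 0,
    include_zero: bool = False,
    fix_i0: bool = False,
) -> PowerFit:
    """Fit f = a·(I − I0)^b with b clamped to [0, 1].

    ``points`` are (I nA, f Hz) pairs; by default only suprathreshold
    (f > 0) points enter the residual.  I0 is a free parameter initialized
    at the largest zero-frequency current; with ``fix_i0`` it is pinned
    there (the current level that first elicited spikes lies just above
    it) and only (a, b) are fitted — the convention for analytic f–I
    curves where the threshold is directly observed.  Requires >= 3
    suprathreshold points.
    """
    pts = np.asarray(sorted(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (I, f) pairs")
    i_all, f_all = pts[:, 0], pts[:, 1]
    pos = f_all > 0
    if pos.sum() < 3:
        raise FitFailure(
            f"need >= 3 suprathreshold points, got {int(pos.sum())}"
        )
    if include_zero:
        i_fit, f_fit = i_all, f_all
    else:
        i_fit, f_fit = i_all[pos], f_all[pos]
    i_first_spiking = float(i_all[pos].min())

    sub = i_all[~pos]
    i0_init = float(sub.max()) if sub.size else i_first_spiking - 0.5
    span = max(i_all.max() - i_all.min(), 1.0)
    f_scale = max(f_fit.max(), 1.0)

    rng = np.random.default_rng(seed)
    if fix_i0:
        def resid2(theta):
            a, b = theta
            return power_law(i_fit, a, i0_init, b) - f_fit

        starts = [np.array([f_scale, b0]) for b0 in (0.2, 0.5, 0.9)]
        for _ in range(_N_STARTS - len(starts)):
            starts.append(
                np.array([f_scale * rng.uniform(0.3, 3.0), rng.uniform(0.05, 0.95)])
            )
        bounds2 = (np.array([0.0, 0.0]), np.array([np.inf, 1.0]))
        sol = _multistart(resid2, starts, bounds2)
        a, b = sol.x
        i0 = i0_init
    else:
        def resid(theta):
            a, i0, b = theta
            return power_law(i_fit, a, i0, b) - f_fit

        starts = [np.array([f_scale, i0_init, b0]) for b0 in (0.2, 0.5, 0.9)]
        for _ in range(_N_STARTS - len(starts)):
            starts.append(
                np.array(
                    [
                        f_scale * rng.uniform(0.3, 3.0),
                        i0_init - rng.uniform(0.0, 0.5) * span,
                        rng.uniform(0.05, 0.95),
                    ]
                )
            )
        eps = 1e-9
        bounds = (
            np.array([0.0, i_all.min() - 2 * span, 0.0]),
            np.array([np.inf, i_first_spiking - eps, 1.0]),
        )
        sol = _multistart(resid, starts, bounds)
        a, i0, b = sol.x
    return PowerFit(
        a=float(a), i0=float(i0), b=float(b),
        residual=float(np.sqrt(2 * sol.cost)), n_points=int(i_fit.size),
        bound_hit=bool(b > 1 - 1e-7 or b < 1e-7),
    )


def fit_sigmoid(
    points: Sequence[Tuple[float, float]],
    mode: str = "cumulative_time",
    seed: int = 0,
) -> SigmoidFit:
    """Fit the logistic sigmoid in one of two bound regimes.

    ``synaptic_IV``: lower bounds a >= −10 (nA) and x_half >= −80 (mV),
    slope sign free.  ``cumulative_time``: a >= 0, x_half >= 0, k > 0
    (curve rises with time).  Requires >= 4 points and non-constant y.
    """
    pts = np.asarray(sorted(points), dtype=float)
    if pts.shape[0] < 4:
        raise FitFailure("need >= 4 points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(y) == 0:
        raise FitFailure("degenerate (constant) input")

    a0 = y[-1] if abs(y[-1]) >= abs(y[0]) else y[0]
    if a0 == 0:
        a0 = float(np.max(np.abs(y))) or 1.0
    xh0 = float(np.interp(0.5, np.abs(y) / np.max(np.abs(y)), x))
    k0 = max(np.ptp(x) / 10.0, 1e-3)

    def resid(theta):
        return sigmoid(x, *theta) - y

    rng = np.random.default_rng(seed)
    if mode == "synaptic_IV":
        bounds = (np.array([-10.0, -80.0, -np.inf]), np.array([np.inf, np.inf, np.inf]))
        starts = [np.array([a0, xh0, k0]), np.array([a0, xh0, -k0])]
    elif mode == "cumulative_time":
        bounds = (np.array([0.0, 0.0, 1e-6]), np.array([np.inf, np.inf, np.inf]))
        starts = [np.array([max(a0, 1e-3), max(xh0, 1e-3), k0])]
    else:
        raise ValueError(f"unknown sigmoid fit mode {mode!r}")
    while len(starts) < _N_STARTS:
        starts.append(
            starts[0]
            * np.array([rng.uniform(0.5, 2.0), rng.uniform(0.5, 2.0), rng.uniform(0.3, 3.0)])
        )
    sol = _multistart(resid, starts, bounds)
    return SigmoidFit(
        a=float(sol.x[0]), x_half=float(sol.x[1]), k=float(sol.x[2]),
        residual=float(np.sqrt(2 * sol.cost)), n_points=int(x.size),
    )


def fit_imi_iv(
    points: Sequence[Tuple[float, float]], seed: int = 0
) -> IMIFit:
    """Bounded fit of the modulator difference-current I–V.

    Bounds: 0 <= a, 0 <= b <= 40 mV, −40 <= V_half <= 0 mV,
    0.1 <= k <= 20 mV.  The peak inward current is the minimum of the
    fitted curve over the sampled voltage span.  A fit pinned at a bounds
    corner is flagged, not raised.
    """
    pts = np.asarray(sorted(points), dtype=float)
    if pts.shape[0] < 5:
        raise FitFailure("need >= 5 points")
    v, y = pts[:, 0], pts[:, 1]

    def resid(theta):
        return imi_iv_curve(v, *theta) - y

    peak_guess = max(-float(y.min()), 1e-3)
    a0 = peak_guess / 30.0
    rng = np.random.default_rng(seed)
    starts = [np.array([a0, 10.0, -20.0, 6.0])]
    while len(starts) < _N_STARTS:
        starts.append(
            np.array(
                [
                    a0 * rng.uniform(0.2, 5.0),
                    rng.uniform(0.0, 40.0),
                    rng.uniform(-40.0, 0.0),
                    rng.uniform(0.5, 15.0),
                ]
            )
        )
    bounds = (np.array([0.0, 0.0, -40.0, 0.1]), np.array([np.inf, 40.0, 0.0, 20.0]))
    sol = _multistart(resid, starts, bounds)
    a, b, v_half, k = (float(u) for u in sol.x)
    grid = np.linspace(v.min(), v.max(), 2001)
    peak = float(np.min(imi_iv_curve(grid, a, b, v_half, k)))
    lo, hi = bounds
    at_bound = [
        abs(x - l) < 1e-9 or abs(x - h) < 1e-9
        for x, l, h in zip(sol.x, lo, hi)
        if np.isfinite(l) or np.isfinite(h)
    ]
    flagged = all(at_bound) and len(at_bound) > 0
    return IMIFit(
        a=a, b=b, v_half=v_half, k=k, peak=peak,
        residual=float(np.sqrt(2 * sol.cost)), n_points=int(v.size),
        flagged=flagged,
    )


def hysteresis_ratio(
    up_steps: Sequence[Tuple[float, float]],
    down_steps: Sequence[Tuple[float, float]],
    band: Tuple[float, float] = (2.0, 4.0),
) -> Optional[float]:
    """Mean frequency in the current band, ascending ÷ descending limb.

    Band endpoints are inclusive.  Returns None (missing) when the
    descending mean is zero; 0 when only the ascending limb is silent.
    """
    lo, hi = band

    def band_mean(steps):
        arr = np.asarray(list(steps), dtype=float)
        sel = arr[(arr[:, 0] >= lo - 1e-12) & (arr[:, 0] <= hi + 1e-12)]
        if sel.size == 0:
            raise ValueError("limb has no steps inside the band")
        return float(sel[:, 1].mean())

    up = band_mean(up_steps)
    down = band_mean(down_steps)
    if down == 0.0:
        return None
    return up / down
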