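"""Closed-form frequency, velocity and growth-rate profiles and PSM length.

The model rescales fixed spatial shapes with the instantaneous tissue
length: the intrinsic frequency is omega(x, t) = omega0 * U(x / xbar(t)),
the cell velocity v(x, t) = v0 * V(x / xbar(t)), with

    U(xi) = sigma + (1 - sigma) * (1 - exp(k (xi - 1))) / (1 - exp(-k))
            for xi <= 1, and 0 for xi > 1 (oscillations arrested beyond
            the anterior end; U(0) = 1, U(1) = sigma),
    V(xi) = 1 - exp(-q xi)  (v(0) = 0 at the posterior tip).

The PSM length follows xbar(t) = x0 + x1 tanh(eta (t - tbar)).
All functions are vectorised over their position/time argument.
"""

from __future__ import annotations

import numpy as np

from .params import (
    FrequencyProfileParams,
    LengthDynamicsParams,
    ParameterError,
    VelocityProfileParams,
)

__all__ = [
    "eval_U",
    "eval_V",
    "psm_length",
    "psm_length_rate",
    "frequency_field",
    "velocity_field",
    "growth_rate_profile",
]


def eval_U(xi, p: FrequencyProfileParams):
    """Scaled frequency profile U(xi) at dimensionless position xi = x/xbar.

    Continuous and strictly decreasing on [0, 1] from U(0) = 1 down to
    U(1) = sigma, then jumps to 0 for xi > 1.
    """
    xi = np.asarray(xi, dtype=float)
    if not np.all(np.isfinite(xi)):
        raise ParameterError("xi must be finite")
    inside = xi <= 1.0
    shoulder = p.sigma + (1.0 - p.sigma) * (1.0 - np.exp(p.k * (xi - 1.0))) / (
        1.0 - np.exp(-p.k)
    )
    out = np.where(inside, shoulder, 0.0)
    return out if out.ndim else float(out)


def eval_V(xi, p: VelocityProfileParams):
    """Scaled velocity profile V(xi) = 1 - exp(-q xi), for xi >= 0."""
    xi = np.asarray(xi, dtype=float)
    if np.any(xi < 0):
        raise ParameterError("xi must be >= 0")
    out = 1.0 - np.exp(-p.q * xi)
    return out if out.ndim else float(out)


def psm_length(t, p: LengthDynamicsParams):
    """PSM length xbar(t) = x0 + x1 tanh(eta (t - tbar)) [um]."""
    t = np.asarray(t, dtype=float)
    out = p.x0 + p.x1 * np.tanh(p.eta * (t - p.tbar))
    return out if out.ndim else float(out)


def psm_length_rate(t, p: LengthDynamicsParams):
    """Analytic d(xbar)/dt = x1 * eta * sech^2(eta (t - tbar)) [um/min]."""
    t = np.asarray(t, dtype=float)
    # sech^2 written via tanh to avoid cosh overflow at large |t|
    out = p.x1 * p.eta * (1.0 - np.tanh(p.eta * (t - p.tbar)) ** 2)
    return out if out.ndim else float(out)


def frequency_field(x, t, fp: FrequencyProfileParams, lp: LengthDynamicsParams):
    """Intrinsic angular frequency omega(x, t) = omega0 U(x/xbar(t)) [rad/min]."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ParameterError("x must be >= 0")
    xbar = psm_length(t, lp)
    out = fp.omega0 * np.asarray(eval_U(x / xbar, fp))
    return out if out.ndim else float(out)


def velocity_field(x, t, vp: VelocityProfileParams, lp: LengthDynamicsParams):
    """Cell velocity v(x, t) = v0 V(x/xbar(t)) [um/min]; v(0, t) = 0 exactly."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ParameterError("x must be >= 0")
    xbar = psm_length(t, lp)
    out = vp.v0 * np.asarray(eval_V(x / xbar, vp))
    return out if out.ndim else float(out)


def growth_rate_profile(x, t, vp: VelocityProfileParams, lp: LengthDynamicsParams):
    """Local growth rate dv/dx = (q v0 / xbar) exp(-q x / xbar) [1/min].

    Maximal at the posterior tip x = 0 and decaying over the length scale
    xbar/q.
    """
    x = np.asarray(x, dtype=float)
    xbar = psm_length(t, lp)
    out = (vp.q * vp.v0 / xbar) * np.exp(-vp.q * x / xbar)
    return out if out.ndim else float(out)
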