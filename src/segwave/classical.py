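"""Closed-form classical-wave analogues of the Doppler and
dynamic-wavelength effects.

Two exact solutions of one-dimensional wave equations with a sinusoidal
source u(0, t) = u0 sin(omega t) and zero initial condition:

* plane wave  u = u0 sin(omega t - 2 pi x / lambda), lambda = 2 pi c /
  omega: an observer moving toward the source at speed vbar sees the
  Doppler-shifted frequency Omega = (1 + vbar/c) omega;
* wave in a medium with time-dependent refractive index n(t) = r t^2:
  u = u0 (1 + (r/c) x t) sin(omega t / (1 + (r/c) x t)), whose local
  wavelength at fixed x shrinks over time, so a static observer sees a
  red-shifted frequency Omega = omega / (1 + r x t / c)^2 — the
  dynamic-wavelength effect with Omega_W < 0.

These closed forms serve as exact oracles for the Doppler and
dynamic-wavelength operators used on simulated phase fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClassicalWaveParams",
    "plane_wave",
    "plane_wave_phase",
    "doppler_observed_frequency",
    "refractive_wave",
    "refractive_phase",
    "refractive_local_wavelength",
    "refractive_local_frequency",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class ClassicalWaveParams:
    """Source frequency ``omega`` [rad/time], propagation speed ``c``
    [length/time], amplitude ``u0``; ``vbar`` >= 0 is the observer speed in
    the Doppler case, ``r`` >= 0 the refractive-index rate [1/time^2] in
    the dynamic-wavelength case."""

    omega: float = 1.0
    c: float = 1.0
    u0: float = 1.0
    vbar: float = 0.0
    r: float = 0.0

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.vbar < 0 or self.r < 0:
            raise ValueError("vbar and r must be >= 0")

    @property
    def wavelength(self) -> float:
        """Plane-wave wavelength lambda = 2 pi c / omega."""
        return TWO_PI * self.c / self.omega


def plane_wave_phase(x, t, p: ClassicalWaveParams):
    """Phase omega t - 2 pi x / lambda of the plane wave.

    Accepts complex arguments (the phase is analytic), so complex-step
    differentiation can be used against it.
    """
    x = np.asarray(x)
    t = np.asarray(t)
    out = p.omega * t - TWO_PI * x / p.wavelength
    return out if out.ndim else out.item()


def plane_wave(x, t, p: ClassicalWaveParams):
    """Amplitude u(x, t) = u0 sin(omega t - 2 pi x / lambda)."""
    out = p.u0 * np.sin(plane_wave_phase(x, t, p))
    return out if np.ndim(out) else float(out)


def doppler_observed_frequency(p: ClassicalWaveParams) -> float:
    """Frequency seen by an observer approaching the source at speed vbar:
    Omega = (1 + vbar/c) omega = omega + Omega_D."""
    return float((1.0 + p.vbar / p.c) * p.omega)


def doppler_shift(p: ClassicalWaveParams) -> float:
    """Omega_D = (dxbar/dt)(dphi/dx) = vbar omega / c for the plane wave."""
    return float(p.vbar * p.omega / p.c)


def refractive_phase(x, t, p: ClassicalWaveParams):
    """Phase omega t / (1 + r x t / c) of the dynamic-index solution.

    Accepts complex arguments (analytic away from the pole), enabling
    complex-step differentiation.
    """
    x = np.asarray(x)
    t = np.asarray(t)
    out = p.omega * t / (1.0 + p.r * x * t / p.c)
    return out if out.ndim else out.item()


def refractive_wave(x, t, p: ClassicalWaveParams):
    """u(x, t) = u0 (1 + (r/c) x t) sin(omega t / (1 + (r/c) x t)).

    Exact solution of u_tt = (c/n(t))^2 u_xx with n(t) = r t^2, source
    u(0, t) = u0 sin(omega t) and u(x, 0) = 0.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    pref = 1.0 + p.r * x * t / p.c
    out = p.u0 * pref * np.sin(p.omega * t / pref)
    return out if out.ndim else float(out)


def refractive_local_wavelength(x, t, p: ClassicalWaveParams):
    """Local wavelength lambda(x, t) = (2 pi / (r c omega)) (r x + c/t)^2.

    Equals 2 pi / |dphi/dx| of the dynamic-index phase; undefined
    (infinite) at t = 0, decreasing in t at fixed x > 0, with the
    time-independent large-time limit 2 pi r x^2 / (c omega).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        out = TWO_PI / (p.r * p.c * p.omega) * (p.r * x + p.c / t) ** 2
    return out if out.ndim else float(out)


def refractive_local_frequency(x, t, p: ClassicalWaveParams):
    """Local frequency Omega(x, t) = omega / (1 + r x t / c)^2 seen by a
    static observer; Omega = omega + Omega_W with Omega_W < 0 for
    x, t > 0."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    out = p.omega / (1.0 + p.r * x * t / p.c) ** 2
    return out if out.ndim else float(out)
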