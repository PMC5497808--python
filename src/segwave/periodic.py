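"""Time-periodic wave patterns at constant PSM length.

With the length frozen at xbar0 the phase field relaxes, after a
transient, to phi(x, t) = Omega t + psi(x): a rigidly rotating pattern
with collective frequency Omega and a stationary profile psi obeying

    Omega + v psi' = omega + (epsilon/2) psi'',   psi'(0) = 0.

For weak coupling the collective frequency is set by the posterior tip,
Omega ~= omega0, and the profile is approximated by the quadrature
psi(x) ~= int_0^x (omega(x') - Omega) / v(x') dx'.  This module finds the
periodic state by relaxation of the full PDE, evaluates the weak-coupling
approximations, and provides the clock-and-wavefront segment length
S = v0 T with T = 2 pi / Omega.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid

from . import profiles
from .params import ModelParameters, SimulationConfig
from .solver import PhaseField, simulate_constant_length

__all__ = [
    "PeriodicState",
    "find_periodic_state",
    "weak_coupling_profile",
    "phase_velocity_approx",
    "clock_wavefront_segment_length",
    "ConvergenceError",
]

TWO_PI = 2.0 * np.pi


class ConvergenceError(RuntimeError):
    """Periodic state not reached within the allotted time."""


@dataclass
class PeriodicState:
    """Converged time-periodic pattern at constant PSM length.

    ``Omega`` [rad/min] and ``T = 2 pi / Omega`` [min]; ``x`` and
    ``psi_profile`` give the stationary phase profile on [0, xbar0] with
    psi(0) = 0; ``residual`` is the sup-norm periodicity defect of psi over
    one period at convergence; ``ode_residual`` the max defect of the
    stationary balance Omega + v psi' - omega - (eps/2) psi'' on the
    interior grid; ``field`` the final relaxation run.
    """

    Omega: float
    T: float
    x: np.ndarray
    psi_profile: np.ndarray
    xbar0: float
    residual: float
    ode_residual: float
    field: PhaseField

    def wave_count(self) -> float:
        """K = |psi(xbar0)| / 2 pi."""
        return float(abs(self.psi_profile[-1]) / TWO_PI)


def _psi_of(pf: PhaseField, j: int, nx_psm: int) -> np.ndarray:
    return pf.phi[j, :nx_psm] - pf.phi[j, 0]


def find_periodic_state(
    mp: ModelParameters,
    xbar0: float,
    sc: Optional[SimulationConfig] = None,
    tol: float = 1e-4,
    max_chunks: int = 40,
) -> PeriodicState:
    """Relax the constant-length PDE to its time-periodic state.

    Runs the solver in chunks of ~5 estimated periods until the relative
    sup-norm change of psi over one period drops below ``tol``.  Omega is
    the least-squares slope of the posterior phase over the final three
    periods.
    """
    if sc is None:
        sc = SimulationConfig(t_end=0.0, dx=1.0, L=1.25 * xbar0, output_stride=8)
    T_est = TWO_PI / mp.freq.omega0
    chunk = 5.0 * T_est
    t_start = 0.0
    phi0 = None
    pf = None
    for _ in range(max_chunks):
        sc_chunk = dc_replace(sc, t_end=t_start + chunk)
        pf = simulate_constant_length(
            mp, xbar0, sc_chunk, t_start=t_start, phi0=phi0
        )
        nx_psm = int(np.floor(xbar0 / pf.dx)) + 1
        t = pf.t_grid
        j_end = len(t) - 1
        j_per = int(np.argmin(np.abs(t - (t[-1] - T_est))))
        psi_now = _psi_of(pf, j_end, nx_psm)
        psi_then = _psi_of(pf, j_per, nx_psm)
        defect = float(np.max(np.abs(psi_now - psi_then)))
        scale = max(float(np.max(np.abs(psi_now))), 1.0)
        if defect / scale < tol:
            break
        t_start = float(t[-1])
        phi0 = pf.phi[-1]
    else:
        raise ConvergenceError(
            f"no periodic state within {max_chunks} chunks "
            f"(last relative defect {defect / scale:.2e})"
        )

    # Omega: LS slope of phi(0, t) over the final 3 estimated periods
    sel = pf.t_grid >= pf.t_grid[-1] - 3.0 * T_est
    Omega = float(np.polyfit(pf.t_grid[sel], pf.phi[sel, 0], 1)[0])

    x = pf.x_grid[:nx_psm]
    psi = _psi_of(pf, len(pf.t_grid) - 1, nx_psm)

    # residual of the stationary balance on the interior grid
    v = mp.vel.v0 * (1.0 - np.exp(-mp.vel.q * x / xbar0))
    omega = mp.freq.omega0 * np.asarray(profiles.eval_U(x / xbar0, mp.freq))
    dpsi = np.gradient(psi, x)
    d2psi = np.gradient(dpsi, x)
    ode_res = Omega + v * dpsi - omega - 0.5 * mp.epsilon * d2psi
    ode_residual = float(np.max(np.abs(ode_res[2:-2])))

    return PeriodicState(
        Omega=Omega,
        T=TWO_PI / Omega,
        x=x,
        psi_profile=psi,
        xbar0=float(xbar0),
        residual=defect / scale,
        ode_residual=ode_residual,
        field=pf,
    )


def weak_coupling_profile(
    mp: ModelParameters,
    xbar0: float,
    Omega: Optional[float] = None,
    n: int = 2001,
) -> tuple[np.ndarray, np.ndarray]:
    """Weak-coupling phase profile psi(x) = int_0^x (omega - Omega)/v dx'.

    Returns (x, psi) on a uniform n-point grid over [0, xbar0].  Omega
    defaults to omega0, for which the integrand has a finite limit
    omega0 U'(0) / (v0 q) at x = 0; any other Omega makes the integral
    divergent at the origin (v(0) = 0) and raises.
    """
    omega0 = mp.freq.omega0
    if Omega is None:
        Omega = omega0
    if not np.isclose(Omega, omega0, rtol=0, atol=1e-12 * omega0):
        raise ValueError(
            "the weak-coupling integral diverges at x=0 unless Omega = omega0"
        )
    x = np.linspace(0.0, xbar0, n)
    xi = x / xbar0
    omega = omega0 * np.asarray(profiles.eval_U(xi, mp.freq))
    v = mp.vel.v0 * (1.0 - np.exp(-mp.vel.q * xi))
    integrand = np.empty_like(x)
    integrand[1:] = (omega[1:] - Omega) / v[1:]
    # analytic x -> 0 limit: omega0 U'(0) / (v0 q)
    k, s = mp.freq.k, mp.freq.sigma
    Uprime0 = -(1.0 - s) * k * np.exp(-k) / (1.0 - np.exp(-k))
    integrand[0] = omega0 * Uprime0 / (mp.vel.v0 * mp.vel.q)
    psi = np.concatenate([[0.0], cumulative_trapezoid(integrand, x)])
    return x, psi


def phase_velocity_approx(x, mp: ModelParameters, xbar0: float):
    """Weak-coupling phase velocity vtilde(x) = v(x) / (1 - omega(x)/omega0).

    Diverges (returns +inf) at x = 0 where omega = omega0; beyond the PSM
    (omega = 0) it reduces to the cell velocity v(x).
    """
    x = np.asarray(x, dtype=float)
    xi = x / xbar0
    omega_ratio = np.asarray(profiles.eval_U(xi, mp.freq))
    v = mp.vel.v0 * (1.0 - np.exp(-mp.vel.q * np.maximum(xi, 0.0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(omega_ratio < 1.0, v / (1.0 - omega_ratio), np.inf)
    return out if out.ndim else float(out)


def clock_wavefront_segment_length(mp: ModelParameters, Omega: float) -> float:
    """Clock-and-wavefront segment length S = v0 * T, T = 2 pi / Omega [um]."""
    if Omega <= 0:
        raise ValueError("Omega must be > 0")
    return float(mp.vel.v0 * TWO_PI / Omega)
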