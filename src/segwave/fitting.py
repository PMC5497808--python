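"""Parameter estimation from tabular data.

Three fits mirror how the zebrafish parameter set was obtained:

* ``fit_length_dynamics`` — nonlinear least squares of the tanh length law
  xbar(t) = x0 + x1 tanh(eta (t - tbar)) to a (time, PSM length) series;
* ``fit_boundary_velocities`` — per-boundary mean velocities (least-squares
  slopes of position tracks) regressed on mean position with the saturating
  profile v0 (1 - exp(-a x)), a = q/xbar treated as a single inverse
  length;
* ``fit_phase_profile`` — the profile-shape parameters (k, sigma, q) and
  the start time t0 from a phase kymograph, by forward-simulating the
  model and minimising a circular mismatch, sum of 1 - cos(psi_model -
  psi_data), over the PSM region.  The circular loss makes the objective
  insensitive to 2 pi wrapping of the data; referencing psi to the
  posterior (x = 0) makes it invariant to any constant phase offset.
  omega0, v0 and epsilon are held fixed (they are measured/literature
  values, not outcomes of this fit).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace as dc_replace
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize

from . import profiles
from .params import (
    LengthDynamicsParams,
    ModelParameters,
    ParameterError,
    SimulationConfig,
)
from .solver import simulate

__all__ = [
    "FitResult",
    "fit_length_dynamics",
    "fit_boundary_velocities",
    "fit_phase_profile",
]


@dataclass
class FitResult:
    """Outcome of a parameter fit.

    ``params``: estimates by name; ``residual``: objective value at the
    optimum (>= 0); ``n_points``: number of data points used;
    ``converged``: optimizer success flag; ``stderr``: asymptotic standard
    errors where the fit provides them; ``warnings``: human-readable notes
    (degenerate data, weakly constrained parameters, ...).
    """

    params: Dict[str, float]
    residual: float
    n_points: int
    converged: bool
    stderr: Dict[str, float] = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def __getitem__(self, key: str) -> float:
        return self.params[key]

    def to_dict(self) -> dict:
        return {
            "params": dict(self.params),
            "stderr": dict(self.stderr),
            "residual": self.residual,
            "n_points": self.n_points,
            "converged": self.converged,
            "warnings": list(self.warnings),
        }


def _tanh_length(t, x0, x1, eta, tbar):
    return x0 + x1 * np.tanh(eta * (t - tbar))


def fit_length_dynamics(series: pd.DataFrame) -> FitResult:
    """Fit the tanh PSM-length law to a table with columns t_min, length_um.

    Needs at least 4 points spanning some curvature of the tanh.  A
    near-constant series is reported with eta ~ 0 and a flat-fit warning
    rather than an error.
    """
    t = np.asarray(series["t_min"], dtype=float)
    y = np.asarray(series["length_um"], dtype=float)
    if len(t) < 4:
        raise ParameterError("need >= 4 points to fit the length dynamics")

    warnings = []
    span = float(y.max() - y.min())
    if span < 1e-9 * max(1.0, abs(float(y.mean()))):
        warnings.append("constant length series: eta ~ 0, flat fit")
        params = {
            "x0": float(y.mean()),
            "x1": 0.0,
            "eta": 0.0,
            "tbar": float(np.median(t)),
        }
        return FitResult(
            params=params, residual=float(np.sum((y - y.mean()) ** 2)),
            n_points=len(t), converged=True, warnings=warnings,
        )

    # initial guesses: midrange level, half-span amplitude, slope sign
    slope = np.polyfit(t, y, 1)[0]
    x0_0 = float((y.max() + y.min()) / 2)
    x1_0 = float(span / 2) * (1.0 if slope > 0 else -1.0)
    eta_0 = max(abs(slope) / max(abs(x1_0), 1e-9), 1e-5)
    p0 = [x0_0, x1_0, eta_0, float(np.median(t))]
    popt, pcov = curve_fit(_tanh_length, t, y, p0=p0, maxfev=20000)
    x0, x1, eta, tbar = popt
    # canonical sign convention: x1 > 0, sign carried by eta
    if x1 < 0:
        x1, eta = -x1, -eta
    resid = float(np.sum((y - _tanh_length(t, x0, x1, eta, tbar)) ** 2))
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan] * 4
    return FitResult(
        params={"x0": float(x0), "x1": float(x1), "eta": float(eta),
                "tbar": float(tbar)},
        stderr=dict(zip(("x0", "x1", "eta", "tbar"), map(float, perr))),
        residual=resid, n_points=len(t), converged=True, warnings=warnings,
    )


def fit_boundary_velocities(tracks: Sequence[pd.DataFrame]) -> FitResult:
    """Fit v0 (1 - exp(-a x)) to per-boundary mean velocities.

    Each track is a table with columns t_min, x_um; its mean velocity is
    the least-squares slope and its mean position the time average.
    ``a = q/xbar`` is treated as a single inverse-length parameter
    [1/um].  Tracks with fewer than 2 points are excluded with a warning;
    at least 2 usable boundaries are required.
    """
    warnings = []
    pos, vel = [], []
    for i, tr in enumerate(tracks):
        if len(tr) < 2:
            warnings.append(f"track {i} has < 2 points; excluded")
            continue
        tt = np.asarray(tr["t_min"], dtype=float)
        xx = np.asarray(tr["x_um"], dtype=float)
        vel.append(float(np.polyfit(tt, xx, 1)[0]))
        pos.append(float(xx.mean()))
    if len(pos) < 2:
        raise ParameterError("need >= 2 usable boundary tracks")
    pos = np.array(pos)
    vel = np.array(vel)

    vmax = float(max(vel.max(), 1e-12))
    if vel.max() <= 1e-9:
        return FitResult(
            params={"v0": 0.0, "q_over_xbar": np.nan},
            residual=float(np.sum(vel**2)), n_points=len(pos), converged=True,
            warnings=warnings + ["all boundaries stationary: v0 ~ 0"],
        )

    def model(x, v0, a):
        return v0 * (1.0 - np.exp(-a * x))

    p0 = [vmax, 2.0 / max(pos.mean(), 1.0)]
    popt, pcov = curve_fit(model, pos, vel, p0=p0, maxfev=20000)
    v0, a = map(float, popt)
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan] * 2
    # a is weakly constrained when all boundaries sit in the saturated
    # far field (a * x >> 1 for every point)
    if np.min(a * pos) > 4.0:
        warnings.append(
            "all tracks in the saturated far field: q/xbar weakly constrained"
        )
    resid = float(np.sum((vel - model(pos, v0, a)) ** 2))
    return FitResult(
        params={"v0": v0, "q_over_xbar": a},
        stderr={"v0": float(perr[0]), "q_over_xbar": float(perr[1])},
        residual=resid, n_points=len(pos), converged=True, warnings=warnings,
    )


def _kymo_psi(kymo: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a kymograph table into (t, x, psi) and reference psi to x=0."""
    t = np.asarray(kymo.index, dtype=float)
    x = np.asarray(kymo.columns, dtype=float)
    psi = np.asarray(kymo, dtype=float)
    return t, x, psi - psi[:, :1]


def fit_phase_profile(
    kymo: pd.DataFrame,
    lp: LengthDynamicsParams,
    fixed: Dict[str, float],
    sc: Optional[SimulationConfig] = None,
    n_starts: int = 8,
    t0_candidates: Optional[Sequence[float]] = None,
    maxiter: int = 400,
) -> FitResult:
    """Estimate (k, sigma, q, t0) from a phase kymograph.

    ``kymo``: DataFrame with times [min] as index, positions [um] as
    columns, phase [rad] as values (any constant offset per frame is
    immaterial: the objective references every frame to x = 0).
    ``lp``: length dynamics, fitted separately beforehand (no joint fit).
    ``fixed``: dict with omega0, v0, epsilon held fixed during the fit.

    Objective: mean over the PSM mask (0 <= x <= xbar(t)) of
    1 - cos(psi_model - psi_data), minimised by Nelder-Mead from a coarse
    grid of ``n_starts`` starting points over (k, sigma, q); t0 is
    initialised by a coarse objective scan over ``t0_candidates``.
    """
    for key in ("omega0", "v0", "epsilon"):
        if key not in fixed:
            raise ParameterError(f"fixed must supply {key}")
    t_data, x_data, psi_data = _kymo_psi(kymo)
    if sc is None:
        sc = SimulationConfig(
            t_end=float(t_data[-1]), dx=5.0,
            L=float(
                np.ceil((profiles.psm_length(t_data, lp).max() + 100.0) / 50) * 50
            ),
            output_stride=1,
        )
    sc = dc_replace(sc, t_end=float(t_data[-1]))

    xbar_t = profiles.psm_length(t_data, lp)
    mask = x_data[None, :] <= xbar_t[:, None]
    n_points = int(mask.sum())

    def objective(theta) -> float:
        k, sigma, q, t0 = theta
        if not (0.05 < k < 25 and 0.01 < sigma <= 1.0 and 0.05 < q < 25):
            return 4.0  # outside the parameter domain; loss is bounded by 2
        if t0 >= t_data[0] - 1.0:
            return 4.0
        mp = ModelParameters.from_dict(
            dict(
                omega0=fixed["omega0"], k=k, sigma=sigma,
                v0=fixed["v0"], q=q,
                x0=lp.x0, x1=lp.x1, eta=lp.eta, tbar=lp.tbar,
                epsilon=fixed["epsilon"], t0=t0,
            )
        )
        pf = simulate(mp, sc)
        psi_m = np.empty_like(psi_data)
        for i, tt in enumerate(t_data):
            prof = pf.profile_at(tt)
            psi_m[i] = np.interp(x_data, pf.x_grid, prof) - prof[0]
        return float(np.mean(1.0 - np.cos(psi_m[mask] - psi_data[mask])))

    # coarse t0 initialisation: scan candidate start times at a mid-grid
    # profile-shape guess
    if t0_candidates is None:
        span = t_data[-1] - t_data[0]
        t0_candidates = t_data[0] - np.array([0.25, 0.75, 1.5]) * max(span, 100.0)
    probe = (2.0, 0.4, 1.8)
    t0_init = min(t0_candidates, key=lambda c: objective((*probe, c)))

    starts = list(
        itertools.product((1.2, 3.0), (0.2, 0.55), (1.0, 2.6))
    )[: max(n_starts, 1)]
    best = None
    for k0, s0, q0 in starts:
        res = minimize(
            objective,
            x0=np.array([k0, s0, q0, t0_init]),
            method="Nelder-Mead",
            options=dict(maxiter=maxiter, xatol=1e-3, fatol=1e-10),
        )
        if best is None or res.fun < best.fun:
            best = res
    k, sigma, q, t0 = map(float, best.x)
    return FitResult(
        params={"k": k, "sigma": sigma, "q": q, "t0": t0},
        residual=float(best.fun), n_points=n_points,
        converged=bool(best.success),
        warnings=[] if best.success else ["optimizer did not report convergence"],
    )
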