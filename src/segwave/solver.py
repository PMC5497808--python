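"""Finite-difference integration of the phase equation on a shortening tissue.

The phase field phi(x, t) obeys

    dphi/dt + v(x,t) dphi/dx = omega(x,t) + (epsilon/2) d^2phi/dx^2

on a fixed lab-frame grid [0, L] that contains the moving PSM; the anterior
end xbar(t) is an interior point of the grid.  Discretisation: method of
lines with first-order upwind advection (v >= 0 everywhere), centred
diffusion, explicit Euler stepping.  Boundary conditions: no-flux
(dphi/dx = 0) at the posterior tip x = 0; at the far end x = L the upwind
stencil needs no advection condition and the diffusion closes with zero
second derivative (outflow).  The frequency jump at xbar(t) is not
smoothed: each node is classified by xi = x/xbar(t) at the current time.

The solver is fully deterministic; identical configurations produce
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Union

import numpy as np

from . import profiles
from .params import LengthDynamicsParams, ModelParameters, SimulationConfig

__all__ = [
    "PhaseField",
    "simulate",
    "simulate_constant_length",
    "ConfigurationError",
    "NumericalError",
]


class ConfigurationError(ValueError):
    """Invalid or unstable solver configuration."""


class NumericalError(RuntimeError):
    """Non-finite state encountered during integration."""


@dataclass
class PhaseField:
    """A solved phase field phi on a (time x space) grid.

    Attributes
    ----------
    x_grid : ndarray, shape (nx,)
        Uniform lab-frame positions [um], x_grid[0] = 0.
    t_grid : ndarray, shape (nt,)
        Output times [min], strictly increasing.
    phi : ndarray, shape (nt, nx)
        Unwrapped cumulative phase [rad].
    xbar : ndarray, shape (nt,)
        PSM length at each output time [um].
    length_params : LengthDynamicsParams or None
        Analytic length dynamics when the run used them (None for
        constant-length runs; the anterior is then static).
    """

    x_grid: np.ndarray
    t_grid: np.ndarray
    phi: np.ndarray
    xbar: np.ndarray
    length_params: Optional[LengthDynamicsParams] = None

    @property
    def dx(self) -> float:
        return float(self.x_grid[1] - self.x_grid[0])

    def _t_index(self, t: float) -> int:
        t0, t1 = self.t_grid[0], self.t_grid[-1]
        slack = 1e-9 * max(1.0, abs(t0), abs(t1))
        if not (t0 - slack <= t <= t1 + slack):
            raise ValueError(f"t={t} outside simulated range [{t0}, {t1}]")
        j = int(np.searchsorted(self.t_grid, t, side="right") - 1)
        return min(max(j, 0), len(self.t_grid) - 1)

    def profile_at(self, t: float) -> np.ndarray:
        """Phase profile phi(., t), linearly interpolated in time."""
        j = self._t_index(t)
        if j == len(self.t_grid) - 1:
            return self.phi[j].copy()
        w = (t - self.t_grid[j]) / (self.t_grid[j + 1] - self.t_grid[j])
        return (1.0 - w) * self.phi[j] + w * self.phi[j + 1]

    def value(self, x, t: float):
        """phi(x, t) by bilinear interpolation (x may be an array)."""
        prof = self.profile_at(t)
        return np.interp(x, self.x_grid, prof)

    def xbar_at(self, t: float) -> float:
        """PSM length at time t (analytic when length_params are known)."""
        if self.length_params is not None:
            return float(profiles.psm_length(t, self.length_params))
        self._t_index(t)
        return float(np.interp(t, self.t_grid, self.xbar))

    def xbar_rate_at(self, t: float) -> float:
        """d(xbar)/dt at time t; analytic when length_params are known,
        zero for constant-length runs."""
        if self.length_params is not None:
            return float(profiles.psm_length_rate(t, self.length_params))
        return 0.0

    # -- serialization ----------------------------------------------------

    def to_text(self, path: Union[str, Path]) -> None:
        """Write a plain-text kymograph.

        Format: '#'-prefixed metadata lines (units, xbar trajectory,
        length parameters when available); then one header data row with a
        leading NaN cell followed by the x grid [um]; then one row per
        output time: t [min] followed by phi(x, t) [rad].  Values are
        printed with 17 significant digits and round-trip losslessly at
        double precision.
        """
        path = Path(path)
        with path.open("w") as fh:
            fh.write("# segwave phase-field kymograph\n")
            fh.write("# units: x um (first row), t min (first column), phi rad\n")
            if self.length_params is not None:
                lp = self.length_params
                fh.write(
                    f"# length_params: x0={lp.x0!r} x1={lp.x1!r} "
                    f"eta={lp.eta!r} tbar={lp.tbar!r}\n"
                )
            fh.write("# xbar_um: " + " ".join(f"{v:.17g}" for v in self.xbar) + "\n")
            header = np.concatenate([[np.nan], self.x_grid])
            body = np.column_stack([self.t_grid, self.phi])
            np.savetxt(fh, np.vstack([header, body]), fmt="%.17g")

    @classmethod
    def from_text(cls, path: Union[str, Path]) -> "PhaseField":
        path = Path(path)
        xbar = None
        length_params = None
        with path.open() as fh:
            rows = []
            for line in fh:
                if line.startswith("#"):
                    if line.startswith("# xbar_um:"):
                        xbar = np.array(
                            [float(v) for v in line.split(":", 1)[1].split()]
                        )
                    elif line.startswith("# length_params:"):
                        kv = dict(
                            item.split("=") for item in line.split(":", 1)[1].split()
                        )
                        length_params = LengthDynamicsParams(
                            x0=float(kv["x0"]),
                            x1=float(kv["x1"]),
                            eta=float(kv["eta"]),
                            tbar=float(kv["tbar"]),
                        )
                    continue
                rows.append([float(v) for v in line.split()])
        arr = np.array(rows)
        x_grid = arr[0, 1:]
        t_grid = arr[1:, 0]
        phi = arr[1:, 1:]
        if xbar is None:
            raise ValueError(f"{path} has no '# xbar_um:' metadata line")
        return cls(x_grid=x_grid, t_grid=t_grid, phi=phi, xbar=xbar,
                   length_params=length_params)

    def to_npz(self, path: Union[str, Path]) -> None:
        """Compact binary container (NumPy .npz)."""
        extra = {}
        if self.length_params is not None:
            lp = self.length_params
            extra["length_params"] = np.array([lp.x0, lp.x1, lp.eta, lp.tbar])
        np.savez_compressed(
            path, x_grid=self.x_grid, t_grid=self.t_grid, phi=self.phi,
            xbar=self.xbar, **extra,
        )

    @classmethod
    def from_npz(cls, path: Union[str, Path]) -> "PhaseField":
        with np.load(path) as data:
            length_params = None
            if "length_params" in data:
                x0, x1, eta, tbar = data["length_params"]
                length_params = LengthDynamicsParams(x0=x0, x1=x1, eta=eta, tbar=tbar)
            return cls(
                x_grid=data["x_grid"], t_grid=data["t_grid"], phi=data["phi"],
                xbar=data["xbar"], length_params=length_params,
            )


def _integrate(
    mp: ModelParameters,
    sc: SimulationConfig,
    xbar_fn: Callable[[float], float],
    t_start: float,
    phi0: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Explicit upwind/centred time stepping; returns (x, t, phi, xbar)."""
    nx = int(round(sc.L / sc.dx)) + 1
    x = np.arange(nx) * sc.dx
    t_end = float(sc.t_end)
    if t_end <= t_start:
        raise ConfigurationError(f"t_end={t_end} must exceed start time {t_start}")

    v0, q = mp.vel.v0, mp.vel.q
    omega0 = mp.freq.omega0
    eps = mp.epsilon

    if sc.dt == "auto":
        dt = sc.auto_dt(v0, eps)
    else:
        dt = float(sc.dt)
        if dt * (v0 / sc.dx + eps / sc.dx**2) > 1.0:
            raise ConfigurationError(
                f"explicit step dt={dt} violates the stability bound "
                f"dt*(v_max/dx + eps/dx^2) <= 1"
            )
    n_steps = int(np.ceil((t_end - t_start) / dt))
    dt = (t_end - t_start) / n_steps  # land exactly on t_end

    phi = np.zeros(nx) if phi0 is None else np.array(phi0, dtype=float)
    if phi.shape != (nx,):
        raise ConfigurationError("phi0 shape does not match the grid")

    stride = int(sc.output_stride)
    out_t = [t_start]
    out_phi = [phi.copy()]
    out_xbar = [float(xbar_fn(t_start))]

    inv_dx = 1.0 / sc.dx
    inv_dx2 = inv_dx * inv_dx
    grad = np.empty(nx)
    lap = np.empty(nx)
    for n in range(n_steps):
        t = t_start + n * dt
        xbar = float(xbar_fn(t))
        xi = x / xbar
        inside = xi <= 1.0
        omega = np.where(
            inside,
            omega0
            * (
                mp.freq.sigma
                + (1.0 - mp.freq.sigma)
                * (1.0 - np.exp(mp.freq.k * (xi - 1.0)))
                / (1.0 - np.exp(-mp.freq.k))
            ),
            0.0,
        )
        v = v0 * (1.0 - np.exp(-q * xi))

        # upwind gradient (v >= 0); v(0) = 0 so grad[0] is irrelevant
        grad[0] = 0.0
        np.subtract(phi[1:], phi[:-1], out=grad[1:])
        grad[1:] *= inv_dx

        # centred Laplacian; Neumann ghost at x=0, zero curvature at x=L
        lap[1:-1] = (phi[2:] - 2.0 * phi[1:-1] + phi[:-2]) * inv_dx2
        lap[0] = 2.0 * (phi[1] - phi[0]) * inv_dx2
        lap[-1] = 0.0
        if not sc.coupling_beyond_psm:
            lap[~inside] = 0.0

        phi = phi + dt * (omega - v * grad + 0.5 * eps * lap)

        step = n + 1
        if step % stride == 0 or step == n_steps:
            if not np.all(np.isfinite(phi)):
                raise NumericalError(
                    f"non-finite phase at t={t + dt:.3f} (dt={dt:.4g}, dx={sc.dx})"
                )
            tt = t_end if step == n_steps else t_start + step * dt
            out_t.append(tt)
            out_phi.append(phi.copy())
            out_xbar.append(float(xbar_fn(tt)))

    return x, np.array(out_t), np.array(out_phi), np.array(out_xbar)


def simulate(mp: ModelParameters, sc: SimulationConfig) -> PhaseField:
    """Integrate the phase equation with the tanh length dynamics.

    Starts from phi identically zero at t = mp.t0 and runs to sc.t_end.
    """
    lp = mp.length
    x, t, phi, xbar = _integrate(
        mp, sc, lambda tt: profiles.psm_length(tt, lp), t_start=mp.t0
    )
    return PhaseField(x_grid=x, t_grid=t, phi=phi, xbar=xbar, length_params=lp)


def simulate_constant_length(
    mp: ModelParameters,
    xbar0: float,
    sc: SimulationConfig,
    t_start: Optional[float] = None,
    phi0: Optional[np.ndarray] = None,
) -> PhaseField:
    """Integrate the phase equation with the PSM length frozen at xbar0.

    ``t_start`` defaults to mp.t0; ``phi0`` (default zero) allows
    continuation runs, e.g. for periodic-state relaxation.
    """
    if xbar0 <= 0:
        raise ConfigurationError("xbar0 must be > 0")
    start = mp.t0 if t_start is None else float(t_start)
    x, t, phi, xbar = _integrate(
        mp, sc, lambda tt: float(xbar0), t_start=start, phi0=phi0
    )
    return PhaseField(x_grid=x, t_grid=t, phi=phi, xbar=xbar, length_params=None)
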