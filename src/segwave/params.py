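"""Parameter containers for the segmentation-clock continuum model.

Units are fixed package-wide: lengths in micrometres (um), times in minutes
(min), phases in radians, angular frequencies in rad/min.  The default
parameter set describes the zebrafish presomitic mesoderm (PSM) at 23.5 C:
a posterior oscillation frequency ``omega0``, an exponential-shoulder
frequency profile with shape ``k`` and anterior fraction ``sigma``, a
saturating cell-velocity profile with amplitude ``v0`` and shape ``q``, a
tanh-shaped shortening of the PSM length, an oscillator coupling strength
``epsilon`` and the time ``t0`` at which the phase field starts from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "FrequencyProfileParams",
    "VelocityProfileParams",
    "LengthDynamicsParams",
    "ModelParameters",
    "SimulationConfig",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


def _finite(name: str, value: float) -> float:
    value = float(value)
    _require(math.isfinite(value), f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class FrequencyProfileParams:
    """Intrinsic-frequency profile omega(x) = omega0 * U(x / xbar(t)).

    Parameters
    ----------
    omega0 : float
        Maximum angular frequency at the posterior tip x = 0 [rad/min].
    k : float
        Dimensionless shape parameter; 1/k is the characteristic scale of
        the exponential shoulder of U.
    sigma : float
        Anterior frequency fraction, U(1) = sigma; oscillations arrest
        (U = 0) beyond the anterior end.
    """

    omega0: float = 0.15
    k: float = 2.07
    sigma: float = 0.34

    def __post_init__(self) -> None:
        _require(_finite("omega0", self.omega0) > 0, "omega0 must be > 0")
        _require(_finite("k", self.k) > 0, "k must be > 0")
        s = _finite("sigma", self.sigma)
        _require(0 < s <= 1, "sigma must lie in (0, 1]")


@dataclass(frozen=True)
class VelocityProfileParams:
    """Cell-velocity profile v(x) = v0 * (1 - exp(-q x / xbar(t))).

    ``v0`` is the saturation speed far from the posterior tip [um/min];
    ``q`` sets the decay scale xbar/q of the local growth rate dv/dx.
    """

    v0: float = 0.87
    q: float = 1.80

    def __post_init__(self) -> None:
        _require(_finite("v0", self.v0) >= 0, "v0 must be >= 0")
        _require(_finite("q", self.q) > 0, "q must be > 0")


@dataclass(frozen=True)
class LengthDynamicsParams:
    """Time-dependent PSM length xbar(t) = x0 + x1 * tanh(eta * (t - tbar)).

    ``eta`` is stored signed; a negative eta (as quantified in zebrafish)
    gives a PSM that shortens from x0 + x1 towards x0 - x1 around the
    inflection time tbar.
    """

    x0: float = 417.0
    x1: float = 202.0
    eta: float = -5.09e-3
    tbar: float = 192.0

    def __post_init__(self) -> None:
        _finite("eta", self.eta)
        _finite("tbar", self.tbar)
        x0 = _finite("x0", self.x0)
        x1 = _finite("x1", self.x1)
        _require(x0 > abs(x1) >= 0, "require x0 > |x1| so the length stays positive")


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the phase model.

    Bundles the frequency profile, velocity profile and length dynamics with
    the coupling strength ``epsilon`` [um^2/min] and the start time ``t0``
    [min] at which the phase field is initialised to zero.  The default
    values are the published zebrafish set.
    """

    freq: FrequencyProfileParams = field(default_factory=FrequencyProfileParams)
    vel: VelocityProfileParams = field(default_factory=VelocityProfileParams)
    length: LengthDynamicsParams = field(default_factory=LengthDynamicsParams)
    epsilon: float = 7.0
    t0: float = -256.0

    def __post_init__(self) -> None:
        _require(_finite("epsilon", self.epsilon) >= 0, "epsilon must be >= 0")
        _finite("t0", self.t0)

    @classmethod
    def zebrafish(cls) -> "ModelParameters":
        """The published zebrafish parameter set (defaults)."""
        return cls()

    # -- flat-dict / config-file round trip -------------------------------

    def to_dict(self) -> dict:
        """Flat dict with keys omega0, k, sigma, v0, q, x0, x1, eta, tbar,
        epsilon, t0."""
        out = {}
        out.update(asdict(self.freq))
        out.update(asdict(self.vel))
        out.update(asdict(self.length))
        out["epsilon"] = self.epsilon
        out["t0"] = self.t0
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        try:
            freq = FrequencyProfileParams(
                omega0=d.pop("omega0"), k=d.pop("k"), sigma=d.pop("sigma")
            )
            vel = VelocityProfileParams(v0=d.pop("v0"), q=d.pop("q"))
            length = LengthDynamicsParams(
                x0=d.pop("x0"), x1=d.pop("x1"), eta=d.pop("eta"), tbar=d.pop("tbar")
            )
            epsilon = d.pop("epsilon")
            t0 = d.pop("t0")
        except KeyError as exc:
            raise ParameterError(f"missing parameter key {exc}") from exc
        if d:
            raise ParameterError(f"unknown parameter keys: {sorted(d)}")
        return cls(freq=freq, vel=vel, length=length, epsilon=epsilon, t0=t0)

    def replace(self, **kwargs) -> "ModelParameters":
        """Return a copy with flat keys (omega0, k, ..., t0) replaced."""
        d = self.to_dict()
        for key, val in kwargs.items():
            if key not in d:
                raise ParameterError(f"unknown parameter {key!r}")
            d[key] = val
        return self.from_dict(d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        """Write the flat parameter dict as a YAML config.

        Keys: omega0 [rad/min], k, sigma [-], v0 [um/min], q [-],
        x0, x1 [um], eta [1/min], tbar [min], epsilon [um^2/min], t0 [min].
        """
        header = (
            "# segwave model parameters\n"
            "# units: omega0 rad/min; k, sigma, q dimensionless; v0 um/min;\n"
            "# x0, x1 um; eta 1/min; tbar, t0 min; epsilon um^2/min\n"
        )
        body = yaml.safe_dump(
            {k: float(v) for k, v in self.to_dict().items()}, sort_keys=True
        )
        Path(path).write_text(header + body)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ModelParameters":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ParameterError(f"config {path} does not contain a mapping")
        return cls.from_dict(data)


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical configuration of the phase-field integration.

    ``dx`` grid spacing [um], ``L`` lab-frame domain length [um] (should
    exceed the largest PSM length over the run), ``t_end`` stop time [min],
    ``dt`` explicit time step [min] or "auto" for the stability-bound value,
    ``output_stride`` keeps every n-th step in the output.
    ``coupling_beyond_psm`` applies the diffusive coupling also in the
    arrested tissue x > xbar(t) (on by default; the model equation is
    written on the whole domain).
    """

    t_end: float = 500.0
    dx: float = 1.0
    L: float = 900.0
    dt: Union[float, str] = "auto"
    output_stride: int = 4
    coupling_beyond_psm: bool = True

    def __post_init__(self) -> None:
        _require(_finite("dx", self.dx) > 0, "dx must be > 0")
        _require(_finite("L", self.L) > 0, "L must be > 0")
        _finite("t_end", self.t_end)
        if self.dt != "auto":
            _require(_finite("dt", self.dt) > 0, "dt must be > 0 or 'auto'")
        _require(int(self.output_stride) >= 1, "output_stride must be >= 1")

    def auto_dt(self, v_max: float, epsilon: float) -> float:
        """Stable explicit step 0.9 / (v_max/dx + epsilon/dx^2)."""
        denom = v_max / self.dx + epsilon / self.dx**2
        if denom <= 0:
            return 1.0
        return 0.9 / denom
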