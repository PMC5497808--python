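"""Synthetic data generation and plain-text table I/O.

Emulates the three kinds of quantified segmentation data from known model
parameters plus additive noise, so that every fitting routine can be
exercised without any experimental download:

* PSM-length time series (time vs length, like embryo-averaged length
  measurements),
* segment-boundary tracks (time vs position per formed boundary),
* phase kymographs (time x position grids of oscillation phase).

All generators are deterministic under a fixed seed (NumPy PCG64); noise
on phases is applied to the unwrapped phase and reported unwrapped —
wrapping is the consumer's concern and the circular fit objective is
insensitive to it.

Tables are comma-delimited UTF-8 text with a header row and '#'-prefixed
metadata lines carrying units and generator provenance (parameters and
seed), so fixtures are self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from . import profiles
from .observables import extract_segments, track_boundaries
from .params import ModelParameters, ParameterError, SimulationConfig
from .solver import simulate

__all__ = [
    "FixtureSpec",
    "make_length_series",
    "make_boundary_tracks",
    "make_phase_kymograph",
    "write_table",
    "read_table",
    "write_kymograph",
    "read_kymograph",
]


@dataclass
class FixtureSpec:
    """Recipe for one synthetic dataset.

    ``generator`` is one of length_series | boundary_tracks |
    phase_kymograph.  ``noise_sd`` is in um for lengths and positions and
    in rad for phases; a seed is mandatory whenever noise_sd > 0.
    ``t_min``/``t_max`` bound the sampled times [min] (t_min is clipped to
    the simulation start for simulated generators), ``n_points`` sets the
    length-series size, ``dt_sample``/``dx_sample`` the kymograph sampling
    steps, and ``sim`` the solver configuration for the simulated kinds.
    """

    generator: str
    params: ModelParameters = field(default_factory=ModelParameters.zebrafish)
    noise_sd: float = 0.0
    seed: Optional[int] = None
    t_min: float = -250.0
    t_max: float = 450.0
    n_points: int = 20
    dt_sample: float = 10.0
    dx_sample: float = 10.0
    track_duration: float = 150.0
    sim: Optional[SimulationConfig] = None

    def __post_init__(self) -> None:
        if self.generator not in (
            "length_series", "boundary_tracks", "phase_kymograph"
        ):
            raise ParameterError(f"unknown generator {self.generator!r}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.noise_sd > 0 and self.seed is None:
            raise ParameterError("a seed is mandatory for nonzero noise")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def sim_config(self) -> SimulationConfig:
        if self.sim is not None:
            return self.sim
        lmax = profiles.psm_length(
            np.linspace(self.params.t0, self.t_max, 200), self.params.length
        ).max()
        return SimulationConfig(
            t_end=float(self.t_max),
            dx=2.0,
            L=float(np.ceil((lmax + 250.0) / 50.0) * 50.0),
            output_stride=8,
        )

    def provenance(self) -> Dict[str, str]:
        meta = {f"param_{k}": repr(v) for k, v in self.params.to_dict().items()}
        meta["generator"] = self.generator
        meta["noise_sd"] = repr(self.noise_sd)
        meta["seed"] = repr(self.seed)
        return meta


def make_length_series(spec: FixtureSpec) -> pd.DataFrame:
    """PSM-length series: tanh law at n_points times plus Gaussian noise.

    Columns: t_min, length_um.
    """
    if spec.n_points < 2:
        raise ParameterError("need n_points >= 2")
    t = np.linspace(spec.t_min, spec.t_max, spec.n_points)
    y = profiles.psm_length(t, spec.params.length)
    if spec.noise_sd > 0:
        y = y + spec.rng().normal(0.0, spec.noise_sd, size=y.shape)
    return pd.DataFrame({"t_min": t, "length_um": np.asarray(y)})


def make_boundary_tracks(spec: FixtureSpec) -> List[pd.DataFrame]:
    """Boundary tracks: simulate, form segments, advect their boundaries.

    Returns one table (t_min, x_um, segment) per formed boundary, with
    i.i.d. Gaussian positional noise added per sample point.
    """
    sc = spec.sim_config()
    pf = simulate(spec.params, sc)
    segs = extract_segments(pf)
    if len(segs) < 2:
        raise ParameterError("simulation too short: fewer than 2 segments formed")
    tracks = track_boundaries(pf, segs, spec.params)
    rng = spec.rng()
    out = []
    for tr in tracks:
        # boundaries are followed over a finite imaging window; long-time
        # averaging over the saturating flow would blur the profile shape
        t_form = float(tr["t_min"].iloc[0])
        tr = tr[tr["t_min"] <= t_form + spec.track_duration].copy()
        # thin to ~the kymograph frame rate to emulate tracked points
        step = max(1, int(round(spec.dt_sample / max(np.median(np.diff(tr["t_min"])), 1e-9))))
        tr = tr.iloc[::step].reset_index(drop=True)
        if spec.noise_sd > 0:
            tr["x_um"] = tr["x_um"] + rng.normal(0.0, spec.noise_sd, size=len(tr))
        out.append(tr)
    return out


def make_phase_kymograph(spec: FixtureSpec) -> pd.DataFrame:
    """Phase kymograph: simulate, reference phase to the posterior,
    sample on a (dt_sample x dx_sample) grid, add phase noise.

    Returns a DataFrame with times [min] as index (name t_min), positions
    [um] as columns, unwrapped relative phase psi [rad] as values;
    psi(0, t) = 0 in every frame (noise included, the posterior column is
    the reference).
    """
    sc = spec.sim_config()
    pf = simulate(spec.params, sc)
    t0 = max(spec.t_min, float(pf.t_grid[0]))
    t_sample = np.arange(t0, spec.t_max + 1e-9, spec.dt_sample)
    x_sample = np.arange(0.0, sc.L + 1e-9, spec.dx_sample)
    psi = np.empty((len(t_sample), len(x_sample)))
    for i, tt in enumerate(t_sample):
        prof = pf.profile_at(tt)
        psi[i] = np.interp(x_sample, pf.x_grid, prof) - prof[0]
    if spec.noise_sd > 0:
        noise = spec.rng().normal(0.0, spec.noise_sd, size=psi.shape)
        noise[:, 0] = 0.0  # the posterior column is the phase reference
        psi = psi + noise
    df = pd.DataFrame(psi, index=t_sample, columns=x_sample)
    df.index.name = "t_min"
    return df


# -- plain-text table I/O -------------------------------------------------


def _fmt_float(v: float) -> str:
    """Shortest representation that round-trips at double precision."""
    return repr(float(v))


def _write_meta(fh, meta: Optional[Dict[str, str]]) -> None:
    for key, val in (meta or {}).items():
        fh.write(f"# {key}: {val}\n")


def _read_meta_lines(path: Path) -> tuple[Dict[str, str], int]:
    meta: Dict[str, str] = {}
    n = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
    return meta, n


def write_table(
    df: pd.DataFrame, path: Union[str, Path], meta: Optional[Dict[str, str]] = None
) -> None:
    """Comma-delimited table with '#' metadata lines and a header row."""
    path = Path(path)
    with path.open("w") as fh:
        _write_meta(fh, meta)
        df.to_csv(fh, index=False, float_format=_fmt_float)


def read_table(path: Union[str, Path]) -> tuple[pd.DataFrame, Dict[str, str]]:
    path = Path(path)
    meta, n = _read_meta_lines(path)
    df = pd.read_csv(path, skiprows=n, float_precision="round_trip")
    return df, meta


def write_kymograph(
    df: pd.DataFrame, path: Union[str, Path], meta: Optional[Dict[str, str]] = None
) -> None:
    """Kymograph table: rows = times (index column t_min, increasing),
    columns = positions [um] (posterior x = 0 leftmost), cells = phase
    [rad], preceded by '#' metadata lines."""
    path = Path(path)
    with path.open("w") as fh:
        _write_meta(fh, meta)
        df.to_csv(fh, index=True, index_label="t_min", float_format=_fmt_float)


def read_kymograph(path: Union[str, Path]) -> tuple[pd.DataFrame, Dict[str, str]]:
    path = Path(path)
    meta, n = _read_meta_lines(path)
    df = pd.read_csv(path, skiprows=n, index_col=0,
                     float_precision="round_trip")
    df.columns = df.columns.astype(float)
    df.index = df.index.astype(float)
    df.index.name = "t_min"
    return df, meta
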