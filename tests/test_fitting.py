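"""Parameter recovery: length dynamics, boundary velocities, phase profile."""

import numpy as np
import pandas as pd
import pytest

import segwave as sw
from segwave import fitting, fixtures
from segwave.params import ParameterError, SimulationConfig


COARSE_SIM = SimulationConfig(t_end=250.0, dx=10.0, L=900.0, output_stride=1)


def coarse_kymo_spec(mp, noise_sd=0.0, seed=None):
    return fixtures.FixtureSpec(
        "phase_kymograph", params=mp, noise_sd=noise_sd, seed=seed,
        t_min=-150.0, t_max=250.0, dt_sample=25.0, dx_sample=25.0,
        sim=COARSE_SIM,
    )


def fit_coarse(kymo, mp, **kwargs):
    return fitting.fit_phase_profile(
        kymo, mp.length,
        fixed={"omega0": mp.freq.omega0, "v0": mp.vel.v0, "epsilon": mp.epsilon},
        sc=COARSE_SIM, **kwargs,
    )


class TestLengthDynamicsFit:
    def test_noiseless_exact_recovery(self, zebrafish):
        df = fixtures.make_length_series(
            fixtures.FixtureSpec("length_series", params=zebrafish)
        )
        res = fitting.fit_length_dynamics(df)
        assert res.converged
        assert res.params["x0"] == pytest.approx(417.0, rel=1e-6)
        assert res.params["x1"] == pytest.approx(202.0, rel=1e-6)
        assert res.params["eta"] == pytest.approx(-5.09e-3, rel=1e-6)
        assert res.params["tbar"] == pytest.approx(192.0, abs=1e-3)
        # recovered peak shortening rate matches the printed observer speed
        assert abs(res.params["x1"] * res.params["eta"]) == pytest.approx(
            1.03, abs=0.01
        )

    def test_sign_of_eta_preserved(self, zebrafish):
        df = fixtures.make_length_series(
            fixtures.FixtureSpec(
                "length_series", params=zebrafish, noise_sd=5.0, seed=42
            )
        )
        res = fitting.fit_length_dynamics(df)
        assert res.params["eta"] < 0
        assert res.params["x1"] > 0

    def test_noisy_recovery_medians(self, zebrafish):
        # Gaussian noise sd 10 um on 20 points; medians over 100 seeds
        errs = {"x0": [], "x1": [], "eta": []}
        for seed in range(100):
            df = fixtures.make_length_series(
                fixtures.FixtureSpec(
                    "length_series", params=zebrafish, noise_sd=10.0, seed=seed
                )
            )
            res = fitting.fit_length_dynamics(df)
            errs["x0"].append(abs(res.params["x0"] / 417.0 - 1))
            errs["x1"].append(abs(res.params["x1"] / 202.0 - 1))
            errs["eta"].append(abs(res.params["eta"] / -5.09e-3 - 1))
        assert np.median(errs["x0"]) < 0.05
        assert np.median(errs["x1"]) < 0.05
        assert np.median(errs["eta"]) < 0.15

    def test_constant_series_flat_fit(self):
        df = pd.DataFrame(
            {"t_min": np.linspace(0, 100, 10), "length_um": np.full(10, 300.0)}
        )
        res = fitting.fit_length_dynamics(df)
        assert res.params["eta"] == pytest.approx(0.0, abs=1e-6)
        assert any("flat" in w for w in res.warnings)

    def test_too_few_points(self):
        df = pd.DataFrame({"t_min": [0.0, 1.0, 2.0], "length_um": [1, 2, 3.0]})
        with pytest.raises(ParameterError):
            fitting.fit_length_dynamics(df)


@pytest.fixture(scope="module")
def const_length_params():
    # frozen PSM length makes q/xbar a well-defined single constant
    return sw.ModelParameters.from_dict(
        dict(omega0=0.15, k=2.07, sigma=0.34, v0=0.87, q=1.80,
             x0=417.0, x1=0.0, eta=0.0, tbar=0.0, epsilon=7.0, t0=-256.0)
    )


class TestBoundaryVelocityFit:
    def test_noiseless_round_trip(self, const_length_params):
        mp = const_length_params
        spec = fixtures.FixtureSpec(
            "boundary_tracks", params=mp, t_min=-250.0, t_max=450.0
        )
        tracks = fixtures.make_boundary_tracks(spec)
        res = fitting.fit_boundary_velocities(tracks)
        assert res.params["v0"] == pytest.approx(0.87, rel=0.05)
        assert res.params["q_over_xbar"] == pytest.approx(1.80 / 417.0, rel=0.05)

    def test_stationary_tracks_give_zero_velocity(self):
        tracks = [
            pd.DataFrame(
                {"t_min": np.arange(10.0), "x_um": np.full(10, 50.0 * i),
                 "segment": i}
            )
            for i in range(1, 4)
        ]
        res = fitting.fit_boundary_velocities(tracks)
        assert res.params["v0"] == pytest.approx(0.0, abs=1e-9)

    def test_far_field_only_flags_weak_constraint(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 100, 12)
        tracks = []
        for x_start in (2000.0, 2500.0, 3000.0):
            x = x_start + 0.87 * t + rng.normal(0, 0.01, len(t))
            tracks.append(pd.DataFrame({"t_min": t, "x_um": x, "segment": 1}))
        res = fitting.fit_boundary_velocities(tracks)
        assert res.params["v0"] == pytest.approx(0.87, rel=0.05)
        assert any("weakly constrained" in w for w in res.warnings)

    def test_single_point_tracks_excluded(self):
        good = pd.DataFrame(
            {"t_min": np.arange(5.0), "x_um": 10 + 0.5 * np.arange(5.0),
             "segment": 1}
        )
        bad = pd.DataFrame({"t_min": [0.0], "x_um": [3.0], "segment": 2})
        with pytest.raises(ParameterError):
            fitting.fit_boundary_velocities([good, bad])


class TestPhaseProfileFit:
    def test_noiseless_inverse_crime_recovery(self, zebrafish):
        kymo = fixtures.make_phase_kymograph(coarse_kymo_spec(zebrafish))
        res = fit_coarse(kymo, zebrafish, n_starts=4)
        assert res.params["k"] == pytest.approx(2.07, rel=0.02)
        assert res.params["sigma"] == pytest.approx(0.34, rel=0.02)
        assert res.params["q"] == pytest.approx(1.80, rel=0.02)
        assert res.params["t0"] == pytest.approx(-256.0, abs=5.0)

    def test_objective_invariant_to_constant_phase_offset(self, zebrafish):
        kymo = fixtures.make_phase_kymograph(coarse_kymo_spec(zebrafish))
        res_a = fit_coarse(kymo, zebrafish, n_starts=1, maxiter=40)
        res_b = fit_coarse(kymo + 1.234, zebrafish, n_starts=1, maxiter=40)
        assert res_a.residual == pytest.approx(res_b.residual, abs=1e-12)
        assert res_a.params == res_b.params

    def test_noisy_recovery_median(self, zebrafish):
        # wrapped-Gaussian phase noise, sd 0.3 rad; medians over 20 seeds
        errs = []
        for seed in range(20):
            kymo = fixtures.make_phase_kymograph(
                coarse_kymo_spec(zebrafish, noise_sd=0.3, seed=seed)
            )
            res = fit_coarse(kymo, zebrafish, n_starts=2, maxiter=250)
            errs.append(
                [
                    abs(res.params["k"] / 2.07 - 1),
                    abs(res.params["sigma"] / 0.34 - 1),
                    abs(res.params["q"] / 1.80 - 1),
                ]
            )
        med = np.median(np.array(errs), axis=0)
        assert np.all(med < 0.10)

    def test_error_shrinks_with_noise_level(self, zebrafish):
        # median recovery error decreases as phase noise sd decreases
        med_err = []
        for sd in (0.5, 0.3, 0.1, 0.0):
            errs = []
            for seed in range(8):
                kymo = fixtures.make_phase_kymograph(
                    coarse_kymo_spec(
                        zebrafish, noise_sd=sd, seed=None if sd == 0 else seed
                    )
                )
                res = fit_coarse(kymo, zebrafish, n_starts=2, maxiter=300)
                errs.append(
                    abs(res.params["k"] / 2.07 - 1)
                    + abs(res.params["sigma"] / 0.34 - 1)
                    + abs(res.params["q"] / 1.80 - 1)
                )
            med_err.append(np.median(errs))
        assert med_err[0] > med_err[-1]
        assert np.all(np.diff(med_err) <= 1e-12)

    def test_missing_fixed_parameter_rejected(self, zebrafish):
        kymo = fixtures.make_phase_kymograph(coarse_kymo_spec(zebrafish))
        with pytest.raises(ParameterError):
            fitting.fit_phase_profile(
                kymo, zebrafish.length, fixed={"omega0": 0.15}
            )
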