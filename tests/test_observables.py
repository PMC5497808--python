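"""Observable extraction: wave counts, segments, frequency decomposition."""

import numpy as np
import pytest

import segwave as sw
from segwave import observables
from segwave.observables import TWO_PI


def plane_wave_field(omega=0.2, lam=40.0, xbar0=300.0):
    """Synthetic phase field phi = omega t + 2 pi (xbar0 - x)/lam: waves of
    wavelength lam; the posterior leads the anterior by 2 pi xbar0/lam."""
    x = np.arange(0.0, 400.0 + 1e-9, 1.0)
    t = np.linspace(0.0, 100.0, 201)
    phi = omega * t[:, None] + TWO_PI * (0.0 - x[None, :]) / lam
    return sw.PhaseField(
        x_grid=x, t_grid=t, phi=phi, xbar=np.full_like(t, xbar0)
    )


class TestCountsOnConstructedFields:
    def test_uniform_field_has_no_waves(self):
        pf = plane_wave_field(lam=1e12)
        assert observables.wave_count(pf, 50.0) == pytest.approx(0.0, abs=1e-9)

    def test_plane_wave_counts_and_length(self):
        lam, xbar0 = 40.0, 300.0
        pf = plane_wave_field(lam=lam, xbar0=xbar0)
        assert observables.wave_count(pf, 50.0) == pytest.approx(xbar0 / lam)
        s_grad = observables.segment_length_at_anterior(pf, 50.0, "gradient")
        s_exact = observables.segment_length_at_anterior(pf, 50.0, "exact")
        assert s_grad == pytest.approx(lam, rel=1e-9)
        assert s_exact == pytest.approx(lam, rel=1e-6)

    def test_plane_wave_phase_velocity(self):
        omega, lam = 0.2, 40.0
        pf = plane_wave_field(omega=omega, lam=lam)
        v = observables.phase_velocity_field(pf)
        inner = v[3:-3, 3:-3]
        np.testing.assert_allclose(
            inner.compressed(), omega * lam / TWO_PI, rtol=1e-6
        )

    def test_relative_phase_reference(self, table1_field):
        psi = observables.relative_phase_profile(table1_field)
        assert np.all(psi[:, 0] == 0.0)

    def test_wave_count_is_minus_anterior_psi(self, table1_field):
        pf = table1_field
        for t in (-100.0, 50.0, 300.0):
            xbar = pf.xbar_at(t)
            psi_a = pf.value(xbar, t) - pf.value(0.0, t)
            assert observables.wave_count(pf, t) == pytest.approx(
                -psi_a / TWO_PI
            )

    def test_out_of_range_time_raises(self, table1_field):
        with pytest.raises(ValueError):
            observables.wave_count(table1_field, 1e5)


class TestTableOneRun:
    def test_segment_event_nearest_time_zero_is_seventh(self, table1_segments):
        df = table1_segments.to_dataframe()
        i = df["formation_time_min"].abs().idxmin()
        assert df.loc[i, "index"] == 7

    def test_formation_times_strictly_increasing(self, table1_segments):
        t = [r.formation_time for r in table1_segments]
        assert np.all(np.diff(t) > 0)

    def test_segment_lengths_have_interior_maximum(self, table1_segments):
        # largest segments around the 12-segment mark: the staged-range
        # length curve rises and then falls
        df = table1_segments.to_dataframe()
        staged = df[df["index"] >= 7].reset_index(drop=True)
        s = staged["S_um"].to_numpy()
        i_max = int(np.argmax(s))
        assert 0 < i_max < len(s) - 1
        assert abs(int(staged.loc[i_max, "index"]) - 12) <= 1

    def test_wave_count_decreases_during_segmentation(self, table1_obs):
        obs = table1_obs
        k_early = obs.K[np.argmin(np.abs(obs.t - 0.0))]
        k_late = obs.K[np.argmin(np.abs(obs.t - 450.0))]
        assert k_late < k_early

    def test_segmentation_rate_is_anterior_frequency(self, table1_obs):
        obs = table1_obs
        dNdt = np.gradient(obs.N, obs.t)
        sel = slice(5, -5)
        np.testing.assert_allclose(
            dNdt[sel], obs.Omega_A[sel] / TWO_PI, atol=2e-4
        )

    def test_decomposition_identity(self, table1_obs):
        obs = table1_obs
        resid = np.abs(obs.Omega_A - (obs.Omega_P + obs.Omega_D + obs.Omega_W))
        assert resid.max() < 1e-3

    def test_doppler_positive_wavelength_negative(self, table1_obs):
        obs = table1_obs
        sel = (obs.t >= 150.0) & (obs.t <= 300.0)
        d = obs.Omega_D[sel].mean()
        w = obs.Omega_W[sel].mean()
        assert d > 0
        assert w < 0
        assert abs(d) > abs(w)

    def test_anterior_faster_than_posterior_while_shortening(self, table1_obs):
        obs = table1_obs
        sel = (obs.t >= 150.0) & (obs.t <= 300.0)
        assert obs.Omega_A[sel].mean() > obs.Omega_P[sel].mean()

    def test_anterior_wavelength_shrinks_over_time(self, table1_field):
        # peaks of psi move closer together as the PSM shortens
        pf = table1_field
        s_early = observables.segment_length_at_anterior(pf, 100.0)
        s_late = observables.segment_length_at_anterior(pf, 450.0)
        assert s_late < s_early


class TestFrequencyRatioApprox:
    def test_no_shortening_is_unshifted(self, zebrafish):
        assert observables.anterior_frequency_approx(zebrafish, 0.0) == 1.0

    def test_uniform_profile_cancels_exactly(self, zebrafish):
        # Doppler factor and dynamic-wavelength factor cancel when the
        # frequency profile is flat (closed-form Delta)
        flat = zebrafish.replace(sigma=1.0)
        ratio = observables.anterior_frequency_approx(flat, 1.03)
        assert ratio == pytest.approx(1.0, abs=1e-12)

    def test_zebrafish_profile_speeds_up_segmentation(self, zebrafish):
        ratio = observables.anterior_frequency_approx(zebrafish, 1.03)
        assert ratio == pytest.approx(1.1782941918959753, rel=1e-9)
        assert ratio > 1.0

    def test_matches_simulated_ratio_during_linear_shortening(
        self, zebrafish, table1_obs
    ):
        obs = table1_obs
        sel = (obs.t >= 150.0) & (obs.t <= 300.0)
        simulated = obs.Omega_A[sel].mean() / obs.Omega_P[sel].mean()
        predicted = observables.anterior_frequency_approx(zebrafish, 1.03)
        assert simulated == pytest.approx(predicted, rel=0.05)


class TestSegmentsAndBoundaries:
    def test_uniform_oscillation_equally_spaced_formations(self):
        # fixed length, sigma=1, no flow: every node oscillates at omega0
        # and segments form every 2 pi / omega0 minutes
        mp = sw.ModelParameters.from_dict(
            dict(omega0=0.15, k=2.07, sigma=1.0, v0=0.0, q=1.8,
                 x0=300.0, x1=0.0, eta=0.0, tbar=0.0, epsilon=0.0, t0=0.0)
        )
        sc = sw.SimulationConfig(t_end=200.0, dx=2.0, L=400.0, output_stride=4)
        pf = sw.simulate_constant_length(mp, 300.0, sc)
        segs = sw.extract_segments(pf, apply_staging=False)
        times = [r.formation_time for r in segs]
        np.testing.assert_allclose(
            np.diff(times), TWO_PI / 0.15, rtol=1e-3
        )

    def test_stationary_boundaries_without_flow(self):
        mp = sw.ModelParameters.from_dict(
            dict(omega0=0.15, k=2.07, sigma=1.0, v0=0.0, q=1.8,
                 x0=300.0, x1=0.0, eta=0.0, tbar=0.0, epsilon=0.0, t0=0.0)
        )
        sc = sw.SimulationConfig(t_end=150.0, dx=2.0, L=400.0, output_stride=4)
        pf = sw.simulate_constant_length(mp, 300.0, sc)
        segs = sw.extract_segments(pf, apply_staging=False)
        tracks = sw.track_boundaries(pf, segs, mp)
        for tr in tracks:
            assert np.ptp(tr["x_um"]) == pytest.approx(0.0, abs=1e-9)

    def test_far_field_boundary_speed_approaches_v0(self, zebrafish):
        # a boundary far beyond the PSM (x >> xbar/q) rides the saturated
        # flow at v0
        rec = sw.SegmentRecord(
            index=1, formation_time=300.0, length=40.0, anterior_position=350.0
        )
        x = np.arange(0.0, 2000.0, 2.0)
        t = np.linspace(250.0, 650.0, 201)
        pf = sw.PhaseField(
            x_grid=x, t_grid=t, phi=np.zeros((len(t), len(x))),
            xbar=np.full_like(t, 300.0), length_params=zebrafish.length,
        )
        (tr,) = sw.track_boundaries(pf, [rec], zebrafish)
        late = tr[tr["t_min"] > 500.0]
        v_late = np.polyfit(late["t_min"], late["x_um"], 1)[0]
        assert v_late == pytest.approx(zebrafish.vel.v0, rel=0.02)

    def test_boundary_summary_follows_velocity_profile(self, table1_field,
                                                       table1_segments,
                                                       zebrafish):
        tracks = sw.track_boundaries(table1_field, table1_segments, zebrafish)
        summary = sw.summarize_boundary_tracks(tracks)
        assert len(summary) == len(tracks)
        # mean velocity rises with mean position toward (but below) v0;
        # the moving xbar(t) keeps the relation from being exactly
        # monotonic across boundaries formed at different epochs
        s = summary.sort_values("mean_position_um")
        v = s["mean_velocity_um_min"].to_numpy()
        assert np.all(v < zebrafish.vel.v0)
        assert v[0] == min(v)
        rho = np.corrcoef(s["mean_position_um"], v)[0, 1]
        assert rho > 0.7

    def test_observable_series_export(self, table1_obs, tmp_path):
        path = tmp_path / "obs.csv"
        table1_obs.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        assert list(df.columns) == [
            "t_min", "K", "N", "S_um",
            "omegaA_rad_min", "omegaP_rad_min", "omegaD_rad_min",
            "omegaW_rad_min",
        ]
        assert len(df) == len(table1_obs.t)
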