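"""Trajectory operators against scripted and generated ground truth."""

import numpy as np
import pytest

from twistpore import synthetic as syn, trajectory_analysis as ta
from twistpore.errors import AnalysisError
from twistpore.trajectory import Trajectory


def _simple_traj(ion_positions, waters=None, box=(20.0, 20.0, 30.0), dt=1.0):
    """Frames from explicit ion (and optional water O) positions."""
    ion_positions = np.asarray(ion_positions, dtype=float)
    n_frames, n_ions = ion_positions.shape[:2]
    n_w = 0 if waters is None else np.asarray(waters).shape[1]
    coords = np.zeros((n_frames, n_ions + n_w, 3))
    coords[:, :n_ions] = ion_positions
    roles = {i: "ion:K" for i in range(n_ions)}
    if waters is not None:
        coords[:, n_ions:] = waters
        for j in range(n_w):
            roles[n_ions + j] = "waterO"
    return Trajectory(
        timestep_ps=dt,
        box=box,
        coords=coords,
        roles=roles,
        layer_z1=10.0,
        layer_z2=13.35,
    )


class TestOccupancy:
    def test_ion_on_plane_occupies_p1(self):
        traj = _simple_traj([[[0.0, 0.0, 10.0]]])
        occ = ta.assign_site_occupancy(traj)
        assert occ[0]["P1"] == 0 and occ[0]["P2"] is None

    def test_dual_occupancy_stage_iv(self):
        traj = _simple_traj([[[0.0, 0.0, 10.0], [0.1, 0.0, 13.35]]])
        occ = ta.assign_site_occupancy(traj)
        assert occ[0]["P1"] == 0 and occ[0]["P2"] == 1

    def test_radially_distant_ion_unbound(self):
        traj = _simple_traj([[[5.0, 0.0, 10.0]]])
        occ = ta.assign_site_occupancy(traj, radial_cutoff=3.0)
        assert occ[0]["P1"] is None

    def test_nearest_ion_wins(self):
        traj = _simple_traj([[[0.0, 0.0, 10.6], [0.0, 0.5, 10.1]]])
        occ = ta.assign_site_occupancy(traj)
        assert occ[0]["P1"] == 1


class TestPermeation:
    @pytest.mark.parametrize("n_events", [1, 7, 25])
    def test_scripted_event_count_recovered(self, n_events):
        traj = syn.gen_permeation_trajectory(n_events, seed=n_events)
        events = ta.detect_permeation_events(traj)
        assert len(events) == n_events
        assert all(e.direction == +1 for e in events)

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_count_with_pbc_wrapping(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 12))
        traj = syn.gen_permeation_trajectory(
            n, seed=seed, wrap=bool(rng.integers(0, 2))
        )
        assert len(ta.detect_permeation_events(traj)) == n

    def test_shuttle_retreat_counts_nothing(self):
        z = [3.0, 6.0, 10.0, 10.0, 6.0, 3.0]  # enters P1 and retreats
        traj = _simple_traj([[[0.0, 0.0, zz]] for zz in z])
        assert ta.detect_permeation_events(traj) == []

    def test_stage_iv_dwell_dominates(self):
        traj = syn.gen_permeation_trajectory(10, seed=0)
        assert ta.dual_occupancy_fraction(traj) >= 0.65


class TestHydration:
    def test_exact_count_at_cutoff(self):
        waters = np.zeros((1, 4, 3))
        for j in range(4):
            waters[0, j] = [10.0 + 3.4 * np.cos(j), 10.0 + 3.4 * np.sin(j), 10.0]
        traj = _simple_traj([[[10.0, 10.0, 10.0]]], waters=waters)
        counts, mean = ta.hydration_number(traj, 0, cutoff=3.5)
        assert counts[0] == 4 and mean == 4.0

    @pytest.mark.parametrize("shell", [7.3, 3.1])
    def test_shell_generator_mean_recovered(self, shell):
        traj = syn.gen_hydration_trajectory(mean_shell=shell, n_frames=300, seed=2)
        counts, mean = ta.hydration_number(traj, 0)
        realized = traj.metadata["realized_mean"]
        assert mean == pytest.approx(realized, abs=1e-9)
        assert mean == pytest.approx(shell, abs=3 * np.sqrt(shell / 300))

    def test_count_nonincreasing_in_cutoff(self):
        traj = syn.gen_hydration_trajectory(mean_shell=6.0, n_frames=50, seed=3)
        means = [ta.hydration_number(traj, 0, cutoff=c)[1] for c in (3.5, 3.0, 2.8)]
        assert means[0] >= means[1] >= means[2]

    def test_minimum_image_distances(self):
        # water across the periodic z boundary is a true neighbour
        waters = np.array([[[0.0, 0.0, 29.5]]])
        traj = _simple_traj([[[0.0, 0.0, 0.5]]], waters=waters)
        counts, _ = ta.hydration_number(traj, 0, cutoff=3.5)
        assert counts[0] == 1


class TestTriplets:
    def test_scripted_single_episode(self):
        traj = syn.gen_triplet_trajectory(
            fraction_n1=1.0,
            lifetime_n1=300.0,
            n_episodes=1,
            timestep=1.0,
            seed=4,
            flip_rate_n1=0.0,
            flip_rate_n2=0.0,
            deterministic_lifetimes=True,
        )
        events, summary = ta.classify_triplets(traj)
        assert len(events) == 1
        assert events[0].n_waters == 1
        assert events[0].lifetime == pytest.approx(300.0, abs=2.0)
        assert summary["fraction_n1"] == 1.0

    def test_fractions_match_generator_truth(self):
        traj = syn.gen_triplet_trajectory(
            n_episodes=150, timestep=2.0, seed=5, flip_rate_n1=0.0, flip_rate_n2=0.0
        )
        _events, summary = ta.classify_triplets(traj)
        truth = traj.metadata["episodes"]
        frac_true = sum(e["n_waters"] == 1 for e in truth) / len(truth)
        assert summary["n_episodes"] == len(truth)
        assert summary["fraction_n1"] == pytest.approx(frac_true, abs=1e-9)

    def test_zero_bridging_water_excluded_and_flagged(self):
        # dual-occupied ions but all waters far from the interlayer band
        ions = np.tile([[0.0, 0.0, 10.0], [0.0, 0.0, 13.35]], (30, 1, 1))
        waters = np.tile([[8.0, 8.0, 2.0]], (30, 1, 1))
        traj = _simple_traj(ions, waters=waters)
        events, summary = ta.classify_triplets(traj)
        assert events == []
        assert summary["n_excluded"] == 1


class TestOrientation:
    def _triplet_with_theta(self, theta_deg, n_frames=30):
        traj = syn.gen_triplet_trajectory(
            fraction_n1=1.0,
            lifetime_n1=float(n_frames),
            n_episodes=1,
            timestep=1.0,
            seed=6,
            flip_rate_n1=0.0,
            flip_rate_n2=0.0,
            deterministic_lifetimes=True,
            angles_n1=(theta_deg, theta_deg),
            theta_sd=0.0,
            ion_jitter=0.0,
        )
        events, _ = ta.classify_triplets(traj)
        return traj, events[0]

    @pytest.mark.parametrize("theta", [0.0, 90.0, 140.0])
    def test_prescribed_dipole_angle_recovered(self, theta):
        traj, ev = self._triplet_with_theta(theta)
        series, _ = ta.dipole_orientation(traj, ev)
        finite = np.asarray(series.theta)
        finite = finite[np.isfinite(finite)]
        assert finite.size > 0
        np.testing.assert_allclose(finite, theta, atol=1e-6)

    def test_rotation_translation_invariance(self):
        traj, ev = self._triplet_with_theta(40.0)
        series, _ = ta.dipole_orientation(traj, ev)
        # rigid rotation + translation of every frame
        ang = 0.7
        rot = np.array(
            [
                [np.cos(ang), 0, np.sin(ang)],
                [0, 1, 0],
                [-np.sin(ang), 0, np.cos(ang)],
            ]
        )
        traj.coords = traj.coords @ rot.T + np.array([3.0, -2.0, 5.0])
        series2, _ = ta.dipole_orientation(traj, ev)
        np.testing.assert_allclose(series2.theta, series.theta, atol=1e-8)

    def test_two_mode_generator_peaks_within_5_degrees(self):
        traj = syn.gen_triplet_trajectory(
            fraction_n1=0.0,
            lifetime_n2=3000.0,
            n_episodes=1,
            timestep=0.05,
            seed=7,
            flip_rate_n2=89.3,
            deterministic_lifetimes=True,
        )
        events, _ = ta.classify_triplets(traj)
        _series, hist = ta.dipole_orientation(traj, events[0])
        peaks = sorted(hist["peaks_deg"])
        assert len(peaks) == 2
        assert peaks[0] == pytest.approx(40.0, abs=5.0)
        assert peaks[1] == pytest.approx(120.0, abs=5.0)


class TestSwitching:
    def test_square_wave_closed_form(self):
        # alternates 40/140 every frame at 1 ps -> transitions/(2T) = 0.5/ps = 500 GHz
        n = 400
        theta = np.where(np.arange(n) % 2 == 0, 40.0, 140.0)
        series = ta.OrientationSeries(np.arange(n) * 1.0, theta, 1.0)
        freq = ta.switching_frequency(series, debounce=1)
        assert freq == pytest.approx(0.5 * 1e3 * (n - 1) / (n - 1), rel=0.01)

    def test_constant_angle_zero_frequency(self):
        series = ta.OrientationSeries(np.arange(50.0), np.full(50, 40.0), 1.0)
        assert ta.switching_frequency(series) == 0.0

    def test_debounce_suppresses_single_frame_flicker(self):
        theta = np.full(200, 40.0)
        theta[::20] = 140.0  # isolated single-frame excursions
        series = ta.OrientationSeries(np.arange(200.0), theta, 1.0)
        assert ta.switching_frequency(series, debounce=2) == 0.0

    def test_telegraph_rate_recovered_within_3_sigma(self):
        f_true = 89.3
        traj = syn.gen_triplet_trajectory(
            fraction_n1=0.0,
            lifetime_n2=6000.0,
            n_episodes=1,
            timestep=0.05,
            seed=8,
            flip_rate_n2=f_true,
            deterministic_lifetimes=True,
        )
        events, _ = ta.classify_triplets(traj)
        series, _ = ta.dipole_orientation(traj, events[0])
        est = ta.switching_frequency(series)
        duration = 6000.0
        sigma = np.sqrt(2 * f_true * 1e-3 * duration) / (2 * duration) * 1e3
        assert abs(est - f_true) < 3 * sigma

    def test_ambiguous_series_rejected(self):
        series = ta.OrientationSeries(np.arange(20.0), np.full(20, 90.0), 1.0)
        with pytest.raises(AnalysisError):
            ta.switching_frequency(series)
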