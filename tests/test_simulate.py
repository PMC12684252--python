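import numpy as np
import pytest
from scipy import stats

from strobetrack import (
    CameraModel,
    CellGeometry,
    DiffusionModel,
    make_colony,
    render_movie,
    simulate_states,
    simulate_trajectory,
)


class TestMakeColony:
    def test_single_cell_mask_area_matches_projection(self):
        cells, mask = make_colony(1, rng=7)
        area_px = (mask == 1).sum() * (65.7 / 1000) ** 2
        assert abs(area_px / cells[0].projected_area() - 1) < 0.02

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            make_colony(0, rng=0)

    def test_same_seed_reproduces_mask(self):
        _, m1 = make_colony(4, rng=42)
        _, m2 = make_colony(4, rng=42)
        assert np.array_equal(m1, m2)

    def test_cells_do_not_overlap(self):
        cells, mask = make_colony(5, rng=3)
        assert len(np.unique(mask)) == 6  # background + 5 labels


class TestStates:
    def test_single_state_is_constant(self):
        m = DiffusionModel(D=[1.0], w=[1.0])
        assert (simulate_states(m, 100, 0) == 0).all()

    def test_identity_matrix_freezes_initial_state(self):
        m = DiffusionModel(D=[1.0, 2.0], w=[0.5, 0.5], A=np.eye(2))
        s = simulate_states(m, 200, 1)
        assert (s == s[0]).all()

    def test_missing_transition_matrix_rejected(self):
        m = DiffusionModel(D=[1.0, 2.0], w=[0.5, 0.5])
        with pytest.raises(ValueError):
            simulate_states(m, 10, 0)

    def test_symmetric_chain_occupancy_near_half(self):
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        m = DiffusionModel(D=[1.0, 2.0], w=[0.5, 0.5], A=A)
        s = simulate_states(m, 100000, 5)
        occ = (s == 0).mean()
        # 3 standard errors for a chain with autocorrelation rho = 0.8
        se = np.sqrt(0.25 / len(s) * (1 + 0.8) / (1 - 0.8))
        assert abs(occ - 0.5) < 3 * se


class TestTrajectory:
    def test_vanishing_diffusion_keeps_position_fixed(self, cell):
        m = DiffusionModel(D=[1e-30], w=[1.0])
        tr = simulate_trajectory(cell, m, 20, 0.005, 0.003, rng=0)
        p = tr.positions.reshape(-1, 3)
        assert np.allclose(p, p[0], atol=1e-9)

    def test_unconfined_msd_matches_brownian_identity(self, cell):
        # mean squared 2D frame displacement = 4 D dt for free diffusion
        D, dt = 5.0, 0.005
        m = DiffusionModel(D=[D], w=[1.0])
        rng = np.random.default_rng(2)
        r2 = []
        for _ in range(500):
            tr = simulate_trajectory(
                cell, m, 21, dt, pulse_time_s=dt, substeps=1, confined=False, rng=rng
            )
            d = np.diff(tr.positions[:, 0, :2], axis=0)
            r2.append((d**2).sum(axis=1))
        r2 = np.concatenate(r2)
        se = r2.std() / np.sqrt(len(r2))
        assert abs(r2.mean() - 4 * D * dt) < 3 * se

    def test_confined_positions_always_inside(self, cell):
        m = DiffusionModel(D=[5.0], w=[1.0])
        for seed in range(3):
            tr = simulate_trajectory(cell, m, 50, 0.005, 0.003, rng=seed)
            assert cell.contains(tr.positions.reshape(-1, 3)).all()

    def test_unconfined_steps_follow_rayleigh_law(self, cell):
        D, dt = 1.0, 0.005
        m = DiffusionModel(D=[D], w=[1.0])
        rng = np.random.default_rng(3)
        r = []
        for _ in range(200):
            tr = simulate_trajectory(
                cell, m, 26, dt, pulse_time_s=dt, substeps=1, confined=False, rng=rng
            )
            d = np.diff(tr.positions[:, 0, :2], axis=0)
            r.append(np.hypot(d[:, 0], d[:, 1]))
        r = np.concatenate(r)
        p = stats.kstest(r, stats.rayleigh(scale=np.sqrt(2 * D * dt)).cdf).pvalue
        assert p > 0.01


class TestRender:
    def make_still(self, cell, n_frames=5, **kw):
        m = DiffusionModel(D=[1e-30], w=[1.0])
        tr = simulate_trajectory(cell, m, n_frames, 0.005, 0.003, rng=4)
        return tr

    def test_empty_frames_average_to_camera_offset(self, cell, camera):
        tr = self.make_still(cell)
        movie, _ = render_movie(
            [tr], [cell], 5, photons_per_pulse=0.0, background=0.0,
            cell_background=0.0, camera=camera, rng=0,
        )
        mean = movie.data.astype(float).mean()
        se = camera.read_noise / np.sqrt(movie.data.size)
        assert abs(mean - camera.offset) < max(3 * se, 0.5)  # uint16 rounding

    def test_photon_conservation_without_noise(self, cell):
        cam = CameraModel(gain=1.0, offset=0.0, read_noise=0.0)
        tr = self.make_still(cell, n_frames=10)
        movie, truth = render_movie(
            [tr], [cell], 10, photons_per_pulse=500, background=0.0,
            cell_background=0.0, camera=cam, rng=1,
        )
        # with unit gain and no noise every emitted photon lands in a pixel
        assert movie.data.sum() == truth["photons"].sum()

    def test_full_frame_pulse_is_accepted_limit(self, cell, camera):
        tr = self.make_still(cell)
        movie, _ = render_movie(
            [tr], [cell], 5, camera=camera, frame_time_s=0.005,
            pulse_time_s=0.005, rng=0,
        )
        assert movie.pulse_time_s == movie.frame_time_s

    def test_pulse_longer_than_frame_rejected(self, cell, camera):
        tr = self.make_still(cell)
        with pytest.raises(ValueError):
            render_movie([tr], [cell], 5, camera=camera,
                         frame_time_s=0.005, pulse_time_s=0.006, rng=0)

    def test_identical_seeds_give_identical_truth(self, cell, camera):
        m = DiffusionModel(D=[0.5], w=[1.0])
        out = []
        for _ in range(2):
            tr = simulate_trajectory(cell, m, 10, 0.005, 0.003, rng=9)
            _, truth = render_movie([tr], [cell], 10, camera=camera, rng=11)
            out.append(truth)
        assert out[0].equals(out[1])
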