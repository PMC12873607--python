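"""Trajectory/movie generator and Monte-Carlo axial-survival oracle."""

import numpy as np
import pandas as pd
import pytest

from dnmt1spt.config import AcquisitionConfig
from dnmt1spt.simulate import (GroundTruthModel, mc_axial_survival,
                               render_movie, simulate_trajectories)


class TestGroundTruthModel:
    def test_fraction_validation(self):
        with pytest.raises(ValueError, match="sum"):
            GroundTruthModel(state_fractions=(0.5, 0.3, 0.3))

    def test_negative_diffusion_rejected(self):
        with pytest.raises(ValueError):
            GroundTruthModel(diffusion_coeffs=(-0.1, 0.3, 2.0))

    def test_unordered_diffusion_rejected(self):
        with pytest.raises(ValueError):
            GroundTruthModel(diffusion_coeffs=(1.0, 0.3, 2.0))


class TestSimulateTrajectories:
    def test_zero_trajectories_empty(self, model, acq):
        ds = simulate_trajectories(model, acq, 0, seed=0)
        assert len(ds.trajectories) == 0

    def test_negative_count_rejected(self, model, acq):
        with pytest.raises(ValueError):
            simulate_trajectories(model, acq, -1, seed=0)

    def test_frozen_particles_have_constant_coordinates(self, acq):
        m = GroundTruthModel(diffusion_coeffs=(0.0, 0.0, 0.0), sigma_loc=0.0)
        ds = simulate_trajectories(m, acq, 50, seed=3)
        for _, g in ds.trajectories.groupby("trajectory_id"):
            assert np.allclose(g["x_um"], g["x_um"].iloc[0])
            assert np.allclose(g["y_um"], g["y_um"].iloc[0])

    def test_msd_matches_2d_brownian_closed_form(self, acq):
        # single free state, no noise, no axial censoring: E[dr^2] = 4 D dt
        D, dt = 1.0, acq.frame_interval
        m = GroundTruthModel(state_fractions=(0.0, 0.0, 1.0),
                             diffusion_coeffs=(0.0, 0.5, D), sigma_loc=0.0,
                             track_length_mean=20.0)
        wide = AcquisitionConfig(dz=np.inf)
        ds = simulate_trajectories(m, wide, 8000, seed=4)
        sq = []
        for _, g in ds.trajectories.groupby("trajectory_id"):
            dx = np.diff(g["x_um"].to_numpy())
            dy = np.diff(g["y_um"].to_numpy())
            sq.append(dx * dx + dy * dy)
        sq = np.concatenate(sq)
        assert len(sq) >= 1e5
        se = sq.std() / np.sqrt(len(sq))
        assert abs(sq.mean() - 4 * D * dt) < 3 * se

    def test_seed_determinism(self, model, acq):
        a = simulate_trajectories(model, acq, 200, seed=9).trajectories
        b = simulate_trajectories(model, acq, 200, seed=9).trajectories
        pd.testing.assert_frame_equal(a, b)

    def test_state_fractions_converge_on_molecules(self, model):
        # without axial censoring every molecule is observed, so the
        # per-molecule state shares must converge to state_fractions
        wide = AcquisitionConfig(dz=np.inf)
        ds = simulate_trajectories(model, wide, 4000, seed=21)
        per_mol = ds.trajectories.drop_duplicates("molecule_id")
        frac = per_mol["true_state"].value_counts(normalize=True)
        n = len(per_mol)
        assert n == 4000
        for state, p in zip(("bound", "free1", "free2"), model.state_fractions):
            tol = 4 * np.sqrt(p * (1 - p) / n)
            assert abs(frac[state] - p) < tol

    def test_fast_state_censored_harder_than_bound(self, three_state_dataset):
        df = three_state_dataset.trajectories
        mean_len = df.groupby(["true_state", "trajectory_id"]).size().groupby("true_state").mean()
        assert mean_len["free2"] < mean_len["bound"]

    def test_frames_strictly_increasing(self, three_state_dataset):
        for _, g in three_state_dataset.trajectories.groupby("trajectory_id"):
            assert (np.diff(g["frame"].to_numpy()) > 0).all()

    def test_switching_mode_produces_mixed_state_tracks(self, acq):
        rates = np.full((3, 3), 8.0)
        np.fill_diagonal(rates, 0.0)
        m = GroundTruthModel(switching_rates=rates, track_length_mean=15.0)
        ds = simulate_trajectories(m, acq, 150, seed=5)
        states_per_track = ds.trajectories.groupby("trajectory_id")["true_state"].nunique()
        assert (states_per_track > 1).any()


class TestRenderMovie:
    def test_background_only_mean(self, model, acq):
        ds = simulate_trajectories(model, acq, 0, seed=0)
        small = AcquisitionConfig(fov=(32, 32), background=100.0)
        stack = render_movie(ds, small, seed=1, n_frames=5)
        # Poisson(100): per-pixel mean over 5*32*32 samples
        assert abs(stack.mean() - 100.0) < 3 * np.sqrt(100.0 / stack.size)

    def test_integrated_signal_conserves_photon_budget(self, acq):
        from conftest import make_static_dataset
        small = AcquisitionConfig(fov=(32, 32), photon_budget=500.0, background=100.0)
        n_frames = 200
        ds = make_static_dataset([(2.56, 2.56)], n_frames, small)
        stack = render_movie(ds, small, seed=2, n_frames=n_frames).astype(float)
        signal = stack.sum(axis=(1, 2)) - 100.0 * 32 * 32
        se = signal.std() / np.sqrt(n_frames)
        assert abs(signal.mean() - 500.0) < 3 * se

    def test_out_of_fov_particles_warn(self, acq):
        from conftest import make_static_dataset
        small = AcquisitionConfig(fov=(16, 16))
        ds = make_static_dataset([(10.0, 10.0)], 2, small)  # 10 µm > 2.56 µm fov
        with pytest.warns(UserWarning, match="field of view"):
            render_movie(ds, small, seed=0, n_frames=2)


class TestMCAxialSurvival:
    def test_immobile_walker_survives(self):
        assert mc_axial_survival(0.0, 0.01, 0.7, 1000, 10, seed=0).probability == 1.0

    def test_wide_slab_limit(self):
        # survival ~ 1 - 2 sqrt(4 D t / pi) / dz (boundary-layer loss)
        r = mc_axial_survival(1.0, 0.01, 100.0, 50000, 10, seed=0)
        loss = 2 * np.sqrt(4 * 1.0 * 0.01 / np.pi) / 100.0
        assert abs(r.probability - (1.0 - loss)) < 4 * r.stderr + 1e-4

    def test_zero_walkers_rejected(self):
        with pytest.raises(ValueError):
            mc_axial_survival(1.0, 0.01, 0.7, 0, 10, seed=0)

    @pytest.mark.parametrize("bridge", [True, False])
    def test_monotone_in_D_and_t(self, bridge):
        ps = [mc_axial_survival(D, 0.02, 0.7, 20000, 20, seed=1, bridge=bridge).probability
              for D in (0.1, 0.5, 2.0, 8.0)]
        assert ps == sorted(ps, reverse=True)
        pt = [mc_axial_survival(1.0, t, 0.7, 20000, 20, seed=2, bridge=bridge).probability
              for t in (0.01, 0.03, 0.07)]
        assert pt == sorted(pt, reverse=True)

    def test_bridge_mode_kills_more_walkers(self):
        # discrete-only checks miss within-step crossings
        pb = mc_axial_survival(1.0, 0.03, 0.7, 50000, 20, seed=3, bridge=True)
        pd_ = mc_axial_survival(1.0, 0.03, 0.7, 50000, 20, seed=3, bridge=False)
        assert pb.probability < pd_.probability
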