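"""Jump histograms, defocalization correction and the kinetic fit."""

import numpy as np
import pandas as pd
import pytest

from dnmt1spt.config import FitConfig
from dnmt1spt.kinetics import (JumpHistogram, axial_survival_probability,
                               compile_jump_histograms, fit_kinetic_model,
                               model_jump_pdf, select_model)
from dnmt1spt.simulate import mc_axial_survival


def traj_table(rows):
    df = pd.DataFrame(rows, columns=["trajectory_id", "frame", "x_um", "y_um"])
    df["cell_id"] = "c"
    return df


def brute_force_histogram(df, cfg):
    """Independent enumeration oracle: all pairs (i, j) within a trajectory
    with frame difference k and every intermediate frame observed; first
    ``jumps_per_trajectory`` by start frame."""
    n_bins = int(round(cfg.max_jump / cfg.bin_width))
    counts = np.zeros((cfg.n_timepoints, n_bins), int)
    for _, g in df.groupby("trajectory_id"):
        g = g.sort_values("frame")
        frames = g["frame"].tolist()
        pts = list(zip(g["x_um"], g["y_um"]))
        for k in range(1, cfg.n_timepoints + 1):
            taken = 0
            for i, f0 in enumerate(frames):
                if cfg.jumps_per_trajectory is not None and taken >= cfg.jumps_per_trajectory:
                    break
                if f0 + k not in frames:
                    continue
                if any(f0 + m not in frames for m in range(1, k)):
                    continue
                j = frames.index(f0 + k)
                r = np.hypot(pts[j][0] - pts[i][0], pts[j][1] - pts[i][1])
                b = int(r / cfg.bin_width)
                if b < n_bins:
                    counts[k - 1, b] += 1
                taken += 1
    return counts


class TestCompileJumpHistograms:
    def test_single_jump_lands_in_expected_bin(self, fit_cfg):
        df = traj_table([(0, 0, 0.0, 0.0), (0, 1, 0.055, 0.0)])
        h = compile_jump_histograms(df, fit_cfg)
        assert h.counts[0, 5] == 1          # bin [0.05, 0.06) at k=1
        assert h.counts.sum() == 1

    def test_cap_limits_long_trajectory_to_four_jumps(self, fit_cfg):
        rows = [(0, f, 0.01 * f, 0.0) for f in range(20)]
        h = compile_jump_histograms(traj_table(rows), fit_cfg)
        assert (h.n_jumps == 4).all()       # every k = 1..7

    def test_matches_brute_force_enumeration_with_gap(self, fit_cfg):
        # hand fixture: 4-point trajectory with a recorded gap at frame 3
        df = traj_table([(5, 0, 0.00, 0.00), (5, 1, 0.08, 0.02),
                         (5, 2, 0.05, 0.09), (5, 4, 0.11, 0.14),
                         (8, 0, 1.00, 1.00), (8, 1, 1.02, 1.01)])
        h = compile_jump_histograms(df, fit_cfg)
        np.testing.assert_array_equal(h.counts, brute_force_histogram(df, fit_cfg))

    def test_matches_brute_force_on_random_gapped_tracks(self, fit_cfg):
        rng = np.random.default_rng(0)
        rows = []
        for tid in range(20):
            frames = sorted(rng.choice(30, size=rng.integers(2, 14), replace=False))
            for f in frames:
                rows.append((tid, int(f), rng.uniform(0, 1), rng.uniform(0, 1)))
        df = traj_table(rows)
        h = compile_jump_histograms(df, fit_cfg)
        np.testing.assert_array_equal(h.counts, brute_force_histogram(df, fit_cfg))

    def test_density_normalized_per_time_gap(self, three_state_dataset, fit_cfg):
        h = compile_jump_histograms(three_state_dataset.trajectories, fit_cfg)
        for k in range(7):
            if h.n_jumps[k]:
                assert h.density[k].sum() * h.bin_width == pytest.approx(1.0)


class TestAxialSurvival:
    def test_immobile_returns_one(self):
        assert axial_survival_probability(0.0, 0.01, 0.7) == 1.0

    def test_wide_slab_limit(self):
        # uniform starts include the boundary layer: the exact wide-slab loss
        # is 2 sqrt(4 D t / pi) / dz, vanishing only as dz -> infinity
        loss = 2 * np.sqrt(4 * 1.0 * 0.01 / np.pi) / 100.0
        assert axial_survival_probability(1.0, 0.01, 100.0) == \
            pytest.approx(1.0 - loss, abs=1e-5)
        assert axial_survival_probability(1.0, 0.01, 1e6) == pytest.approx(1.0, abs=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            axial_survival_probability(1.0, -0.01, 0.7)
        with pytest.raises(ValueError):
            axial_survival_probability(-1.0, 0.01, 0.7)

    def test_matches_monte_carlo_oracle(self):
        # spot check; the full grid runs in the acceptance suite
        p = axial_survival_probability(2.0, 0.01, 0.7)
        mc = mc_axial_survival(2.0, 0.01, 0.7, 200_000, 100, seed=0)
        assert abs(p - mc.probability) < 0.005

    def test_vectorized_over_D_and_t(self):
        D = np.array([0.1, 1.0, 3.0])
        t = np.array([[0.01], [0.07]])
        out = axial_survival_probability(D, t, 0.7)
        assert out.shape == (2, 3)
        assert np.all(np.diff(out, axis=1) < 0)   # decreasing in D
        assert np.all(out[1] < out[0])            # decreasing in t


class TestModelJumpPdf:
    centers = np.arange(0.005, 1.2, 0.01)

    def test_single_free_state_matches_rayleigh(self):
        # sigma=0, dz=inf: density r/(2 D tau) exp(-r^2/(4 D tau)), i.e. a
        # Rayleigh with per-axis variance 2 D tau; oracle via scipy
        from scipy.stats import rayleigh
        D, tau = 1.0, 0.01
        dens = model_jump_pdf(self.centers, [0.0, 0.0, 1.0], [0.001, 0.1, D],
                              sigma=0.0, tau=tau, dz=np.inf)
        edges = np.arange(0.0, 1.2001, 0.01)
        ray = rayleigh(scale=np.sqrt(2 * D * tau))
        expected = np.diff(ray.cdf(edges)) / 0.01
        assert np.max(np.abs(dens - expected)) < 1e-6
        # mode in bin [0.14, 0.15): r* = sqrt(2 D tau)
        assert 0.14 <= self.centers[np.argmax(dens)] < 0.15

    def test_normalization_for_random_bounded_parameters(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            fb, f1 = rng.uniform(0, 1), rng.uniform(0, 1)
            fr = [fb, (1 - fb) * f1, (1 - fb) * (1 - f1)]
            Ds = [rng.uniform(1e-4, 0.05), rng.uniform(0.05, 1), rng.uniform(1, 10)]
            sigma = rng.uniform(0.01, 0.075)
            for tau in (0.01, 0.04, 0.07):
                dens = model_jump_pdf(self.centers, fr, Ds, sigma, tau, dz=0.7)
                assert abs(dens.sum() * 0.01 - 1.0) < 1e-3

    def test_pure_bound_short_jump_mass_matches_rayleigh_cdf(self):
        # closed form: mass below r is 1 - exp(-r^2 / (4 (D tau + sigma^2)))
        D, sigma, tau = 0.001, 0.035, 0.01
        dens = model_jump_pdf(self.centers, [1.0, 0.0, 0.0], [D, 0.1, 2.0],
                              sigma=sigma, tau=tau, dz=0.7)
        s2 = D * tau + sigma ** 2
        expected_below = 1.0 - np.exp(-0.1 ** 2 / (4 * s2))
        below = dens[self.centers < 0.1].sum() / dens.sum()
        assert below == pytest.approx(expected_below, abs=1e-3)
        # localization error sets the short-jump floor: >= 99% within 0.16 µm
        # (closed form: 1 - exp(-0.16^2 / (4 s2)) = 0.9946)
        assert dens[self.centers < 0.16].sum() / dens.sum() >= 0.99

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            model_jump_pdf(self.centers, [1.0, 0.0, 0.0], [0.001, 0.1, 2.0],
                           sigma=-0.01, tau=0.01)
        with pytest.raises(ValueError):
            model_jump_pdf(self.centers, [0.7, 0.7, -0.4], [0.001, 0.1, 2.0],
                           sigma=0.01, tau=0.01)

    def test_defocalization_shifts_weight_to_slow_states(self):
        with_corr = model_jump_pdf(self.centers, [0.3, 0.2, 0.5],
                                   [0.002, 0.3, 2.5], 0.03, 0.07, dz=0.7)
        without = model_jump_pdf(self.centers, [0.3, 0.2, 0.5],
                                 [0.002, 0.3, 2.5], 0.03, 0.07, dz=np.inf)
        # more mass at short jumps once fast molecules are censored
        assert with_corr[self.centers < 0.1].sum() > without[self.centers < 0.1].sum()


def synthetic_histogram(fractions, Ds, sigma, n_jumps, seed, cfg, dz=None):
    """Sample displacements directly from the mixture (independent of the
    trajectory simulator) and bin them like the compiler does."""
    rng = np.random.default_rng(seed)
    n_bins = int(round(cfg.max_jump / cfg.bin_width))
    edges = np.linspace(0, n_bins * cfg.bin_width, n_bins + 1)
    counts = np.zeros((cfg.n_timepoints, n_bins), int)
    nj = np.zeros(cfg.n_timepoints, int)
    for k in range(1, cfg.n_timepoints + 1):
        tau = k * cfg.frame_interval
        w = np.asarray(fractions, float)
        if dz is not None:
            w = w * axial_survival_probability(np.asarray(Ds), tau, dz)
        w = w / w.sum()
        states = rng.choice(len(w), size=n_jumps, p=w)
        scale = np.sqrt(np.asarray(Ds)[states] * tau + sigma ** 2)
        r = rng.rayleigh(np.sqrt(2) * scale)
        r = r[r < edges[-1]]
        counts[k - 1] = np.histogram(r, bins=edges)[0]
        nj[k - 1] = len(r)
    density = counts / (nj[:, None] * cfg.bin_width)
    return JumpHistogram(edges, counts, density, nj, cfg.frame_interval,
                         cfg.jumps_per_trajectory)


class TestFitKineticModel:
    def test_pure_bound_state_recovered(self, fit_cfg):
        h = synthetic_histogram([1.0, 0.0, 0.0], [0.002, 0.3, 2.0], 0.035,
                                n_jumps=1500, seed=0, cfg=fit_cfg)
        fit = fit_kinetic_model(h, fit_cfg)
        assert fit.F_bound >= 0.95

    def test_three_state_mixture_recovered(self, fit_cfg):
        h = synthetic_histogram([0.10, 0.18, 0.72], [0.005, 0.35, 2.3], 0.035,
                                n_jumps=3000, seed=1, cfg=fit_cfg, dz=0.7)
        fit = fit_kinetic_model(h, fit_cfg)
        assert abs(fit.F_bound - 0.10) < 0.03
        assert abs(fit.D_free2 - 2.3) / 2.3 < 0.10

    def test_fractions_sum_to_one_and_bounds_respected(self, fit_cfg):
        h = synthetic_histogram([0.2, 0.3, 0.5], [0.01, 0.2, 3.0], 0.03,
                                n_jumps=1000, seed=2, cfg=fit_cfg, dz=0.7)
        fit = fit_kinetic_model(h, fit_cfg)
        assert fit.F_bound + fit.F_free1 + fit.F_free2 == pytest.approx(1.0, abs=1e-6)
        for name, val in (("D_bound", fit.D_bound), ("D_free1", fit.D_free1),
                          ("D_free2", fit.D_free2)):
            lo, hi = fit_cfg.bounds[name]
            assert lo <= val <= hi

    def test_invariant_to_count_rescaling(self, fit_cfg):
        h = synthetic_histogram([0.2, 0.3, 0.5], [0.01, 0.2, 3.0], 0.03,
                                n_jumps=1000, seed=3, cfg=fit_cfg, dz=0.7)
        h10 = JumpHistogram(h.bin_edges, h.counts * 10, h.density,
                            h.n_jumps * 10, h.frame_interval,
                            h.jumps_per_trajectory_cap)
        f1 = fit_kinetic_model(h, fit_cfg)
        f2 = fit_kinetic_model(h10, fit_cfg)
        assert f1.F_bound == pytest.approx(f2.F_bound, abs=1e-9)
        assert f1.D_free2 == pytest.approx(f2.D_free2, abs=1e-9)

    def test_too_few_jumps_refused(self, fit_cfg):
        h = synthetic_histogram([0.5, 0.2, 0.3], [0.01, 0.2, 3.0], 0.03,
                                n_jumps=10, seed=4, cfg=fit_cfg)
        with pytest.raises(ValueError, match="too few jumps"):
            fit_kinetic_model(h, fit_cfg)

    def test_disabling_dz_correction_biases_fbound_up(self, three_state_dataset):
        cfg_on = FitConfig(jumps_per_trajectory=None)
        cfg_off = FitConfig(jumps_per_trajectory=None, use_dz_correction=False)
        h = compile_jump_histograms(three_state_dataset.trajectories, cfg_on)
        f_on = fit_kinetic_model(h, cfg_on)
        f_off = fit_kinetic_model(h, cfg_off)
        assert f_off.F_bound > f_on.F_bound

    def test_two_state_fit_has_two_fractions(self):
        cfg2 = FitConfig.two_state()
        h = synthetic_histogram([0.3, 0.0, 0.7], [0.01, 0.2, 3.0], 0.03,
                                n_jumps=2000, seed=5, cfg=cfg2)
        fit = fit_kinetic_model(h, cfg2)
        assert fit.n_states == 2
        assert fit.F_free1 == 0.0
        assert fit.F_bound + fit.F_free2 == pytest.approx(1.0, abs=1e-6)


class TestSelectModel:
    def test_three_state_data_selects_three_states(self, fit_cfg):
        h = synthetic_histogram([0.10, 0.18, 0.72], [0.005, 0.35, 2.3], 0.035,
                                n_jumps=3000, seed=6, cfg=fit_cfg, dz=0.7)
        sel = select_model(h, FitConfig.two_state(), fit_cfg)
        assert sel.selected == 3
        assert sel.residual3 < sel.residual2

    def test_two_state_data_selects_two_states(self, fit_cfg):
        h = synthetic_histogram([0.30, 0.0, 0.70], [0.002, 0.3, 2.0], 0.035,
                                n_jumps=3000, seed=7, cfg=fit_cfg, dz=0.7)
        sel = select_model(h, FitConfig.two_state(), fit_cfg)
        assert sel.selected == 2

    def test_equal_residuals_prefer_fewer_parameters(self, fit_cfg, monkeypatch):
        from dnmt1spt import kinetics as K
        h = synthetic_histogram([0.3, 0.2, 0.5], [0.01, 0.2, 3.0], 0.03,
                                n_jumps=1000, seed=8, cfg=fit_cfg)

        def fake_fit(hist, cfg):
            return K.KineticFit(cfg.n_states, 0.3, 0.2, 0.5, 0.01, 0.2, 3.0,
                                0.03, residual=1.0, n_jumps_used=1000,
                                converged=True)

        monkeypatch.setattr(K, "fit_kinetic_model", fake_fit)
        sel = K.select_model(h, FitConfig.two_state(), fit_cfg)
        assert sel.selected == 2
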