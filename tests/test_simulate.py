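"""Synthetic movie generator: kinetics, rendering, scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import curve_fit

from iscatrack import (
    BlobParams,
    SimulationConfig,
    render_movie,
    sample_events,
    score_detections,
    simulate_movie,
    uniform_surface,
)
from iscatrack.errors import ConfigurationError, InvalidParameterError
from iscatrack.simulate import ParticleTruth

from conftest import single_scatterer_cfg


class TestSampleEvents:
    def test_zero_arrival_rate_gives_no_events(self):
        cfg = SimulationConfig(n_frames=50, arrival_rate=0.0)
        truth = sample_events(cfg, uniform_surface((cfg.n_px, cfg.n_px)))
        assert truth == []

    def test_poisson_event_count(self):
        """Total arrivals stay within 3 sd of rate * n_frames."""
        cfg = SimulationConfig(n_frames=500, arrival_rate=2.0, seed=21,
                               mean_dwell_ms=20.0)
        truth = sample_events(cfg, uniform_surface((cfg.n_px, cfg.n_px)))
        # count arrivals (events can be dropped only by instant exit, which
        # cannot happen on landing inside the FOV)
        assert abs(len(truth) - 1000) <= 3 * np.sqrt(1000)

    def test_degenerate_affinity_pins_landing_pixel(self):
        cfg = SimulationConfig(n_frames=100, arrival_rate=1.0, seed=3,
                               diffusion_um2_s=0.0)
        surf = uniform_surface((cfg.n_px, cfg.n_px))
        surf.affinity[:] = 0.0
        surf.affinity[40, 60] = 1.0
        truth = sample_events(cfg, surf)
        assert truth
        for p in truth:
            assert 60 * cfg.pixel_nm <= p.x_nm[0] < 61 * cfg.pixel_nm
            assert 40 * cfg.pixel_nm <= p.y_nm[0] < 41 * cfg.pixel_nm

    def test_zero_affinity_with_positive_rate_rejected(self):
        cfg = SimulationConfig(n_frames=50, arrival_rate=1.0, seed=5)
        surf = uniform_surface((cfg.n_px, cfg.n_px))
        surf.affinity[:] = 0.0
        with pytest.raises(ConfigurationError):
            sample_events(cfg, surf)

    def test_dwell_mean_converges(self):
        """Continuous dwell draws average to mean_dwell_ms within 3 SE."""
        cfg = SimulationConfig(n_frames=500, arrival_rate=20.0, seed=17,
                               mean_dwell_ms=50.0, diffusion_um2_s=0.0)
        truth = sample_events(cfg, uniform_surface((cfg.n_px, cfg.n_px)))
        dwells = np.array([p.dwell_ms_true for p in truth])
        assert len(dwells) >= 9000
        se = 50.0 / np.sqrt(len(dwells))
        assert abs(dwells.mean() - 50.0) < 3 * se

    def test_truth_msd_matches_diffusion_coefficient(self):
        """Per-axis MSD at lag tau = 2 D tau for the simulated paths."""
        cfg = SimulationConfig(n_frames=400, arrival_rate=1.0, seed=9,
                               mean_dwell_ms=200.0, diffusion_um2_s=0.02,
                               boundary="reflecting")
        truth = sample_events(cfg, uniform_surface((cfg.n_px, cfg.n_px)))
        dt_s = cfg.frame_period_ms / 1000.0
        for lag in (1, 2):
            sq = []
            for p in truth:
                if p.dwell_frames > lag:
                    sq.extend(((p.x_nm[lag:] - p.x_nm[:-lag]) / 1000.0) ** 2)
            sq = np.asarray(sq)
            expected = 2.0 * cfg.diffusion_um2_s * dt_s * lag  # um^2 per axis
            se = sq.std() / np.sqrt(len(sq))
            assert abs(sq.mean() - expected) < 3 * se

    def test_bit_reproducible_under_seed(self):
        cfg = SimulationConfig(n_frames=120, arrival_rate=0.2, seed=33)
        surf = uniform_surface((cfg.n_px, cfg.n_px))
        a = sample_events(cfg, surf)
        b = sample_events(cfg, surf)
        assert len(a) == len(b)
        for p, q in zip(a, b):
            assert p.arrival_frame == q.arrival_frame
            assert np.array_equal(p.x_nm, q.x_nm)
            assert np.array_equal(p.z_nm, q.z_nm)

    def test_absorbing_truth_is_truncation_of_reflecting_truth(self):
        """Same seed, boundary applied post hoc: absorbing <= reflecting."""
        kw = dict(n_frames=300, arrival_rate=0.3, seed=44, mean_dwell_ms=80.0,
                  diffusion_um2_s=0.5)
        surf_shape = (SimulationConfig(**kw).n_px,) * 2
        absorbing = sample_events(SimulationConfig(**kw, boundary="absorbing"),
                                  uniform_surface(surf_shape))
        reflecting = sample_events(SimulationConfig(**kw, boundary="reflecting"),
                                   uniform_surface(surf_shape))
        ref = {p.particle_id: p for p in reflecting}
        assert any(p.exited_fov for p in absorbing)
        for p in absorbing:
            assert p.dwell_frames <= ref[p.particle_id].dwell_frames


class TestRenderMovie:
    def test_empty_truth_no_noise_reproduces_background(self, small_cfg,
                                                        small_surface):
        movie = render_movie(small_cfg, small_surface, [])
        assert np.allclose(movie.frames,
                           small_surface.background_template[None], rtol=1e-6)

    def test_movie_bit_reproducible(self):
        cfg = SimulationConfig(n_frames=60, arrival_rate=0.2, seed=12)
        surf = uniform_surface((cfg.n_px, cfg.n_px))
        m1, _ = simulate_movie(cfg, surf)
        m2, _ = simulate_movie(cfg, surf)
        assert np.array_equal(m1.frames, m2.frames)

    def test_zero_scatterers_rejected(self):
        with pytest.raises(ConfigurationError):
            BlobParams(n_scatterers=0)

    def test_single_scatterer_renders_gaussian_of_configured_width(self):
        """A K=1 blob's contrast profile is Gaussian; fitting recovers sigma."""
        cfg = single_scatterer_cfg()
        surf = uniform_surface((cfg.n_px, cfg.n_px))
        pos = (51 + 0.5) * cfg.pixel_nm
        p = ParticleTruth(0, 5, np.array([pos]), np.array([pos]), np.array([0.0]))
        movie = render_movie(cfg, surf, [p])
        contrast = (movie.frames[5] - surf.background_template) / surf.background_template
        profile = contrast[51, :]
        x_nm = (np.arange(cfg.n_px) + 0.5) * cfg.pixel_nm

        def gauss(x, a, mu, sigma):
            return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

        popt, _ = curve_fit(gauss, x_nm, profile, p0=[0.05, pos, 100.0])
        assert abs(popt[2]) == pytest.approx(cfg.blob.psf_sigma_nm, rel=0.05)
        assert popt[1] == pytest.approx(pos, abs=5.0)


class TestScoreDetections:
    def _truth(self):
        return [
            ParticleTruth(0, 0, np.array([500.0]), np.array([600.0]),
                          np.array([0.0])),
            ParticleTruth(1, 0, np.array([1500.0]), np.array([1600.0]),
                          np.array([0.0])),
        ]

    def test_perfect_detections(self):
        found = pd.DataFrame(
            {"frame": [0, 0], "x_nm": [500.0, 1500.0], "y_nm": [600.0, 1600.0]}
        )
        s = score_detections(self._truth(), found, match_radius_nm=100.0)
        assert (s.precision, s.recall, s.rmse_nm) == (1.0, 1.0, 0.0)

    def test_empty_found_zero_recall(self):
        found = pd.DataFrame(columns=["frame", "x_nm", "y_nm"])
        s = score_detections(self._truth(), found, match_radius_nm=100.0)
        assert s.recall == 0.0
        assert not s.precision_defined

    def test_both_empty_is_perfect(self):
        found = pd.DataFrame(columns=["frame", "x_nm", "y_nm"])
        s = score_detections([], found, match_radius_nm=100.0)
        assert (s.precision, s.recall) == (1.0, 1.0)

    def test_greedy_matching_equals_optimal_on_swap_instance(self):
        """Two truths, two founds slightly swapped: greedy == brute force."""
        truth = self._truth()
        found = pd.DataFrame(
            {"frame": [0, 0], "x_nm": [530.0, 1480.0], "y_nm": [630.0, 1590.0]}
        )
        s = score_detections(truth, found, match_radius_nm=120.0)
        # brute force over both possible assignments
        t = np.array([[500.0, 600.0], [1500.0, 1600.0]])
        f = found[["x_nm", "y_nm"]].to_numpy()
        costs = []
        for perm in itertools.permutations(range(2)):
            d = [np.linalg.norm(t[i] - f[perm[i]]) for i in range(2)]
            if all(v <= 120.0 for v in d):
                costs.append((len(d), -np.sum(np.square(d))))
        best_matches = max(costs)[0]
        assert s.n_matched == best_matches == 2

    def test_prewarmup_truth_excluded(self):
        found = pd.DataFrame({"frame": [0], "x_nm": [500.0], "y_nm": [600.0]})
        s = score_detections(self._truth(), found, match_radius_nm=100.0,
                             frame_offset=5)
        assert s.n_truth == 0  # all truth lives in frame 0 < offset

    def test_invalid_radius(self):
        with pytest.raises(InvalidParameterError):
            score_detections([], pd.DataFrame(columns=["frame", "x_nm", "y_nm"]),
                             match_radius_nm=0.0)
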