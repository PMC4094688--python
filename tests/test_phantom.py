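"""Phantom generator: geometry, time course, noise moments, simulators."""

import numpy as np
import pytest

from lvecho.geometry import half_plane_side
from lvecho.phantom import (
    ConfigurationError,
    PhantomConfig,
    generate_sequence,
    simulate_physio_log,
    simulate_score_table,
)
from lvecho.scoring import score_distribution
from lvecho.stats import paired_t, physio_effect


def plateau_frame(seq):
    cfg = seq.meta
    t_mid = cfg.arrival_time + cfg.washin_time + cfg.plateau_duration / 2
    return seq.frames[int(np.argmin(np.abs(seq.timestamps - t_mid)))]


class TestGenerateSequence:
    def test_noiseless_homogeneous_plateau_is_flat(self, noiseless_seq_128):
        frame = plateau_frame(noiseless_seq_128)
        cavity = frame[noiseless_seq_128.truth_mask]
        assert np.allclose(cavity, noiseless_seq_128.meta.peak_intensity)

    def test_same_seed_bit_identical(self):
        cfg = PhantomConfig.for_dose("3", rng_seed=7, image_height=96, image_width=96)
        a, b = generate_sequence(cfg), generate_sequence(cfg)
        assert all(np.array_equal(x, y) for x, y in zip(a.frames, b.frames))
        assert np.array_equal(a.timestamps, b.timestamps)
        c = generate_sequence(cfg.with_(rng_seed=8))
        assert not np.array_equal(a.frames[20], c.frames[20])

    def test_speckle_moments_match_gamma_model(self):
        # homogeneous plateau: mean ≈ peak, CV ≈ 1/sqrt(looks), >1e4 cavity px
        cfg = PhantomConfig.for_dose("5", rng_seed=5).with_(
            peak_intensity=0.8, speckle_looks=16, inhomogeneity=0.0
        )
        seq = generate_sequence(cfg)
        vals = plateau_frame(seq)[seq.truth_mask]
        n = vals.size
        assert n > 10_000
        se = 0.8 * 0.25 / np.sqrt(n)
        assert abs(vals.mean() - 0.8) < 3 * se
        assert abs(vals.std() / vals.mean() - 0.25) < 0.025

    def test_timestamps_and_truth_invariants(self, seq5_128):
        seq = seq5_128
        assert np.all(np.diff(seq.timestamps) > 0)
        assert len(seq.frames) == len(seq.truth_masks)
        assert all(np.array_equal(m, seq.truth_mask) for m in seq.truth_masks)
        atrial = half_plane_side(
            seq.shape, *seq.av_plane, reference=(seq.meta.cavity.apex_row + 1, seq.meta.cavity.apex_col)
        )
        assert not (seq.truth_mask & atrial).any()

    @pytest.mark.parametrize("param,values", [
        ("peak_intensity", [0.3, 0.5, 0.7, 0.9]),
        ("inhomogeneity", [0.0, 0.2, 0.45, 0.7]),
    ])
    def test_plateau_moments_monotone(self, param, values):
        means, cvs = [], []
        for v in values:
            cfg = PhantomConfig.for_dose("5", rng_seed=3, image_height=128, image_width=128)
            cfg = cfg.with_(**{param: v})
            seq = generate_sequence(cfg)
            vals = plateau_frame(seq)[seq.truth_mask]
            means.append(vals.mean())
            cvs.append(vals.std() / vals.mean())
        if param == "peak_intensity":
            assert np.all(np.diff(means) > 0)
        else:
            assert np.all(np.diff(cvs) > 0)

    def test_enhancement_duration_monotone_in_plateau(self):
        def time_above(plateau):
            cfg = PhantomConfig.for_dose("5", rng_seed=2, image_height=96, image_width=96)
            seq = generate_sequence(cfg.with_(plateau_duration=plateau))
            m = np.array([f[seq.truth_mask].mean() for f in seq.frames])
            return (m > 0.3).sum() * cfg.frame_interval

        durations = [time_above(p) for p in (8.0, 15.0, 25.0)]
        assert np.all(np.diff(durations) > 0)

    def test_raster_too_small_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomConfig.for_dose("5", image_height=32, image_width=32)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(peak_intensity=1.5)
        with pytest.raises(ValueError):
            PhantomConfig(inhomogeneity=-0.1)
        with pytest.raises(ValueError):
            PhantomConfig(plateau_duration=0.0)


class TestScoreTable:
    def test_full_design_counts(self):
        table = simulate_score_table(8, 3, {"5": (0.1, 0.3, 0.6)}, rng=0)
        assert len(table) == 144
        n0, n1, n2 = score_distribution(table, "5")
        assert n0 + n1 + n2 == 144
        for region in ("apical", "mid", "base"):
            assert sum(score_distribution(table, "5", region)) == 48

    def test_degenerate_distribution(self):
        table = simulate_score_table(8, 3, {"5": (0.0, 0.0, 1.0)}, rng=0)
        assert score_distribution(table, "5") == (0, 0, 144)

    def test_marginals_within_binomial_bounds(self):
        # target marginal (1, 39, 104)/144 – the SonoVue visibility distribution
        probs = (1 / 144, 39 / 144, 104 / 144)
        table = simulate_score_table(8, 3, {"sv": probs}, rng=42)
        counts = score_distribution(table, "sv")
        for c, p in zip(counts, probs):
            half = 2.576 * np.sqrt(144 * p * (1 - p))
            assert abs(c - 144 * p) <= half + 1e-9

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            simulate_score_table(2, 1, {"5": (0.5, 0.5, 0.5)})


class TestPhysioLog:
    def test_baseline_long_run_mean(self):
        log = simulate_physio_log(
            1, [], duration_min=400,
            between_sd={"sao2": 0.0, "hr": 0.0, "map": 0.0}, rng=1,
        )
        sao2 = log.samples["sao2"]
        assert abs(sao2.mean() - 98.0) < 3 * 0.3 / np.sqrt(len(sao2))

    def test_zero_noise_effect_is_exact(self):
        log = simulate_physio_log(
            1, [("x", 8)], effects={"x": {"hr": -0.04}},
            between_sd={v: 0.0 for v in ("sao2", "hr", "map")},
            within_sd={v: 0.0 for v in ("sao2", "hr", "map")},
            rng=0,
        )
        eff = physio_effect(log, "x")
        hr = eff[eff["variable"] == "hr"]["rel_diff_pct"].iloc[0]
        assert hr == pytest.approx(-4.0)
        sao2 = eff[eff["variable"] == "sao2"]["rel_diff_pct"].iloc[0]
        assert sao2 == pytest.approx(0.0)

    def test_null_effect_type_one_error_near_nominal(self):
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            log = simulate_physio_log(8, [("x", 8)], rng=int(rng.integers(2**31)))
            eff = physio_effect(log, "x")
            hr = eff[eff["variable"] == "hr"]["rel_diff_pct"].to_numpy()
            rejections += paired_t(hr).p_value < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_injection_outside_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_physio_log(1, [("x", 50)], duration_min=20)
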