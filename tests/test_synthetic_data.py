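import math

import numpy as np
import pytest

from fmica import (
    SimConfig,
    apply_subject_variation,
    fastica,
    generate_group_sources,
    generate_timecourses,
    match_components,
    synthesize_dataset,
)
from fmica.synthetic_data import canonical_hrf, task_boxcar


class TestSimConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(grid_side=4),
            dict(unique_event_prob=1.5),
            dict(cnr=0.0),
            dict(n_blocks=20),                     # block design overflows T
            dict(task_sources=((99, 4.0, 0.2),)),
            dict(translation_sd=-1.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)

    def test_defaults_match_study_conditions(self):
        cfg = SimConfig()
        assert (cfg.n_subjects, cfg.grid_side, cfg.n_sources) == (20, 148, 12)
        assert (cfg.n_timepoints, cfg.tr, cfg.baseline, cfg.cnr) == (120, 2.0, 800.0, 1.0)
        assert cfg.unique_event_prob == 0.2 and cfg.psc_mean == 3.0


class TestGroupSources:
    def test_count_shape_and_peak_normalization(self):
        cfg = SimConfig(seed=1)
        maps = generate_group_sources(cfg)
        assert maps.shape == (12, 148 * 148)
        assert np.allclose(maps.max(axis=1), 1.0)

    def test_single_blob_peak_one(self):
        cfg = SimConfig(n_sources=1, grid_side=32, seed=9)
        maps = generate_group_sources(cfg)
        assert maps.shape == (1, 1024)
        assert maps.max() == pytest.approx(1.0)

    def test_determinism_and_seed_sensitivity(self):
        cfg = SimConfig(n_sources=3, grid_side=40, seed=5)
        a = generate_group_sources(cfg)
        b = generate_group_sources(cfg)
        assert np.array_equal(a, b)
        c = generate_group_sources(SimConfig(n_sources=3, grid_side=40, seed=6))
        peaks_a = np.argmax(a, axis=1)
        peaks_c = np.argmax(c, axis=1)
        assert not np.array_equal(peaks_a, peaks_c)

    def test_sources_pairwise_distinguishable(self):
        maps = generate_group_sources(SimConfig(seed=2))
        C = np.corrcoef(maps)
        off = C[~np.eye(12, dtype=bool)]
        assert np.max(np.abs(off)) < 0.5

    def test_grid_too_small_raises(self):
        with pytest.raises(ValueError):
            generate_group_sources(SimConfig(grid_side=8, n_sources=12))


class TestSubjectVariation:
    def test_zero_spreads_identity(self):
        g = generate_group_sources(SimConfig(n_sources=3, grid_side=40, seed=0))
        out, params = apply_subject_variation(g, (0.0, 0.0, 0.0), seed=3)
        assert np.array_equal(out, g)
        assert np.allclose(params[:, :3], 0.0) and np.allclose(params[:, 3], 1.0)

    def test_translation_moves_blob_by_drawn_offset(self):
        side = 100
        ii, jj = np.mgrid[0:side, 0:side].astype(float)
        blob = np.exp(-0.5 * (((ii - 50) / 4) ** 2 + ((jj - 50) / 4) ** 2))
        out, params = apply_subject_variation(
            blob.ravel()[None, :], (2.0, 0.0, 0.0), seed=11, grid_side=side
        )
        dx, dy = params[0, 0], params[0, 1]
        pi, pj = np.unravel_index(np.argmax(out[0]), (side, side))
        assert pi == pytest.approx(50 + dx, abs=0.6)
        assert pj == pytest.approx(50 + dy, abs=0.6)

    def test_rotation_of_symmetric_blob_is_noop(self):
        side = 60
        ii, jj = np.mgrid[0:side, 0:side].astype(float)
        blob = np.exp(-0.5 * (((ii - 30) / 5) ** 2 + ((jj - 30) / 5) ** 2))
        out, params = apply_subject_variation(
            blob.ravel()[None, :], (0.0, 45.0, 0.0), seed=1, grid_side=side
        )
        assert abs(params[0, 2]) > 1.0          # a real rotation was drawn
        assert np.max(np.abs(out[0] - blob.ravel())) < 0.02


class TestTimecourses:
    def test_boxcar_on_off_pattern(self):
        cfg = SimConfig()
        box = task_boxcar(cfg)
        assert box.size == 120
        assert box.sum() == 5 * 12              # n_blocks * block_on / tr
        expected = np.tile(np.r_[np.ones(12), np.zeros(12)], 5)
        assert np.array_equal(box, expected)

    def test_no_events_no_task_gives_flat_timecourse(self):
        cfg = SimConfig(unique_event_prob=0.0, task_sources=())
        tc = generate_timecourses(cfg, seed=0)
        assert np.allclose(tc, 0.0)

    def test_event_rate_matches_binomial_mean(self):
        # p = 0.2 over 120 TRs: 24 expected events per course
        cfg = SimConfig(task_sources=())
        counts = []
        for seed in range(300):
            _, events = generate_timecourses(cfg, seed=seed, return_events=True)
            counts.extend(events.sum(axis=0))
        assert np.mean(counts) == pytest.approx(24.0, abs=0.5)

    def test_task_source_follows_block_design(self):
        cfg = SimConfig(unique_event_prob=0.0)
        tc = generate_timecourses(cfg, seed=4)
        box = np.convolve(task_boxcar(cfg), canonical_hrf(cfg.tr))[:120]
        r = np.corrcoef(tc[:, 9], box)[0, 1]
        assert r > 0.999
        assert np.allclose(tc[:, 0], 0.0)       # non-task source has no events

    def test_determinism(self):
        cfg = SimConfig()
        assert np.array_equal(generate_timecourses(cfg, 7), generate_timecourses(cfg, 7))


class TestSynthesizeDataset:
    def test_study_scale_shapes(self):
        subjects, truth = synthesize_dataset(SimConfig(seed=3))
        assert len(subjects) == 20
        assert subjects[0].data.shape == (120, 148 * 148)
        assert truth.group_sources.shape == (12, 148 * 148)
        assert truth.subject_sources.shape == (20, 12, 148 * 148)
        assert truth.timecourses.shape == (20, 120, 12)

    def test_determinism_bit_identical(self, tiny_sim):
        cfg, subjects, truth = tiny_sim
        again, truth2 = synthesize_dataset(cfg)
        assert np.array_equal(subjects[0].data, again[0].data)
        assert np.array_equal(truth.subject_sources, truth2.subject_sources)
        assert np.array_equal(truth.variation_params, truth2.variation_params)

    def test_noiseless_limit_regression_recovers_sources(self):
        cfg = SimConfig(n_subjects=1, grid_side=36, n_sources=4, n_timepoints=60,
                        n_blocks=2, task_sources=(), cnr=math.inf, seed=8)
        subjects, truth = synthesize_dataset(cfg)
        X = truth.timecourses[0]
        beta, *_ = np.linalg.lstsq(X - X.mean(0), subjects[0].data - subjects[0].data.mean(0),
                                   rcond=None)
        for k in range(4):
            r = np.corrcoef(beta[k], truth.subject_sources[0][k])[0, 1]
            assert abs(r) > 0.999

    def test_cnr_ratio_realized(self, tiny_sim):
        cfg, subjects, truth = tiny_sim
        for i in [0, 1]:
            signal = truth.timecourses[i] @ truth.subject_sources[i]
            noise = subjects[i].data - cfg.baseline - signal
            inbrain = np.max(np.abs(truth.subject_sources[i]), axis=0) > 0.05
            fluct = signal[:, inbrain] - signal[:, inbrain].mean(axis=0)
            assert fluct.std() / noise.std() == pytest.approx(cfg.cnr, rel=0.02)

    def test_end_to_end_single_subject_ica_recovery(self):
        # zero variation, zero noise: plain ICA must recover every source
        cfg = SimConfig(n_subjects=1, grid_side=48, n_sources=5, n_timepoints=80,
                        n_blocks=1, task_sources=(), cnr=math.inf,
                        translation_sd=0, rotation_sd=0, scale_sd=0, seed=21)
        subjects, truth = synthesize_dataset(cfg)
        model = fastica(subjects[0].data, 5, seed=0)
        res = match_components(model.sources, truth.group_sources)
        assert all(abs(r) > 0.99 for r in res.correlations.values())
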