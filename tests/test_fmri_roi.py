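import numpy as np
import pytest

from vergefmri import (
    BoldRun,
    BoldRunSpec,
    bandpass_filter,
    compute_frame_displacement,
    extract_tissue_pcs,
    generate_bold_run,
    nuisance_regress,
    percent_signal_change,
    run_subject_roi_analysis,
    threshold_and_pool,
    voxel_correlation_map,
)
from vergefmri.fmri_roi import NuisanceSet


def tiny_run(seed=0, T=40, physio=None, noise=1.0):
    """Small hand-built run: 8 GM + 6 WM + 6 CSF voxels."""
    rng = np.random.default_rng(seed)
    n = 20
    signal = 100.0 + rng.normal(0, noise, (n, T))
    if physio is not None:
        loadings = rng.normal(0, 1.0, n)
        signal += np.outer(loadings, physio)
    tissue = np.zeros((n, 3))
    tissue[:8] = (0.95, 0.02, 0.02)
    tissue[8:14] = (0.01, 0.99, 0.0)
    tissue[14:] = (0.0, 0.0, 1.0)
    motion = rng.normal(0, 0.05, (T, 6))
    return BoldRun(signal, tissue, motion, 2.0)


class TestFrameDisplacement:
    def test_constant_motion_zero_displacement(self):
        fd = compute_frame_displacement(np.ones((10, 6)))
        assert np.allclose(fd.mean_abs, 0.0)
        assert np.allclose(fd.composite, 0.0)

    def test_single_parameter_arithmetic(self):
        motion = np.zeros((3, 6))
        motion[:, 0] = [0.0, 1.0, 3.0]
        fd = compute_frame_displacement(motion)
        assert fd.mean_abs[0] == pytest.approx(1.5)

    def test_spike_raises_composite_at_that_volume(self, study_timeline):
        spec = BoldRunSpec(motion_spikes=((30, 2.0),), n_gm_voxels=14,
                           n_csf_voxels=6, n_wm_voxels=6)
        run, _ = generate_bold_run(spec, study_timeline, seed=1)
        fd = compute_frame_displacement(run.motion)
        assert fd.composite[30] >= 2.0

    def test_spike_strictly_increases_composite(self, study_timeline):
        """QC soundness: adding a spike strictly raises FD at that volume."""
        base_spec = BoldRunSpec(n_gm_voxels=14, n_csf_voxels=6, n_wm_voxels=6)
        spike_spec = BoldRunSpec(motion_spikes=((25, 1.0),), n_gm_voxels=14,
                                 n_csf_voxels=6, n_wm_voxels=6)
        run0, _ = generate_bold_run(base_spec, study_timeline, seed=2)
        run1, _ = generate_bold_run(spike_spec, study_timeline, seed=2)
        fd0 = compute_frame_displacement(run0.motion)
        fd1 = compute_frame_displacement(run1.motion)
        assert fd1.composite[25] > fd0.composite[25]


class TestTissuePcs:
    def test_rank_one_sinusoid_dominates_pc1(self):
        T = 60
        t = np.arange(T)
        sine = np.sin(2 * np.pi * 0.2 * t)
        rng = np.random.default_rng(0)
        signal = 100.0 + np.outer(np.full(30, 1.0), sine) + rng.normal(0, 0.01, (30, T))
        tissue = np.zeros((30, 3))
        tissue[:15, 2] = 1.0  # CSF
        tissue[15:, 1] = 0.99  # WM
        run = BoldRun(signal, tissue, np.zeros((T, 6)), 2.0)
        nuis = extract_tissue_pcs(run, n_pcs=5)
        assert abs(np.corrcoef(nuis.wm_pcs[:, 0], sine)[0, 1]) > 0.99
        assert abs(np.corrcoef(nuis.csf_pcs[:, 0], sine)[0, 1]) > 0.99

    def test_default_set_has_sixteen_columns(self):
        run = tiny_run()
        nuis = extract_tissue_pcs(run, n_pcs=5)
        assert nuis.n_columns == 16
        # PC columns are zero-mean unit-norm and mutually orthogonal per tissue
        for pcs in (nuis.csf_pcs, nuis.wm_pcs):
            assert np.allclose(pcs.mean(axis=0), 0.0, atol=1e-10)
            gram = pcs.T @ pcs
            assert np.allclose(gram, np.eye(5), atol=1e-8)

    def test_impossible_threshold_errors_naming_tissue(self):
        run = tiny_run()
        with pytest.raises(ValueError, match="CSF"):
            extract_tissue_pcs(run, csf_thresh=1.01)


class TestNuisanceRegression:
    def test_motion_component_exactly_removed(self):
        T = 50
        rng = np.random.default_rng(1)
        nuis = NuisanceSet(
            motion=rng.normal(0, 1, (T, 6)),
            csf_pcs=np.linalg.qr(rng.normal(size=(T, 5)))[0],
            wm_pcs=np.linalg.qr(rng.normal(size=(T, 5)))[0],
        )
        nuis.motion -= nuis.motion.mean(axis=0)
        signal = (2.0 * nuis.motion[:, 0] + 100.0)[None, :]
        resid = nuisance_regress(signal, nuis)
        assert np.std(resid) < 1e-6 * np.std(signal)
        assert resid.mean() == pytest.approx(100.0)

    def test_orthogonal_signal_unchanged(self):
        T = 64
        rng = np.random.default_rng(2)
        M = rng.normal(size=(T, 20))
        M -= M.mean(axis=0)  # orthogonal to the intercept as well
        Q = np.linalg.qr(M)[0]
        nuis = NuisanceSet(motion=Q[:, :6], csf_pcs=Q[:, 6:11], wm_pcs=Q[:, 11:16])
        signal = (Q[:, 17] + 10.0)[None, :]  # orthogonal to all regressors
        resid = nuisance_regress(signal, nuis)
        assert np.allclose(resid, signal, atol=1e-10)

    def test_residuals_orthogonal_to_design(self):
        run = tiny_run(seed=3)
        nuis = extract_tissue_pcs(run, n_pcs=5)
        resid = nuisance_regress(run.signal, nuis) - run.signal.mean(1, keepdims=True)
        X = np.column_stack([np.ones(run.n_volumes), nuis.matrix])
        dots = np.abs(resid @ X)
        assert dots.max() < 1e-7

    def test_rank_deficiency_reported(self):
        T = 30
        col = np.linspace(-1, 1, T)
        nuis = NuisanceSet(
            motion=np.tile(col[:, None], (1, 6)),
            csf_pcs=np.linalg.qr(np.random.default_rng(0).normal(size=(T, 5)))[0],
            wm_pcs=np.linalg.qr(np.random.default_rng(1).normal(size=(T, 5)))[0],
        )
        with pytest.raises(ValueError, match="rank deficient"):
            nuisance_regress(np.zeros((1, T)), nuis)

    def test_protected_regressor_survives_cleaning(self):
        """Design protection retains the task component the confounds would
        otherwise absorb by chance."""
        T = 60
        rng = np.random.default_rng(4)
        task = np.sin(2 * np.pi * 0.025 * np.arange(T) * 2.0)
        nuis = NuisanceSet(
            motion=np.cumsum(rng.normal(0, 0.1, (T, 6)), axis=0),
            csf_pcs=np.linalg.qr(rng.normal(size=(T, 5)))[0],
            wm_pcs=np.linalg.qr(rng.normal(size=(T, 5)))[0],
        )
        nuis.motion -= nuis.motion.mean(axis=0)
        signal = (100.0 + 5.0 * task)[None, :]
        protected = nuisance_regress(signal, nuis, protect=task)
        amp = (protected[0] - protected.mean()) @ task / (task @ task)
        assert amp == pytest.approx(5.0, rel=0.02)


class TestBandpass:
    def test_task_fundamental_preserved(self):
        """0.025 Hz (the 40 s block cycle) passes with < 5% amplitude loss."""
        T, tr = 80, 2.0  # 160 s window: 0.025 Hz sits on a DFT bin
        t = np.arange(T) * tr
        x = np.sin(2 * np.pi * 0.025 * t)
        filt, _ = bandpass_filter(x, 0.01, 0.15, tr)
        assert np.abs(filt - x).max() < 0.05

    def test_out_of_band_sinusoid_attenuated(self):
        T, tr = 100, 2.0
        t = np.arange(T) * tr
        x = np.sin(2 * np.pi * 0.2 * t)
        filt, _ = bandpass_filter(x, 0.01, 0.15, tr)
        assert np.std(filt) < 0.1 * np.std(x)

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(np.zeros(50), 0.01, 0.3, 2.0)

    def test_constant_signal_zeroed_with_mean_retained(self):
        filt, mean = bandpass_filter(np.full(40, 7.0), 0.01, 0.15, 2.0)
        assert np.allclose(filt, 0.0, atol=1e-12)
        assert mean == pytest.approx(7.0)


class TestCorrelationMap:
    def test_voxel_equal_to_regressor(self):
        reg = np.sin(np.arange(30.0))
        signal = np.vstack([reg, -reg, np.full(30, 2.0)])
        r = voxel_correlation_map(signal, reg)
        assert r[0] == pytest.approx(1.0)
        assert r[1] == pytest.approx(-1.0)
        assert r[2] == 0.0  # constant voxel flagged to zero

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError):
            voxel_correlation_map(np.zeros((2, 10)), np.ones(10))


class TestPooling:
    def test_all_voxels_survive_gives_mask_mean(self):
        signal = np.arange(40, dtype=float).reshape(4, 10)
        mask = np.array([True, True, False, False])
        rmap = np.array([0.9, 0.8, 0.9, 0.1])
        pooled, n_in, n_pooled, fb = threshold_and_pool(rmap, signal, mask, 0.4)
        assert n_in == 2 and n_pooled == 2 and not fb
        assert np.array_equal(pooled, signal[:2].mean(axis=0))

    def test_half_survive_exact_mean_of_survivors(self):
        signal = np.arange(40, dtype=float).reshape(4, 10)
        mask = np.ones(4, bool)
        rmap = np.array([0.9, 0.1, 0.8, 0.2])
        pooled, _, n_pooled, _ = threshold_and_pool(rmap, signal, mask, 0.4)
        assert n_pooled == 2
        assert np.array_equal(pooled, signal[[0, 2]].mean(axis=0))

    def test_task_roi_empty_pool_falls_back_with_flag(self):
        signal = np.ones((3, 10))
        mask = np.ones(3, bool)
        rmap = np.zeros(3)
        pooled, _, n_pooled, fb = threshold_and_pool(rmap, signal, mask, 0.4, "FEF_L")
        assert fb and n_pooled == 0
        assert np.array_equal(pooled, np.ones(10))

    def test_control_roi_always_uses_full_mask(self):
        signal = np.arange(30, dtype=float).reshape(3, 10)
        mask = np.ones(3, bool)
        rmap = np.array([0.9, 0.0, 0.0])
        pooled, _, _, fb = threshold_and_pool(
            rmap, signal, mask, 0.4, "Broca_L", is_control=True
        )
        assert not fb
        assert np.array_equal(pooled, signal.mean(axis=0))

    def test_pool_size_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        rmap = rng.uniform(-1, 1, 50)
        signal = rng.normal(size=(50, 10)) + 100
        mask = np.ones(50, bool)
        sizes = [
            threshold_and_pool(rmap, signal, mask, th)[2]
            for th in np.linspace(-1, 1, 21)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            threshold_and_pool(np.zeros(3), np.ones((3, 5)), np.zeros(3, bool), 0.4)


class TestPercentSignalChange:
    def test_on_off_arithmetic(self, study_timeline):
        labels = study_timeline.phase_labels(2.0, 70, 0, 0.0)
        series = np.where(labels, 102.0, 100.0)
        psc = percent_signal_change(series, study_timeline, 2.0, 0, shift_s=0.0)
        assert psc == pytest.approx(2.0)

    def test_non_positive_baseline_rejected(self, study_timeline):
        labels = study_timeline.phase_labels(2.0, 70, 0, 0.0)
        series = np.where(labels, 1.0, -1.0)
        with pytest.raises(ValueError, match="mean-preserved"):
            percent_signal_change(series, study_timeline, 2.0, 0, shift_s=0.0)

    def test_single_phase_rejected(self, study_timeline):
        with pytest.raises(ValueError, match="phase"):
            # 5 volumes at the start are all fixation
            percent_signal_change(np.ones(5), study_timeline, 2.0, 0, shift_s=0.0)


@pytest.fixture(scope="module")
def subject(study_timeline):
    spec = BoldRunSpec(
        injected_psc={
            "FEF_L": 1.2, "FEF_R": 1.2, "PPC_L": 1.0, "PPC_R": 1.0,
            "CV": 0.8, "Broca_L": 0.0, "Broca_R": 0.0,
        }
    )
    runs, masks = [], None
    for seed in (10, 11, 12):
        run, masks = generate_bold_run(spec, study_timeline, seed=seed)
        runs.append(run)
    return runs, masks


class TestSubjectPipeline:
    def test_injected_psc_recovered(self, subject, study_timeline):
        runs, masks = subject
        res = run_subject_roi_analysis(runs, masks, study_timeline)
        for roi, injected in (("FEF_L", 1.2), ("PPC_L", 1.0), ("CV", 0.8)):
            assert res.results[roi].percent_signal_change == pytest.approx(
                injected, abs=0.2
            )

    def test_control_roi_stays_null(self, subject, study_timeline):
        runs, masks = subject
        res = run_subject_roi_analysis(runs, masks, study_timeline)
        for roi in ("Broca_L", "Broca_R"):
            assert abs(res.results[roi].percent_signal_change) < 0.3
            assert res.results[roi].correlation_with_design < 0.4

    def test_identical_inputs_identical_results(self, subject, study_timeline):
        runs, masks = subject
        a = run_subject_roi_analysis(runs, masks, study_timeline)
        b = run_subject_roi_analysis(runs, masks, study_timeline)
        for roi in a.results:
            assert (
                a.results[roi].percent_signal_change
                == b.results[roi].percent_signal_change
            )

    def test_stage_errors_name_the_run(self, subject, study_timeline):
        runs, masks = subject
        with pytest.raises(ValueError, match="run 0"):
            run_subject_roi_analysis(runs, masks, study_timeline, csf_thresh=1.01)
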