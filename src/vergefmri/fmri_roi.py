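"""ROI-based BOLD percent-signal-change pipeline.

Given a voxel-by-time BOLD run, rigid-body motion parameters, tissue
probability maps, and ROI masks, the pipeline

1. drops the first volumes (scanner transient),
2. computes frame-displacement motion QC,
3. extracts CompCor-style nuisance regressors (top principal components of
   high-confidence CSF and WM voxel time series) and combines them with the
   six motion parameters,
4. regresses the 16 nuisance regressors out of every voxel,
5. band-pass filters the residuals (0.01-0.15 Hz),
6. correlates each voxel with the HRF-convolved block regressor,
7. pools mask voxels with r >= 0.4 into one ROI time series, and
8. computes the percent signal change of the vergence task relative to
   sustained fixation.

Anatomical preprocessing (motion correction, brain extraction, segmentation)
is upstream: motion parameters and tissue probabilities are inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hrf import build_design_regressor
from .timeline import DesignTimeline

logger = logging.getLogger(__name__)

TASK_ROIS = ("FEF_L", "FEF_R", "PPC_L", "PPC_R", "CV")
CONTROL_ROIS = ("Broca_L", "Broca_R")
ALL_ROIS = TASK_ROIS + CONTROL_ROIS


@dataclass
class BoldRun:
    """Voxel-by-time BOLD matrix with tissue labels and motion series.

    ``tissue_probs`` columns are (GM, WM, CSF) probabilities in [0, 1];
    ``motion`` columns are 3 translations (mm) then 3 rotations (deg) per
    volume.
    """

    signal: np.ndarray  # (n_voxels, n_volumes)
    tissue_probs: np.ndarray  # (n_voxels, 3): gm, wm, csf
    motion: np.ndarray  # (n_volumes, 6)
    tr: float
    coords: np.ndarray | None = None  # (n_voxels, 3) integer grid coordinates

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, float)
        self.tissue_probs = np.asarray(self.tissue_probs, float)
        self.motion = np.asarray(self.motion, float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be (n_voxels, n_volumes)")
        if self.tissue_probs.shape != (self.signal.shape[0], 3):
            raise ValueError("tissue_probs must be (n_voxels, 3)")
        if self.tissue_probs.min() < 0 or self.tissue_probs.max() > 1:
            raise ValueError("tissue probabilities must lie in [0, 1]")
        if self.motion.shape != (self.signal.shape[1], 6):
            raise ValueError("motion must be (n_volumes, 6)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_voxels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[1]

    def trimmed(self, n_drop: int) -> "BoldRun":
        """Remove the first ``n_drop`` volumes from data and motion alike."""
        if not 0 <= n_drop < self.n_volumes:
            raise ValueError("n_drop must be in [0, n_volumes)")
        return BoldRun(
            self.signal[:, n_drop:],
            self.tissue_probs,
            self.motion[n_drop:],
            self.tr,
            self.coords,
        )


@dataclass
class FrameDisplacementReport:
    """Mean absolute frame-to-frame change per motion parameter, plus a
    per-volume composite (sum of the six absolute changes)."""

    param_names: tuple[str, ...]
    mean_abs: np.ndarray  # (6,)
    sd_abs: np.ndarray  # (6,)
    composite: np.ndarray  # (n_volumes,), first volume 0

    def as_dict(self) -> dict:
        return {
            name: {"mean": float(m), "sd": float(s)}
            for name, m, s in zip(self.param_names, self.mean_abs, self.sd_abs)
        }


@dataclass
class NuisanceSet:
    """The 16 nuisance regressors: 6 motion + 5 CSF PCs + 5 WM PCs."""

    motion: np.ndarray  # (T, 6), demeaned
    csf_pcs: np.ndarray  # (T, n_pcs), zero-mean unit-norm
    wm_pcs: np.ndarray  # (T, n_pcs)

    @property
    def matrix(self) -> np.ndarray:
        return np.column_stack([self.motion, self.csf_pcs, self.wm_pcs])

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


@dataclass
class RoiResult:
    roi: str
    n_voxels_in_mask: int
    n_voxels_pooled: int
    percent_signal_change: float
    correlation_with_design: float
    pooled_series: np.ndarray | None = None
    empty_pool_fallback: bool = False

    def __post_init__(self) -> None:
        if self.n_voxels_pooled > self.n_voxels_in_mask:
            raise ValueError("pooled voxels cannot exceed mask voxels")
        if not np.isfinite(self.percent_signal_change):
            raise ValueError("percent signal change must be finite")


def compute_frame_displacement(motion: np.ndarray) -> FrameDisplacementReport:
    """Absolute frame-to-frame displacement of the six rigid-body parameters."""
    motion = np.asarray(motion, float)
    if motion.ndim != 2 or motion.shape[1] != 6 or motion.shape[0] < 2:
        raise ValueError("motion must be (n_volumes >= 2, 6)")
    d = np.abs(np.diff(motion, axis=0))  # (T-1, 6)
    composite = np.concatenate([[0.0], d.sum(axis=1)])
    names = ("trans_x", "trans_y", "trans_z", "rot_yaw", "rot_pitch", "rot_roll")
    return FrameDisplacementReport(
        names, d.mean(axis=0), d.std(axis=0, ddof=0), composite
    )


def _principal_components(X: np.ndarray, n_pcs: int) -> np.ndarray:
    """Top temporal principal components of voxel time series.

    ``X`` is (n_voxels, T); rows are demeaned and the temporal components
    (right singular vectors, ordered by explained variance) are returned as
    zero-mean unit-norm columns (T, n_pcs).
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    pcs = vt[:n_pcs].T
    pcs = pcs - pcs.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(pcs, axis=0)
    norms[norms == 0] = 1.0
    return pcs / norms


def extract_tissue_pcs(
    run: BoldRun,
    csf_thresh: float = 0.99,
    wm_thresh: float = 0.97,
    n_pcs: int = 5,
) -> NuisanceSet:
    """CompCor nuisance set: motion + top PCs of high-confidence CSF/WM voxels.

    Voxels with tissue probability >= threshold (99% CSF, 97% WM by default)
    are selected; the first ``n_pcs`` principal components of each tissue's
    time-series set become nuisance regressors.
    """
    gm, wm, csf = run.tissue_probs.T
    cols = {}
    for name, probs, thresh in (("CSF", csf, csf_thresh), ("WM", wm, wm_thresh)):
        sel = probs >= thresh
        if sel.sum() < n_pcs:
            raise ValueError(
                f"only {int(sel.sum())} {name} voxels survive the "
                f"{thresh:.2f} probability threshold; need >= {n_pcs}"
            )
        cols[name] = _principal_components(run.signal[sel], n_pcs)
    motion = run.motion - run.motion.mean(axis=0, keepdims=True)
    return NuisanceSet(motion=motion, csf_pcs=cols["CSF"], wm_pcs=cols["WM"])


def nuisance_regress(
    signal: np.ndarray,
    nuisance: NuisanceSet,
    protect: np.ndarray | None = None,
) -> np.ndarray:
    """OLS removal of the nuisance regressors from every voxel.

    Fits each voxel's series on [intercept | 16 regressors] and returns the
    residual with the voxel mean re-added, so percent signal change remains
    computable downstream.

    ``protect`` optionally supplies task regressors (columns) to estimate
    jointly with the confounds and retain in the output.  Over a short run,
    smooth confounds absorb task variance by chance if removed sequentially,
    biasing the task amplitude toward zero; joint estimation with design
    protection is the standard task-fMRI remedy and removes only the
    confound contribution.
    """
    Y = np.asarray(signal, float)
    cols = [np.ones(Y.shape[1]), nuisance.matrix]
    n_protect = 0
    if protect is not None:
        P = np.atleast_2d(np.asarray(protect, float))
        if P.shape[0] == Y.shape[1]:
            P = P.T
        n_protect = P.shape[0]
        cols.append(P.T)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify near-collinear columns via the QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [i for i, d in enumerate(diag) if d < 1e-8 * diag.max()]
        raise ValueError(f"nuisance design is rank deficient (columns {bad})")
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ beta).T
    if n_protect:
        # re-add the jointly estimated task contribution
        resid = resid + (X[:, -n_protect:] @ beta[-n_protect:]).T
    return resid + Y.mean(axis=1, keepdims=True)


def bandpass_filter(
    signal: np.ndarray,
    low_hz: float,
    high_hz: float,
    tr: float,
    taper_frac: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-domain band-pass with Gaussian-tapered edges.

    The spectral mask is 1 inside [low, high] and rolls off outside each
    cutoff with a Gaussian whose FWHM is ``taper_frac`` of that cutoff.  DC
    is removed; the voxel means are returned separately so percent-change
    computations can re-add them.

    Returns ``(filtered, means)`` where ``filtered`` has zero mean per voxel.
    """
    signal = np.asarray(signal, float)
    Y = np.atleast_2d(signal)
    T = Y.shape[1]
    nyq = 1.0 / (2.0 * tr)
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low < high")
    if high_hz > nyq + 1e-12:
        raise ValueError(f"high cutoff {high_hz} Hz exceeds Nyquist {nyq} Hz")

    means = Y.mean(axis=1, keepdims=True)
    freqs = np.fft.rfftfreq(T, d=tr)
    mask = np.ones_like(freqs)

    def sigma(cut: float) -> float:
        fwhm = taper_frac * cut
        return max(fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))), 1e-12)

    if low_hz > 0:
        lo = freqs < low_hz
        mask[lo] = np.exp(-0.5 * ((freqs[lo] - low_hz) / sigma(low_hz)) ** 2)
    hi = freqs > high_hz
    mask[hi] = np.exp(-0.5 * ((freqs[hi] - high_hz) / sigma(high_hz)) ** 2)
    mask[0] = 0.0  # DC always removed

    spec = np.fft.rfft(Y - means, axis=1)
    filt = np.fft.irfft(spec * mask, n=T, axis=1)
    if signal.ndim == 1:
        return filt[0], means[0]
    return filt, means


def voxel_correlation_map(signal: np.ndarray, regressor: np.ndarray) -> np.ndarray:
    """Pearson r between every voxel's series and the design regressor.

    Constant voxels get r = 0 (flagged via a log message).
    """
    Y = np.asarray(signal, float)
    x = np.asarray(regressor, float)
    if np.ptp(x) == 0:
        raise ValueError("design regressor is constant")
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ys = np.linalg.norm(Yc, axis=1)
    const = ys == 0
    ys[const] = 1.0
    r = (Yc @ xc) / (ys * np.linalg.norm(xc))
    if const.any():
        logger.warning("%d constant voxels assigned r = 0", int(const.sum()))
        r[const] = 0.0
    return r


def threshold_and_pool(
    rmap: np.ndarray,
    signal: np.ndarray,
    mask: np.ndarray,
    r_thresh: float = 0.4,
    roi: str = "",
    is_control: bool = False,
) -> tuple[np.ndarray, int, int, bool]:
    """Average mask voxels whose design correlation reaches ``r_thresh``.

    Control ROIs (non-stimulated by design) always pool the full mask; task
    ROIs fall back to the full-mask mean with a warning when no voxel
    survives.

    Returns (pooled series, n_in_mask, n_pooled, fallback_used).
    """
    mask = np.asarray(mask, bool)
    n_in_mask = int(mask.sum())
    if n_in_mask == 0:
        raise ValueError(f"ROI mask {roi!r} is empty")
    surviving = mask & (np.asarray(rmap) >= r_thresh)
    n_pooled = int(surviving.sum())
    fallback = False
    if is_control or n_pooled == 0:
        if not is_control:
            logger.warning(
                "ROI %s: no voxels reach r >= %.2f; falling back to full-mask mean",
                roi, r_thresh,
            )
            fallback = True
        pooled = signal[mask].mean(axis=0)
        n_pooled = n_pooled if is_control else 0
    else:
        pooled = signal[surviving].mean(axis=0)
    return pooled, n_in_mask, n_pooled, fallback


def percent_signal_change(
    pooled: np.ndarray,
    timeline: DesignTimeline,
    tr: float,
    n_drop: int = 0,
    shift_s: float = 4.0,
) -> float:
    """PSC = 100 * (movement mean - fixation mean) / fixation mean.

    Volumes are assigned to phases after shifting the timeline by the
    hemodynamic delay ``shift_s`` (default 4 s = 2 volumes at TR 2 s), so the
    delayed BOLD response is credited to the phase that evoked it.  The
    pooled series must be mean-preserved (positive baseline).
    """
    pooled = np.asarray(pooled, float)
    n_volumes = n_drop + pooled.size
    labels = timeline.phase_labels(tr, n_volumes, n_drop, shift_s)
    if labels.all() or not labels.any():
        raise ValueError("both phase types must be present after trimming")
    on = pooled[labels].mean()
    off = pooled[~labels].mean()
    if off <= 0:
        raise ValueError(
            "fixation-phase mean is not positive; pass a mean-preserved series"
        )
    return float(100.0 * (on - off) / off)


@dataclass
class SubjectRoiAnalysis:
    """Per-ROI results for one subject (runs averaged at the PSC level)."""

    results: dict[str, RoiResult]
    frame_displacement: list[FrameDisplacementReport]
    per_run: list[dict[str, RoiResult]] = field(default_factory=list)


def _analyze_single_run(
    run: BoldRun,
    masks: dict[str, np.ndarray],
    timeline: DesignTimeline,
    *,
    n_drop: int,
    band: tuple[float, float],
    r_thresh: float,
    csf_thresh: float,
    wm_thresh: float,
    n_pcs: int,
    shift_s: float,
) -> tuple[dict[str, RoiResult], FrameDisplacementReport]:
    trimmed = run.trimmed(n_drop)
    fd = compute_frame_displacement(trimmed.motion)
    nuisance = extract_tissue_pcs(trimmed, csf_thresh, wm_thresh, n_pcs)
    regressor = build_design_regressor(timeline, run.tr, n_drop)
    cleaned = nuisance_regress(trimmed.signal, nuisance, protect=regressor)
    filtered, means = bandpass_filter(cleaned, band[0], band[1], run.tr)
    mean_preserved = filtered + means
    rmap = voxel_correlation_map(filtered, regressor)

    results: dict[str, RoiResult] = {}
    for roi, mask in masks.items():
        is_control = roi in CONTROL_ROIS
        pooled, n_in, n_pooled, fallback = threshold_and_pool(
            rmap, mean_preserved, mask, r_thresh, roi, is_control
        )
        psc = percent_signal_change(pooled, timeline, run.tr, n_drop, shift_s)
        pooled_r = float(
            np.corrcoef(pooled - pooled.mean(), regressor - regressor.mean())[0, 1]
        ) if np.ptp(pooled) > 0 else 0.0
        results[roi] = RoiResult(
            roi, n_in, n_pooled, psc, pooled_r,
            pooled_series=pooled, empty_pool_fallback=fallback,
        )
    return results, fd


def run_subject_roi_analysis(
    runs,
    masks: dict[str, np.ndarray],
    timeline: DesignTimeline,
    *,
    n_drop: int = 5,
    band: tuple[float, float] = (0.01, 0.15),
    r_thresh: float = 0.4,
    csf_thresh: float = 0.99,
    wm_thresh: float = 0.97,
    n_pcs: int = 5,
    shift_s: float = 4.0,
) -> SubjectRoiAnalysis:
    """Full pipeline over a subject's repeated runs, averaged at the PSC level.

    The experiment is repeated (three runs per subject in the study design);
    each run is processed independently and per-ROI percent signal changes
    and design correlations are averaged across runs.
    """
    if isinstance(runs, BoldRun):
        runs = [runs]
    per_run: list[dict[str, RoiResult]] = []
    fds: list[FrameDisplacementReport] = []
    for i, run in enumerate(runs):
        try:
            res, fd = _analyze_single_run(
                run, masks, timeline,
                n_drop=n_drop, band=band, r_thresh=r_thresh,
                csf_thresh=csf_thresh, wm_thresh=wm_thresh,
                n_pcs=n_pcs, shift_s=shift_s,
            )
        except ValueError as exc:
            raise ValueError(f"run {i}: {exc}") from exc
        per_run.append(res)
        fds.append(fd)

    averaged: dict[str, RoiResult] = {}
    for roi in masks:
        rs = [pr[roi] for pr in per_run]
        averaged[roi] = RoiResult(
            roi,
            rs[0].n_voxels_in_mask,
            int(round(np.mean([r.n_voxels_pooled for r in rs]))),
            float(np.mean([r.percent_signal_change for r in rs])),
            float(np.mean([r.correlation_with_design for r in rs])),
            pooled_series=None,
            empty_pool_fallback=any(r.empty_pool_fallback for r in rs),
        )
    return SubjectRoiAnalysis(averaged, fds, per_run)
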