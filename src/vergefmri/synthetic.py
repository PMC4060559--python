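"""Synthetic cohort generator with known ground truth.

Emulates the study's raw data so every downstream stage can be validated
against injected values:

* binocular vergence step trials (logistic position profile whose analytic
  maximum slope is the injected peak velocity, with optional blink dropouts
  and conjugate saccadic transients), emitted in voltage units through an
  inverse per-eye calibration;
* block-design BOLD runs (voxel-by-time) whose ROI voxels carry an injected
  percent signal change on top of baseline, drift, shared "physiological"
  sinusoids (also present in CSF/WM voxels, so tissue-PC regression can
  remove them), and white noise, plus a rigid-body motion series;
* whole cohorts of BNC / CI-pre / CI-post subjects whose peak-velocity and
  PSC ground truths are drawn so the pooled across-subject brain-behavior
  correlation targets a configured value, with CI post rows paired to pre
  rows through shared subject-level latents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import math

import numpy as np
import pandas as pd
from scipy.special import expit

from .eye_movement import CalibrationModel, EyeMovementTrial
from .group_stats import CISS_ITEM_MAX, CISS_N_ITEMS
from .fmri_roi import ALL_ROIS, BoldRun
from .hrf import build_design_regressor
from .timeline import DesignTimeline, generate_block_timeline

logger = logging.getLogger(__name__)

#: Sentinel monocular position (deg) written during a blink; beyond the
#: tracker's 25 deg linear range, so blink detection flags it.
BLINK_SENTINEL_DEG = 30.0

#: logistic position profile: fraction of the step completed within the
#: nominal rise window (1% .. 99%)
_LOGISTIC_99 = math.log(99.0)

ROI_PAIRS = ("FEF", "PPC", "CV", "Broca")


# ---------------------------------------------------------------------------
# eye-movement trials
# ---------------------------------------------------------------------------

@dataclass
class VergenceResponseSpec:
    """Parameters of one synthetic symmetric convergence step response."""

    amplitude_deg: float = 4.0
    peak_velocity: float = 20.0  # deg/s; analytic max of the vergence profile
    latency_s: float = 0.2
    duration_s: float = 3.0
    sample_rate: float = 200.0
    stim_onset_s: float = 0.5
    blink_times: tuple[float, ...] = ()
    saccade_times: tuple[float, ...] = ()
    noise_sd_deg: float = 0.01  # monocular white position noise
    saccade_velocity_ratio: float = 12.0  # monocular saccade peak / vergence peak

    def __post_init__(self) -> None:
        if self.amplitude_deg <= 0:
            raise ValueError("amplitude must be positive")
        if self.peak_velocity <= 0:
            raise ValueError("peak velocity must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")
        if self.latency_s < 0:
            raise ValueError("latency must be >= 0")

    @property
    def logistic_rate(self) -> float:
        """Slope parameter k of the logistic; max slope = amplitude*k/4."""
        return 4.0 * self.peak_velocity / self.amplitude_deg

    @property
    def peak_time_s(self) -> float:
        """Time of the maximum vergence velocity (logistic midpoint)."""
        return self.stim_onset_s + self.latency_s + _LOGISTIC_99 / self.logistic_rate

    @property
    def movement_end_s(self) -> float:
        """Time by which 99% of the step is complete."""
        return self.peak_time_s + _LOGISTIC_99 / self.logistic_rate


def generate_vergence_trial(
    spec: VergenceResponseSpec,
    calibration: CalibrationModel,
    seed: int,
    trial_id: str = "",
) -> EyeMovementTrial:
    """Synthesize one binocular step-response recording in voltage units.

    The vergence difference (left - right) follows a logistic step of the
    requested amplitude whose analytic maximum derivative equals the
    requested peak velocity.  Blinks saturate both channels beyond the
    tracker range for 100-300 ms; saccades add a conjugate (same-sign)
    raised-cosine transient an order of magnitude faster than the vergence
    profile.  Channels are emitted as volts via the inverse calibration.
    """
    if spec.movement_end_s > spec.duration_s:
        raise ValueError(
            f"peak velocity {spec.peak_velocity} deg/s is infeasible: the "
            f"{spec.amplitude_deg} deg step would not complete within "
            f"{spec.duration_s} s"
        )
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * spec.sample_rate)) + 1
    t = np.arange(n) / spec.sample_rate

    k = spec.logistic_rate
    s = expit(k * (t - spec.peak_time_s))
    half = spec.amplitude_deg / 2.0
    left = half * s + rng.normal(0.0, spec.noise_sd_deg, n)
    right = -half * s + rng.normal(0.0, spec.noise_sd_deg, n)

    # conjugate saccadic transients: same sign in both eyes, cancelling in the
    # vergence difference but dominating the monocular velocity
    sacc_peak_vel = spec.saccade_velocity_ratio * spec.peak_velocity
    sacc_dur = 0.03  # s, typical small-saccade duration
    sacc_amp = sacc_peak_vel * 2.0 * sacc_dur / math.pi
    for ts in spec.saccade_times:
        rel = (t - ts) / sacc_dur
        pulse = np.where(
            rel <= 0, 0.0, np.where(rel >= 1, 1.0, 0.5 * (1 - np.cos(math.pi * rel)))
        )
        left += sacc_amp * pulse
        right += sacc_amp * pulse

    # blinks: limbus trackers lose the signal during lid closure; model as
    # saturation to an out-of-range sentinel
    for tb in spec.blink_times:
        dur = rng.uniform(0.1, 0.3)
        sel = (t >= tb) & (t < tb + dur)
        left[sel] = BLINK_SENTINEL_DEG
        right[sel] = -BLINK_SENTINEL_DEG

    left_v, right_v = calibration.to_volts(left, right)
    obstructing = any(
        abs(ts - spec.peak_time_s) <= 0.1 for ts in spec.saccade_times
    )
    truth = {
        "peak_velocity": spec.peak_velocity,
        "amplitude_deg": spec.amplitude_deg,
        "has_blink": bool(spec.blink_times),
        "saccade_obstructing": bool(spec.saccade_times) and obstructing,
        "has_saccade": bool(spec.saccade_times),
    }
    return EyeMovementTrial(
        t, left_v, right_v, spec.sample_rate, "volts",
        trial_id, spec.stim_onset_s, truth=truth,
    )


def make_calibration_table(
    calibration: CalibrationModel,
    angles_deg=(2.0, 4.0, 6.0, 8.0),
    n_repeats: int = 2,
    noise_v: float = 0.003,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic fixation records (angle_deg, left_v, right_v).

    At a symmetric vergence angle theta the left eye sits at +theta/2 and the
    right eye at -theta/2; voltages come from the inverse calibration plus
    acquisition noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_repeats):
        for a in angles_deg:
            lv, rv = calibration.to_volts(a / 2.0, -a / 2.0)
            rows.append(
                (a, lv + rng.normal(0, noise_v), rv + rng.normal(0, noise_v))
            )
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# BOLD runs
# ---------------------------------------------------------------------------

@dataclass
class BoldRunSpec:
    """Parameters of one synthetic block-design BOLD run."""

    n_volumes: int = 70
    tr: float = 2.0
    n_gm_voxels: int = 210  # split evenly across the seven ROI footprints
    n_csf_voxels: int = 50
    n_wm_voxels: int = 60
    injected_psc: dict = field(default_factory=dict)  # roi -> % signal change
    shared_physio_components: int = 2
    motion_spikes: tuple = ()  # (volume, magnitude mm)
    baseline: float = 1000.0
    noise_sd: float = 3.0  # BOLD units per voxel
    drift_amplitude: float = 5.0
    physio_amplitude: float = 3.0
    # convention used to scale the injected response so the analysis-side PSC
    # definition (trim + hemodynamic shift) recovers the injected value
    n_drop_convention: int = 5
    shift_convention_s: float = 4.0

    def __post_init__(self) -> None:
        if self.n_volumes < 10:
            raise ValueError("need n_volumes >= 10")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        for roi, v in self.injected_psc.items():
            if not np.isfinite(v):
                raise ValueError(f"injected PSC for {roi} must be finite")
            if roi not in ALL_ROIS:
                raise ValueError(f"unknown ROI {roi!r}")


def _grid_coords(n: int) -> np.ndarray:
    side = int(np.ceil(n ** (1.0 / 3.0)))
    idx = np.arange(n)
    return np.column_stack(
        [idx % side, (idx // side) % side, idx // (side * side)]
    ).astype(int)


def generate_bold_run(
    spec: BoldRunSpec,
    timeline: DesignTimeline,
    seed: int,
) -> tuple[BoldRun, dict[str, np.ndarray]]:
    """Synthesize one BOLD run and its ROI masks.

    GM voxels inside each ROI footprint carry
    ``baseline * (1 + psc/100 * response)`` where ``response`` is the
    HRF-convolved boxcar scaled so the analysis-side percent-signal-change
    definition recovers the injected value exactly on clean data; all voxels
    additionally carry linear + slow sinusoidal drift, shared physiological
    sinusoids (strong in CSF/WM), and white noise.
    """
    if timeline.n_volumes(spec.tr) != spec.n_volumes:
        raise ValueError(
            f"timeline duration {timeline.total_duration_s} s is inconsistent "
            f"with {spec.n_volumes} volumes at TR {spec.tr} s"
        )
    rng = np.random.default_rng(seed)
    T = spec.n_volumes
    tv = (np.arange(T) + 0.5) * spec.tr

    # injected response shape, normalized under the analysis convention
    x = build_design_regressor(timeline, spec.tr, n_drop=0)
    labels = timeline.phase_labels(
        spec.tr, T, spec.n_drop_convention, spec.shift_convention_s
    )
    x_trim = x[spec.n_drop_convention:]
    m_on, m_off = x_trim[labels].mean(), x_trim[~labels].mean()
    response = (x - m_off) / (m_on - m_off)

    n_roi = len(ALL_ROIS)
    per_roi = spec.n_gm_voxels // n_roi
    if per_roi < 1:
        raise ValueError("n_gm_voxels must cover at least one voxel per ROI")
    roi_of_gm: list[str | None] = []
    for roi in ALL_ROIS:
        roi_of_gm.extend([roi] * per_roi)
    roi_of_gm.extend([None] * (spec.n_gm_voxels - per_roi * n_roi))

    n_total = spec.n_gm_voxels + spec.n_csf_voxels + spec.n_wm_voxels
    signal = np.empty((n_total, T))
    tissue = np.zeros((n_total, 3))

    # shared physiological components (aliased cardiac/respiratory range)
    freqs = [0.2, 0.3, 0.12, 0.17][: max(spec.shared_physio_components, 0)]
    physio = np.array(
        [np.sin(2 * np.pi * f * tv + rng.uniform(0, 2 * np.pi)) for f in freqs]
    ) if freqs else np.zeros((0, T))

    def drift() -> np.ndarray:
        slope = rng.uniform(-1, 1) * spec.drift_amplitude / (T * spec.tr)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0) * spec.drift_amplitude
        return slope * (tv - tv.mean()) + amp * np.sin(2 * np.pi * 0.005 * tv + phase)

    row = 0
    for roi in roi_of_gm:
        psc = spec.injected_psc.get(roi, 0.0) if roi else 0.0
        task = spec.baseline * (1.0 + psc / 100.0 * response)
        loadings = rng.normal(0.0, spec.physio_amplitude, physio.shape[0])
        signal[row] = (
            task + drift() + loadings @ physio
            + rng.normal(0.0, spec.noise_sd, T)
        )
        tissue[row] = (0.96, 0.02, 0.02)
        row += 1
    for _ in range(spec.n_csf_voxels):
        loadings = rng.normal(0.0, 2.0 * spec.physio_amplitude, physio.shape[0])
        signal[row] = (
            0.6 * spec.baseline + drift() + loadings @ physio
            + rng.normal(0.0, spec.noise_sd, T)
        )
        tissue[row] = (0.0, 0.0, 0.995)
        row += 1
    for _ in range(spec.n_wm_voxels):
        loadings = rng.normal(0.0, 2.0 * spec.physio_amplitude, physio.shape[0])
        signal[row] = (
            0.8 * spec.baseline + drift() + loadings @ physio
            + rng.normal(0.0, spec.noise_sd, T)
        )
        tissue[row] = (0.01, 0.98, 0.01)
        row += 1

    # rigid-body motion: slow random walk, translations (mm) then rotations (deg)
    steps = rng.normal(0.0, 1.0, (T, 6)) * np.array(
        [0.02, 0.02, 0.02, 0.01, 0.01, 0.01]
    )
    motion = np.cumsum(steps, axis=0)
    for vol, mag in spec.motion_spikes:
        motion[int(vol), 0] += mag

    masks = {
        roi: np.array([r == roi for r in roi_of_gm] + [False] * (n_total - len(roi_of_gm)))
        for roi in ALL_ROIS
    }
    run = BoldRun(signal, tissue, motion, spec.tr, coords=_grid_coords(n_total))
    return run, masks


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _default_pv_mean() -> dict:
    return {"BNC": 20.0, "CI-pre": 11.0, "CI-post": 16.0}


def _default_pv_sd() -> dict:
    return {"BNC": 3.0, "CI-pre": 2.5, "CI-post": 2.5}


def _default_psc_mean() -> dict:
    return {
        "BNC": {"FEF": 1.2, "PPC": 1.0, "CV": 0.8, "Broca": 0.0},
        "CI-pre": {"FEF": 0.55, "PPC": 0.45, "CV": 0.35, "Broca": 0.0},
        "CI-post": {"FEF": 1.0, "PPC": 0.85, "CV": 0.65, "Broca": 0.0},
    }


def _default_psc_sd() -> dict:
    return {"FEF": 0.25, "PPC": 0.22, "CV": 0.20, "Broca": 0.10}


def _default_ciss_target() -> dict:
    return {"BNC": 6.0, "CI-pre": 32.0, "CI-post": 14.0}


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort (7 BNC, 4 CI by default)."""

    n_bnc: int = 7
    n_ci: int = 4
    peak_velocity_mean: dict = field(default_factory=_default_pv_mean)
    peak_velocity_sd: dict = field(default_factory=_default_pv_sd)
    psc_mean: dict = field(default_factory=_default_psc_mean)
    psc_sd: dict = field(default_factory=_default_psc_sd)
    behavior_bold_correlation: float = 0.6  # pooled across-subject target r
    hemi_jitter_sd: float = 0.05  # left/right PSC asymmetry, %
    paired_jitter_pv_sd: float = 0.8  # deg/s, pre->post subject noise
    paired_jitter_psc_sd: float = 0.08  # %, pre->post subject noise
    noise_sd: float = 3.0  # BOLD units
    drift_amplitude: float = 5.0
    physio_amplitude: float = 3.0
    baseline: float = 1000.0
    n_gm_voxels: int = 210
    n_csf_voxels: int = 50
    n_wm_voxels: int = 60
    trials_per_subject: int = 40
    trial_pv_sd: float = 1.5  # deg/s trial-to-trial peak-velocity spread
    n_runs: int = 3
    blink_rate: float = 0.02
    saccade_obstruct_rate: float = 0.08
    saccade_clear_rate: float = 0.05
    ciss_target: dict = field(default_factory=_default_ciss_target)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bnc < 1 or self.n_ci < 1:
            raise ValueError("cohort counts must be >= 1")
        if abs(self.behavior_bold_correlation) > 1:
            raise ValueError("|behavior_bold_correlation| must be <= 1")
        for d in (self.peak_velocity_sd, self.psc_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("standard deviations must be >= 0")
        if min(self.noise_sd, self.drift_amplitude, self.physio_amplitude) < 0:
            raise ValueError("noise magnitudes must be >= 0")

    @property
    def conditions(self) -> list[tuple[str, int]]:
        return [("BNC", self.n_bnc), ("CI-pre", self.n_ci), ("CI-post", self.n_ci)]


def _within_group_rho(spec: CohortSpec, roi: str) -> float:
    """Within-group latent correlation that makes the POOLED peak-velocity /
    PSC correlation hit the configured target.

    Group means co-vary (slower groups also show weaker activation), so the
    pooled correlation exceeds the within-group one; this solves for the
    within-group value from the group-mean geometry and the configured
    spreads.  The control ROI targets r = 0.
    """
    target = 0.0 if roi == "Broca" else spec.behavior_bold_correlation
    conds = spec.conditions
    n_total = sum(n for _, n in conds)
    w = np.array([n / n_total for _, n in conds])
    a = np.array([spec.peak_velocity_mean[g] for g, _ in conds])
    b = np.array([spec.psc_mean[g][roi] for g, _ in conds])
    sig = np.array([spec.peak_velocity_sd[g] for g, _ in conds], float)
    tau = np.full(len(conds), spec.psc_sd[roi], float)
    extra_pv = np.array(
        [spec.paired_jitter_pv_sd**2 if g == "CI-post" else 0.0 for g, _ in conds]
    )
    extra_psc = np.array(
        [spec.paired_jitter_psc_sd**2 if g == "CI-post" else 0.0 for g, _ in conds]
    )
    hemi = 0.0 if roi == "CV" else spec.hemi_jitter_sd**2 / 2.0

    abar, bbar = w @ a, w @ b
    var_a = float(w @ ((a - abar) ** 2 + sig**2 + extra_pv))
    var_b = float(w @ ((b - bbar) ** 2 + tau**2 + extra_psc + hemi))
    cov_between = float(w @ ((a - abar) * (b - bbar)))
    denom = float(w @ (sig * tau))
    if denom == 0:
        return 0.0
    rho = (target * math.sqrt(var_a * var_b) - cov_between) / denom
    if abs(rho) > 0.999:
        logger.warning(
            "ROI %s: pooled correlation target %.2f needs within-group rho "
            "%.2f; clamping to +/-0.999", roi, target, rho,
        )
        rho = math.copysign(0.999, rho)
    return rho


@dataclass
class SubjectData:
    """Raw synthetic data bundle for one subject-condition."""

    subject_id: str
    group: str
    condition: str
    calibration: CalibrationModel
    calibration_table: np.ndarray
    trials: list[EyeMovementTrial]
    bold_runs: list[BoldRun]
    masks: dict[str, np.ndarray]
    truth: dict


@dataclass
class Cohort:
    spec: CohortSpec
    timeline: DesignTimeline
    truth_table: pd.DataFrame
    subjects: list[SubjectData] | None = None


def _ciss_items(rng: np.random.Generator, target_total: float) -> np.ndarray:
    """15 survey items (0-4) whose expected total equals the target score."""
    p = min(max(target_total / (CISS_N_ITEMS * CISS_ITEM_MAX), 0.0), 1.0)
    return rng.binomial(CISS_ITEM_MAX, p, CISS_N_ITEMS)


def generate_cohort(spec: CohortSpec, include_raw: bool = False) -> Cohort:
    """Draw a full synthetic cohort; optionally with raw per-subject data.

    The truth table holds per-subject-condition ground truths (peak velocity,
    per-ROI PSC, CISS total, clinical measures).  With ``include_raw`` each
    subject-condition also gets eye-movement trials (with the configured
    blink/saccade contamination rates), a per-subject calibration, and
    ``n_runs`` BOLD runs carrying the subject's true PSC values.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(4)  # deterministic child streams
    rng_truth = np.random.default_rng(children[0])
    rng_clin = np.random.default_rng(children[1])
    timeline = generate_block_timeline(
        20.0, 3.5, 3.0, 5.0, seed=int(children[2].generate_state(1)[0] % (2**31))
    )
    ss_raw = children[3]

    rho = {roi: _within_group_rho(spec, roi) for roi in ROI_PAIRS}

    rows = []
    subject_latents: dict[str, tuple[float, dict]] = {}
    clin_pre: dict[str, dict] = {}
    for group, n in spec.conditions:
        base_group = "CI" if group.startswith("CI") else "BNC"
        condition = group.split("-")[1] if "-" in group else "n/a"
        for i in range(n):
            sid = f"{base_group}{i + 1:02d}"
            if group == "CI-post":
                z1, z2 = subject_latents[sid]
            else:
                z1 = rng_truth.normal()
                z2 = {roi: rng_truth.normal() for roi in ROI_PAIRS}
                if group == "CI-pre":
                    subject_latents[sid] = (z1, z2)

            pv = spec.peak_velocity_mean[group] + spec.peak_velocity_sd[group] * z1
            if group == "CI-post":
                pv += rng_truth.normal(0.0, spec.paired_jitter_pv_sd)
            pv = max(pv, 2.0)

            row = {
                "subject_id": sid, "group": base_group, "condition": condition,
                "peak_velocity": pv,
            }
            for roi in ROI_PAIRS:
                u = rho[roi] * z1 + math.sqrt(1 - rho[roi] ** 2) * z2[roi]
                val = spec.psc_mean[group][roi] + spec.psc_sd[roi] * u
                if group == "CI-post":
                    val += rng_truth.normal(0.0, spec.paired_jitter_psc_sd)
                if roi == "CV":
                    row["psc_CV"] = val
                else:
                    row[f"psc_{roi}_L"] = val + rng_truth.normal(0, spec.hemi_jitter_sd)
                    row[f"psc_{roi}_R"] = val + rng_truth.normal(0, spec.hemi_jitter_sd)

            row["ciss_total"] = int(_ciss_items(rng_clin, spec.ciss_target[group]).sum())
            if base_group == "BNC":
                row["npc_cm"] = float(np.clip(rng_clin.normal(4.5, 1.5), 2.0, 7.9))
                row["bo_range_pd"] = float(max(rng_clin.normal(25.0, 5.0), 12.0))
                row["near_phoria_pd"] = float(np.clip(rng_clin.normal(2.0, 1.5), -2.0, 5.0))
            elif condition == "pre":
                pre = {
                    "npc_cm": float(np.clip(rng_clin.normal(13.4, 5.6), 8.0, 28.0)),
                    "bo_range_pd": float(np.clip(rng_clin.normal(14.0, 4.5), 6.0, 25.0)),
                    "near_phoria_pd": float(max(rng_clin.normal(9.0, 1.4), 4.0)),
                }
                clin_pre[sid] = pre
                row.update(pre)
            else:
                pre = clin_pre[sid]
                row["npc_cm"] = max(pre["npc_cm"] - abs(rng_clin.normal(6.9, 1.5)), 3.0)
                row["bo_range_pd"] = pre["bo_range_pd"] + abs(rng_clin.normal(11.0, 2.5))
                row["near_phoria_pd"] = max(
                    pre["near_phoria_pd"] - abs(rng_clin.normal(3.5, 1.0)), 0.0
                )
            rows.append(row)

    truth = pd.DataFrame(rows)
    subjects = None
    if include_raw:
        subjects = [
            _generate_subject_raw(spec, timeline, row, child)
            for row, child in zip(rows, ss_raw.spawn(len(rows)))
        ]
    return Cohort(spec, timeline, truth, subjects)


def _generate_subject_raw(
    spec: CohortSpec,
    timeline: DesignTimeline,
    row: dict,
    seedseq: np.random.SeedSequence,
) -> SubjectData:
    children = seedseq.spawn(3 + spec.trials_per_subject + spec.n_runs)
    rng = np.random.default_rng(children[0])

    cal = CalibrationModel(
        left_gain=rng.normal(10.0, 0.5),
        left_offset=rng.normal(0.0, 0.2),
        right_gain=rng.normal(10.0, 0.5),
        right_offset=rng.normal(0.0, 0.2),
    )
    cal_table = make_calibration_table(
        cal, seed=int(children[1].generate_state(1)[0] % (2**31))
    )

    trials: list[EyeMovementTrial] = []
    n_blink = n_obstruct = n_clear = 0
    for i in range(spec.trials_per_subject):
        pv = max(rng.normal(row["peak_velocity"], spec.trial_pv_sd), 1.0)
        tspec = VergenceResponseSpec(
            peak_velocity=pv, latency_s=max(rng.normal(0.2, 0.02), 0.05)
        )
        u = rng.uniform()
        if u < spec.blink_rate:
            tspec.blink_times = (rng.uniform(0.2, tspec.duration_s - 0.4),)
            n_blink += 1
        elif u < spec.blink_rate + spec.saccade_obstruct_rate:
            tspec.saccade_times = (tspec.peak_time_s,)
            n_obstruct += 1
        elif u < spec.blink_rate + spec.saccade_obstruct_rate + spec.saccade_clear_rate:
            tspec.saccade_times = (
                min(tspec.peak_time_s + 0.5, tspec.duration_s - 0.1),
            )
            n_clear += 1
        trials.append(
            generate_vergence_trial(
                tspec, cal,
                seed=int(children[3 + i].generate_state(1)[0] % (2**31)),
                trial_id=f"{row['subject_id']}_{row['condition']}_t{i:03d}",
            )
        )

    injected = {
        "FEF_L": row["psc_FEF_L"], "FEF_R": row["psc_FEF_R"],
        "PPC_L": row["psc_PPC_L"], "PPC_R": row["psc_PPC_R"],
        "CV": row["psc_CV"],
        "Broca_L": row["psc_Broca_L"], "Broca_R": row["psc_Broca_R"],
    }
    run_spec = BoldRunSpec(
        injected_psc=injected,
        baseline=spec.baseline,
        noise_sd=spec.noise_sd,
        drift_amplitude=spec.drift_amplitude,
        physio_amplitude=spec.physio_amplitude,
        n_gm_voxels=spec.n_gm_voxels,
        n_csf_voxels=spec.n_csf_voxels,
        n_wm_voxels=spec.n_wm_voxels,
    )
    runs, masks = [], None
    offset = 3 + spec.trials_per_subject
    for j in range(spec.n_runs):
        run, m = generate_bold_run(
            run_spec, timeline,
            seed=int(children[offset + j].generate_state(1)[0] % (2**31)),
        )
        runs.append(run)
        masks = m

    truth = dict(row)
    truth.update(
        n_blink_trials=n_blink,
        n_obstructing_saccade_trials=n_obstruct,
        n_clear_saccade_trials=n_clear,
    )
    return SubjectData(
        row["subject_id"], row["group"], row["condition"],
        cal, cal_table, trials, runs, masks, truth,
    )
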