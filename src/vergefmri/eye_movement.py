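"""Vergence eye-movement analysis: calibration, vergence traces, QC, peak velocity.

Binocular recordings arrive as left/right channel voltages from a limbus
tracker sampled at 200 Hz.  The analysis converts voltages to degrees with a
per-eye linear calibration (fit on 2/4/6/8 deg fixations), computes the net
vergence response as the difference of the two eyes (convergence positive),
differentiates it with a two-point central difference, rejects trials
contaminated by blinks (anywhere in the trial) or by saccades that obstruct
the vergence velocity peak, and summarizes the convergence peak velocity per
subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Linear range of the limbus tracker (deg); samples at/beyond it are treated
#: as signal loss (blink).
DEVICE_RANGE_DEG = 25.0


@dataclass(frozen=True)
class CalibrationModel:
    """Per-eye linear voltage-to-degrees map (deg = gain * volts + offset)."""

    left_gain: float
    left_offset: float
    right_gain: float
    right_offset: float
    fit_residual: float = 0.0  # deg RMS over the calibration fixations

    def __post_init__(self) -> None:
        for g in (self.left_gain, self.right_gain):
            if not np.isfinite(g) or g == 0:
                raise ValueError("calibration gains must be finite and nonzero")
        if self.fit_residual < 0:
            raise ValueError("fit residual must be >= 0")

    def to_degrees(self, left_v: np.ndarray, right_v: np.ndarray):
        return (
            self.left_gain * np.asarray(left_v, float) + self.left_offset,
            self.right_gain * np.asarray(right_v, float) + self.right_offset,
        )

    def to_volts(self, left_deg: np.ndarray, right_deg: np.ndarray):
        return (
            (np.asarray(left_deg, float) - self.left_offset) / self.left_gain,
            (np.asarray(right_deg, float) - self.right_offset) / self.right_gain,
        )


@dataclass
class QCFlags:
    blink: bool = False
    saccade_obstructed: bool = False

    @property
    def accepted(self) -> bool:
        return not (self.blink or self.saccade_obstructed)


@dataclass
class EyeMovementTrial:
    """One binocular step-response recording.

    ``left``/``right`` are rightward-positive channel values, either raw volts
    (``units='volts'``) or calibrated degrees (``units='deg'``).
    ``stim_onset_s`` marks the disparity step onset within the recording.
    """

    time_s: np.ndarray
    left: np.ndarray
    right: np.ndarray
    sample_rate: float
    units: str = "volts"
    trial_id: str = ""
    stim_onset_s: float = 0.0
    qc: QCFlags = field(default_factory=QCFlags)
    truth: dict = field(default_factory=dict)  # generator ground truth, if synthetic

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, float)
        self.left = np.asarray(self.left, float)
        self.right = np.asarray(self.right, float)
        if not (self.time_s.size == self.left.size == self.right.size):
            raise ValueError("time/left/right must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.units not in ("volts", "deg"):
            raise ValueError("units must be 'volts' or 'deg'")

    def calibrated(self, cal: CalibrationModel) -> "EyeMovementTrial":
        if self.units == "deg":
            return self
        left, right = cal.to_degrees(self.left, self.right)
        return EyeMovementTrial(
            self.time_s, left, right, self.sample_rate, "deg",
            self.trial_id, self.stim_onset_s, self.qc, self.truth,
        )


@dataclass
class VergenceTrace:
    """Net vergence response (convergence positive) and its velocity.

    Velocity endpoints are NaN: the central difference is undefined there.
    """

    time_s: np.ndarray
    position: np.ndarray  # deg, convergence positive
    velocity: np.ndarray  # deg/s, NaN at the two endpoints
    sample_rate: float

    @property
    def phase_points(self) -> np.ndarray:
        """(amplitude, velocity) pairs for the phase plot, endpoints excluded."""
        return np.column_stack([self.position[1:-1], self.velocity[1:-1]])


@dataclass
class PeakVelocityResult:
    subject_id: str
    trial_peaks: list[float]
    subject_mean: float
    subject_sd: float
    n_accepted: int
    n_rejected_blink: int
    n_rejected_saccade: int

    @property
    def n_total(self) -> int:
        return self.n_accepted + self.n_rejected_blink + self.n_rejected_saccade


def fit_channel(target_deg: np.ndarray, volts: np.ndarray) -> tuple[float, float, float]:
    """Least-squares linear map deg = gain * V + offset for one eye channel.

    Returns (gain, offset, residual sum of squares).
    """
    target_deg = np.asarray(target_deg, float)
    volts = np.asarray(volts, float)
    if target_deg.size < 2 or np.ptp(volts) == 0:
        raise ValueError("channel calibration needs >= 2 distinct voltages")
    X = np.column_stack([volts, np.ones_like(volts)])
    beta, _, rank, _ = np.linalg.lstsq(X, target_deg, rcond=None)
    if rank < 2:
        raise ValueError("calibration voltages are rank deficient")
    gain, offset = float(beta[0]), float(beta[1])
    rss = float(np.sum((target_deg - X @ beta) ** 2))
    return gain, offset, rss


def fit_calibration(fixations) -> CalibrationModel:
    """Per-eye calibration from symmetric-vergence fixations.

    ``fixations`` is an iterable of (angle_deg, left_v, right_v) rows recorded
    while the subject fixates midline targets at known vergence angles
    (2/4/6/8 deg).  At a symmetric vergence angle theta each eye rotates
    inward by theta/2, so under rightward-positive monocular axes the left
    eye's target position is +theta/2 and the right eye's is -theta/2; each
    channel is fit against its own target.
    """
    rows = np.asarray(list(fixations), float)
    if rows.ndim != 2 or rows.shape[1] != 3 or rows.shape[0] < 2:
        raise ValueError("need >= 2 (angle_deg, left_v, right_v) fixation rows")
    angles, left_v, right_v = rows.T
    if np.unique(angles).size < 2:
        raise ValueError("calibration needs >= 2 distinct angles")

    lg, lo, lrss = fit_channel(angles / 2.0, left_v)
    rg, ro, rrss = fit_channel(-angles / 2.0, right_v)
    rms = float(np.sqrt((lrss + rrss) / (2 * rows.shape[0])))
    return CalibrationModel(lg, lo, rg, ro, rms)


def central_difference_velocity(position: np.ndarray, sample_rate: float) -> np.ndarray:
    """Two-point central difference: v[i] = (x[i+1] - x[i-1]) * fs / 2.

    Endpoint samples are NaN (undefined) and excluded from any maxima.
    """
    x = np.asarray(position, float)
    if x.size < 3:
        raise ValueError("central difference needs >= 3 samples")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    v = np.full(x.size, np.nan)
    v[1:-1] = (x[2:] - x[:-2]) * sample_rate / 2.0
    return v


def compute_vergence(trial: EyeMovementTrial) -> VergenceTrace:
    """Net vergence = left - right under rightward-positive axes.

    For a symmetric convergence step both eyes rotate inward (left eye
    rightward, right eye leftward), so left - right is positive: convergence
    is plotted positive, as required.
    """
    if trial.units != "deg":
        raise ValueError("trial must be calibrated to degrees first")
    position = trial.left - trial.right
    velocity = central_difference_velocity(position, trial.sample_rate)
    return VergenceTrace(trial.time_s, position, velocity, trial.sample_rate)


def detect_blinks(trial: EyeMovementTrial, device_range_deg: float = DEVICE_RANGE_DEG):
    """Flag a trial if either channel leaves the tracker's calibrated range.

    Limbus trackers lose the signal during lid closure; the generator models
    this as saturation beyond the linear range.  A blink anywhere in the
    trial flags it (responses with blinks at any point are omitted).

    Returns ``(flag, intervals)`` where intervals are (start_s, end_s) spans.
    """
    if trial.units != "deg":
        raise ValueError("blink detection operates on calibrated degrees")
    bad = (np.abs(trial.left) >= device_range_deg) | (
        np.abs(trial.right) >= device_range_deg
    )
    if not bad.any():
        return False, []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], bad.view(np.int8), [0]])))
    intervals = [
        (trial.time_s[a], trial.time_s[min(b, trial.time_s.size - 1)])
        for a, b in zip(edges[::2], edges[1::2])
    ]
    return True, intervals


def _running_scale(v: np.ndarray, sample_rate: float, window_s: float = 0.1) -> np.ndarray:
    """Moving-average |velocity| scale, NaN-safe, same length as input."""
    w = max(int(round(window_s * sample_rate)), 1)
    a = np.abs(np.nan_to_num(v))
    kernel = np.ones(w) / w
    return np.convolve(a, kernel, mode="same")


def saccade_samples(
    left_vel: np.ndarray,
    right_vel: np.ndarray,
    vergence_vel: np.ndarray,
    sample_rate: float,
    ratio: float = 5.0,
    floor_deg_s: float = 40.0,
) -> np.ndarray:
    """Boolean mask of saccadic samples.

    Saccade velocities are an order of magnitude above vergence velocities;
    operationally a sample is saccadic when either monocular velocity exceeds
    max(ratio * running vergence-velocity scale, floor).  The floor keeps the
    threshold meaningful where the vergence velocity is near zero.
    """
    scale = _running_scale(vergence_vel, sample_rate)
    thresh = np.maximum(ratio * scale, floor_deg_s)
    with np.errstate(invalid="ignore"):
        return (np.abs(left_vel) > thresh) | (np.abs(right_vel) > thresh)


def peak_velocity(
    trace: VergenceTrace,
    stim_onset_s: float = 0.0,
    window_s: float = 2.0,
) -> tuple[float, int]:
    """Maximum convergence velocity in the response window; ties -> earliest.

    The search window runs from stimulus onset to onset + ``window_s`` (slow
    convergence-insufficiency responses can take up to ~2 s to fuse); a
    bounded window avoids end-of-trial artifacts.
    """
    in_win = (trace.time_s >= stim_onset_s) & (
        trace.time_s <= stim_onset_s + window_s
    )
    v = np.where(in_win, trace.velocity, np.nan)
    if np.all(np.isnan(v)):
        raise ValueError("no defined velocity samples in the response window")
    idx = int(np.nanargmax(v))
    return float(v[idx]), idx


def screen_saccade_obstruction(
    trace: VergenceTrace,
    left_vel: np.ndarray,
    right_vel: np.ndarray,
    stim_onset_s: float = 0.0,
    window_s: float = 2.0,
    ratio: float = 5.0,
    floor_deg_s: float = 40.0,
    obstruction_halfwidth_s: float = 0.1,
) -> bool:
    """True when a saccadic interval overlaps the vergence velocity peak.

    Saccades elsewhere in the trial leave the convergence peak measurable and
    do not reject the response.
    """
    sacc = saccade_samples(
        left_vel, right_vel, trace.velocity, trace.sample_rate, ratio, floor_deg_s
    )
    if not sacc.any():
        return False
    _, peak_idx = peak_velocity(trace, stim_onset_s, window_s)
    half = int(round(obstruction_halfwidth_s * trace.sample_rate))
    lo = max(peak_idx - half, 0)
    hi = min(peak_idx + half + 1, sacc.size)
    return bool(sacc[lo:hi].any())


@dataclass
class TrialAnalysis:
    trial: EyeMovementTrial
    trace: VergenceTrace | None
    peak_velocity: float | None
    flags: QCFlags


def analyze_trial(
    trial: EyeMovementTrial,
    calibration: CalibrationModel,
    device_range_deg: float = DEVICE_RANGE_DEG,
    window_s: float = 2.0,
    saccade_ratio: float = 5.0,
    saccade_floor_deg_s: float = 40.0,
) -> TrialAnalysis:
    """Calibrate, QC, and extract the convergence peak velocity of one trial."""
    cal = trial.calibrated(calibration)
    flags = QCFlags()
    flags.blink, _ = detect_blinks(cal, device_range_deg)
    if flags.blink:
        return TrialAnalysis(cal, None, None, flags)
    trace = compute_vergence(cal)
    lv = central_difference_velocity(cal.left, cal.sample_rate)
    rv = central_difference_velocity(cal.right, cal.sample_rate)
    flags.saccade_obstructed = screen_saccade_obstruction(
        trace, lv, rv, cal.stim_onset_s, window_s, saccade_ratio, saccade_floor_deg_s
    )
    if flags.saccade_obstructed:
        return TrialAnalysis(cal, trace, None, flags)
    pk, _ = peak_velocity(trace, cal.stim_onset_s, window_s)
    return TrialAnalysis(cal, trace, pk, flags)


def summarize_subject(
    trials,
    calibration: CalibrationModel,
    subject_id: str = "",
    **analyze_kwargs,
) -> PeakVelocityResult:
    """Per-subject mean/sd of convergence peak velocity over accepted trials."""
    peaks: list[float] = []
    n_blink = n_sacc = 0
    for tr in trials:
        res = analyze_trial(tr, calibration, **analyze_kwargs)
        if res.flags.blink:
            n_blink += 1
        elif res.flags.saccade_obstructed:
            n_sacc += 1
        else:
            peaks.append(res.peak_velocity)
    n_total = len(peaks) + n_blink + n_sacc
    if not peaks:
        raise ValueError(
            f"subject {subject_id!r}: zero accepted trials "
            f"(blink {n_blink}, saccade-obstructed {n_sacc} of {n_total})"
        )
    if n_total:
        logger.info(
            "subject %s: %d/%d accepted (%.1f%% blink, %.1f%% saccade-obstructed)",
            subject_id, len(peaks), n_total,
            100 * n_blink / n_total, 100 * n_sacc / n_total,
        )
    arr = np.asarray(peaks)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return PeakVelocityResult(
        subject_id, peaks, float(arr.mean()), sd, len(peaks), n_blink, n_sacc
    )
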