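"""Analyze one synthetic subject's 4 deg convergence step responses.

Generates 40 binocular trials (voltage units, with realistic blink and
saccade contamination), fits the per-eye calibration from 2/4/6/8 deg
fixations, and extracts the subject's convergence peak velocity with QC.
"""

import numpy as np

from vergefmri import (
    CalibrationModel,
    VergenceResponseSpec,
    fit_calibration,
    generate_vergence_trial,
    make_calibration_table,
    summarize_subject,
)

rng = np.random.default_rng(3)
true_cal = CalibrationModel(9.5, 0.2, 10.4, -0.1)
subject_mean_pv = 14.0  # deg/s: a convergence-insufficiency-like subject

trials = []
for i in range(40):
    spec = VergenceResponseSpec(
        peak_velocity=max(rng.normal(subject_mean_pv, 1.5), 1.0)
    )
    u = rng.uniform()
    if u < 0.02:  # blink somewhere in the trial
        spec.blink_times = (rng.uniform(0.3, 2.5),)
    elif u < 0.10:  # saccade right on the vergence peak
        spec.saccade_times = (spec.peak_time_s,)
    trials.append(generate_vergence_trial(spec, true_cal, seed=100 + i))

calibration = fit_calibration(make_calibration_table(true_cal, seed=5))
print(f"fitted gains (deg/V): left {calibration.left_gain:.2f}, "
      f"right {calibration.right_gain:.2f} "
      f"(residual {calibration.fit_residual:.3f} deg RMS)")

result = summarize_subject(trials, calibration, subject_id="CI01")
print(f"\nconvergence peak velocity: {result.subject_mean:.1f} "
      f"+/- {result.subject_sd:.1f} deg/s over {result.n_accepted} accepted trials")
print(f"rejected: {result.n_rejected_blink} blink, "
      f"{result.n_rejected_saccade} saccade-obstructed")
print(f"(injected subject mean was {subject_mean_pv} deg/s; taking the max of "
      "a differentiated noisy trace biases each estimate upward by a similar "
      "amount, so group contrasts and correlations are preserved)")
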