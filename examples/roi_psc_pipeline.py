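"""Recover injected percent signal change from a synthetic BOLD subject.

Builds three repeated 70-volume runs whose ROI voxels carry known percent
signal changes, then runs the full pipeline: drop 5 volumes, frame
displacement QC, CompCor tissue-PC + motion nuisance regression, 0.01-0.15
Hz band-pass, r >= 0.4 correlation thresholding, ROI pooling, and percent
signal change vs. fixation.
"""

from vergefmri import (
    BoldRunSpec,
    generate_block_timeline,
    generate_bold_run,
    run_subject_roi_analysis,
)

timeline = generate_block_timeline(20.0, 3.5, 3.0, 5.0, seed=2)
injected = {
    "FEF_L": 1.2, "FEF_R": 1.2, "PPC_L": 1.0, "PPC_R": 1.0,
    "CV": 0.8, "Broca_L": 0.0, "Broca_R": 0.0,
}
spec = BoldRunSpec(injected_psc=injected)

runs, masks = [], None
for seed in (21, 22, 23):  # the experiment is repeated three times
    run, masks = generate_bold_run(spec, timeline, seed=seed)
    runs.append(run)

analysis = run_subject_roi_analysis(runs, masks, timeline)

fd = analysis.frame_displacement[0]
print("frame displacement (mean abs frame-to-frame change):")
for name, stats in fd.as_dict().items():
    unit = "mm" if name.startswith("trans") else "deg"
    print(f"  {name:>9s}: {stats['mean']:.3f} +/- {stats['sd']:.3f} {unit}")

print(f"\n{'ROI':>8s} {'injected %':>10s} {'recovered %':>11s} "
      f"{'design r':>8s} {'pooled':>6s}")
for roi, res in analysis.results.items():
    print(f"{roi:>8s} {injected[roi]:>10.2f} "
          f"{res.percent_signal_change:>11.2f} "
          f"{res.correlation_with_design:>8.2f} "
          f"{res.n_voxels_pooled:>3d}/{res.n_voxels_in_mask}")
print("\nBroca (non-stimulated control) stays near zero and below the "
      "r >= 0.4 threshold, as it should.")
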