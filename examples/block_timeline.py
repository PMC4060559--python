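"""Build the fixation / eye-movement block design and its BOLD regressor.

The experiment alternates 20 s of sustained fixation with 20 s of vergence
eye movements for 3.5 cycles (140 s = 70 volumes at TR 2 s).  During each
movement phase one of three LED targets (2/3/4 deg vergence demand) lights
up for a random 3-5 s so the subject cannot anticipate the next step.
"""

from vergefmri import build_design_regressor, generate_block_timeline

timeline = generate_block_timeline(
    phase_s=20.0, n_cycles=3.5, illum_min=3.0, illum_max=5.0, seed=1
)

print(f"total duration: {timeline.total_duration_s:.0f} s")
print(f"volumes at TR 2 s: {timeline.n_volumes(2.0)}")
print(f"phases: {[p.label for p in timeline.phases]}")
print("first illuminations (target, onset s, duration s):")
for ev in timeline.illuminations[:5]:
    print(f"  {ev.target:>6s} ({ev.demand_deg:.0f} deg) "
          f"at {ev.onset_s:6.2f} for {ev.duration_s:.2f}")

regressor = build_design_regressor(timeline, tr=2.0, n_drop=5)
print(f"\nHRF-convolved regressor after dropping 5 volumes: {regressor.size} points")
print("the regressor rises ~2 volumes after each movement phase begins, "
      "reflecting the hemodynamic lag")
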