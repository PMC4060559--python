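"""Group statistics on a synthetic cohort (7 BNC, 4 CI pre/post).

Generates ground-truth subject tables and reproduces the study's comparison
battery: unpaired BNC vs CI-pre t-tests, paired pre/post t-tests (peak
velocity, per-ROI PSC, CISS, clinical measures), and the pooled
peak-velocity-vs-PSC regressions.
"""

from vergefmri import CohortSpec, generate_cohort, group_comparisons

cohort = generate_cohort(CohortSpec(seed=8))
table = cohort.truth_table
print(table.groupby(["group", "condition"])[
    ["peak_velocity", "psc_FEF_L", "ciss_total", "npc_cm"]
].mean().round(2))

stats = group_comparisons(table)

u = stats["unpaired_bnc_vs_ci_pre"]["peak_velocity"]
print(f"\nBNC vs CI-pre peak velocity: t({u.df}) = {u.t:.2f}, p = {u.p:.4f}, "
      f"mean gap {u.mean_difference:.1f} deg/s")
p = stats["paired_pre_vs_post"]["peak_velocity"]
print(f"CI pre vs post peak velocity: t({p.df}) = {p.t:.2f}, p = {p.p:.4f}")

print("\nclinical pre/post (paired):")
for measure, res in stats["clinical"].items():
    print(f"  {measure:>15s}: t({res.df}) = {res.t:6.2f}, p = {res.p:.4f} "
          f"({res.note})")

print("\npeak velocity vs ROI percent signal change (pooled, L/R averaged):")
for roi, reg in stats["regression"].items():
    print(f"  {roi:>5s}: r = {reg.r:+.2f}, p = {reg.p:.4f}, "
          f"slope = {reg.slope:5.1f} deg/s per % (n = {reg.n})")
print("\nthe cohort is generated with a pooled behavior-BOLD correlation of "
      "0.6 in the task ROIs and 0 in the Broca control; with only 15 rows "
      "the per-ROI sample correlations scatter widely around those values.")
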