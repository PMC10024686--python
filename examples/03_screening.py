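"""Screen aggregated gait features against rater mobility scores.

Builds a 100-cow feature table (7 kinematic series x 7 summary statistics,
48 columns), correlates each column with the consolidated score, and
reports inter-rater concordance for the three simulated scorers.
"""

import numpy as np

import gaitkit as gk

params = gk.GaitParams()
cohort = gk.simulate_cohort(params, 100, seed=11)
table = gk.build_feature_table(cohort.tracks, cohort.rater_table)
report = gk.pearson_screen(table)

print("feature                      rho      p        band")
for feat in ("back_rmse_median", "back_rmse_max", "area_total_mean",
             "area_hip_centre_mean", "head_nose_pos_mean", "neck_angle_std"):
    row = report.loc[feat]
    print(f"{feat:<26} {row['rho']:>7.3f}  {row['p_value']:.2e}  {row['band']}")

raters = np.array([r.rater_scores for r in cohort.rater_table]).T
w, p = gk.kendalls_w(raters)
print(f"\nKendall's W across 3 raters: {w:.3f} (p = {p:.2e})")
print("\nback curvature and area features correlate strongly and positively with")
print("the score; the head/nose elevation is negative because lame cows drop")
print("the head below the extended back line.")
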