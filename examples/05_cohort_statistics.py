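"""Full endotoxemia-cohort statistics on ground-truth Hurst values.

Samples a 3 x 10-subject cohort at the study's group profiles (control,
LPS, LPS + resuscitation), summarises the generating Hurst values per
site and timepoint, and runs the nonparametric battery: Kruskal-Wallis,
Bonferroni-corrected pairwise rank-sum, Friedman, and the Youden cutoff
separating control from LPS.
"""

import pandas as pd

from dlsflow import lps_study_scenario, run_comparisons, simulate_cohort

records = simulate_cohort(lps_study_scenario(n_per_group=10, seed=5))
rows = [dict(subject_id=r.subject_id, group=r.group, site=site, timepoint=tp,
             parameter="hurst", value=r.ground_truth(site, tp)["hurst"])
        for r in records
        for site in ("central", "peripheral")
        for tp in ("T0", "T1", "T2", "T3")]
results = run_comparisons(pd.DataFrame(rows))

omni = results["between_groups"]
omni = omni[omni.contrast == "omnibus"]
print("Kruskal-Wallis raw p per site/timepoint:")
print(omni.pivot(index="timepoint", columns="site", values="p_raw").round(4))
print("\nYouden cutoff (control vs LPS), peripheral site:")
y = results["youden"]
print(y[y.site == "peripheral"][
    ["timepoint", "cutoff", "sensitivity", "specificity"]].round(3).to_string(index=False))
print("\nOn ground-truth values the group contrast strengthens sharply after")
print("endotoxin: p-values drop by orders of magnitude at T2-T3, and the")
print("Youden cutoff then separates control from LPS almost perfectly.")
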