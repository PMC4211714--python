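"""Protein intake by energy-balance class and predisposition-score level.

Annual weight change proxies cumulative energy balance (negative < −0.5,
neutral within ±0.5, positive > 0.5 kg/y); each class is split by
BMI-score above/below the cohort mean.  For the six cells the table lists
n, mean protein intake (E% and g/kg body weight/day), SEM and 95% CI.
With no planted intake-score-balance dependence the cell means should be
similar and their CIs overlap.
"""

import genediet as gd

defs = gd.load_panel()
cohort = gd.simulate_cohort(gd.SimConfig(n=3000, name="EB"), defs, seed=99)
score_group = gd.split_at_mean(gd.build_score(cohort.genotypes, defs, "BMI"))
tab = gd.protein_by_subgroup(cohort.pheno, score_group)
cols = ["balance", "score_group", "n", "mean_e_pct", "sem_e_pct",
        "lo_e_pct", "hi_e_pct", "mean_g_kg_d"]
print(tab[cols].round(3).to_string(index=False))
print("\nmean_e_pct: protein as % of energy; mean_g_kg_d: grams per kg baseline weight per day")
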