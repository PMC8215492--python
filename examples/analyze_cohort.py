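"""Run the group-comparison pipeline over a synthetic cohort.

One-way ANOVA across the four groups with Tukey all-pairs comparisons for
each endpoint, plus within-group basal-vs-stimulated t-tests for the ROS
responder fractions; stars follow the usual p < 0.05/0.01/0.001/0.0001
convention.
"""

from marrow_reservoir import analyze_cohort, generate_cohort

cohort = generate_cohort(seed=1)
results = analyze_cohort(cohort, seed=0)

anova = results[results["test"] == "anova"][["endpoint", "statistic", "df", "p", "stars"]]
print("ANOVA across groups per endpoint:")
print(anova.to_string(index=False, float_format=lambda x: f"{x:.3g}"))

pair = results[(results["endpoint"] == "classical_pct") & (results["test"] == "tukey")]
print("\nTukey pairwise comparisons for the classical subset:")
print(pair[["groups", "statistic", "p_adj", "stars"]].to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print(
    "\nEvery patient group differs from the healthy controls on the classical"
    "\nsubset, while SMC and MCI are mutually indistinguishable — the pattern"
    "\nthe generator was configured to encode."
)
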