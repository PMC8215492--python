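"""Generate a default synthetic immunophenotyping cohort and inspect it.

The default configuration reproduces the study's four groups (HC n=15,
SMC n=10, MCI n=14, AD n=14), the printed monocyte subset means, a
stage-ordered chemotaxis decline and the reported ROS responder fractions.
"""

from marrow_reservoir import generate_cohort

cohort = generate_cohort(seed=1)
print(f"cohort: {len(cohort)} subjects, {cohort.shape[1]} columns")
print("\ngroup sizes:")
print(cohort["group"].value_counts().reindex(["HC", "SMC", "MCI", "AD"]).to_string())

summary = cohort.groupby("group", sort=False)[
    ["classical_pct", "intermediate_pct", "nonclassical_pct", "chemo_basal", "ros_ecoli_pct"]
].mean()
print("\ngroup means (monocyte subsets %, basal chemotaxis counts, E. coli ROS %):")
print(summary.to_string(float_format=lambda x: f"{x:.1f}"))
print(
    "\nThe classical subset shrinks and the proinflammatory subsets grow from"
    "\nhealthy controls towards AD, chemotaxis declines, and the E. coli ROS"
    "\nresponse is strongest in the healthy group."
)
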