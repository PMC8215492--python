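"""Calibrate the reservoir model to stage-wise cohort observations.

The bridge maps model state to what a cohort measures: the inflammatory
share (intermediate + non-classical %) is an affine function of m(t) and the
relative chemotaxis is c(t)/c0.  A coarse grid scan plus Nelder-Mead
refinement recovers the capacity-depletion factor alpha and the exogenous
signal level from a large synthetic cohort.
"""

from marrow_reservoir import (
    CohortConfig,
    FitConfig,
    fit,
    generate_cohort,
    observed_stage_vector,
)
from marrow_reservoir.cohort import GROUPS

config = CohortConfig()
config.sizes = {g: 2000 for g in GROUPS}  # large groups for stable stage means
cohort = generate_cohort(config, seed=3)

observed = observed_stage_vector(cohort)
print("observed stage vector (group means):")
print(observed.to_string(index=False, float_format=lambda x: f"{x:.3f}"))

result = fit(observed, free_params=("alpha", "level"), config=FitConfig(seed=0))
print("\nfitted parameters:")
for name, value in result.theta_hat.items():
    print(f"  {name:6s} = {value:.4f}")
print(f"loss = {result.loss:.4f} after {result.n_evals} evaluations (converged={result.converged})")
print(
    "\nalpha scales how strongly the production flux depletes capacity; level"
    "\nis the constant exogenous signal.  The fitted values are milder than the"
    "\npathological-scenario defaults because this cohort's chemotaxis only"
    "\nhalves by the AD stage, whereas the default scenario nearly exhausts"
    "\ncapacity — the fit reports the least-squares compromise between the"
    "\nshare and chemotaxis observables."
)
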