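# Methods

## The reservoir model

The model describes the bone marrow as a finite reservoir of resources for
producing proinflammatory monocytes, driven by an unknown exogenous signal
`I(t) ≥ 0`.  Two state variables evolve in time:

- `m(t) ∈ [0, 1]` — the fraction of those resources already mobilised into
  the circulation; the remaining reservoir is `1 − m` (only `m` is stored, so
  the conservation `reservoir + circulating = 1` is structural, not asserted);
- `c(t) ∈ [0, c0]` — the marrow's capacity for readily producing such cells,
  taken as indirectly coupled to the migration (chemotactic) capacity of
  circulating monocytes.

The governing equations are

```
flux  = c · I · (1 − m)
dm/dt = flux − (m − m0) / τ_m
dc/dt = (c0 − c) / τ_c − α · flux
```

**This algebraic form is a reconstruction.**  The published account of the
model is verbal: a Markov state diagram, the statement that production is
driven by `I(t)` and saturates because resources are finite, a replenishment
time constant `τ_m`, a capacity recovery time constant `τ_c` towards the
healthy baseline `c0`, and depletion of capacity by synthesis through an
unknown factor `α`.  No equations or parameter values are printed.  The form
above is the minimal two-state law consistent with every verbal constraint:
the flux is proportional to the remaining reservoir (so production decays
under a constant signal even at constant `c`), `m` relaxes to its healthy
baseline `m0` with `τ_m`, and `c` is depleted in proportion to the synthesis
flux while recovering to `c0` with `τ_c`.  An ambiguity worth recording:
whether `α` multiplies the raw signal or the production flux is not decidable
from the verbal description; the flux form is used because it makes synthesis
the single depletion pathway, and it is isolated in one function
(`model.derivatives`) should the alternative be preferred.

### Default parameters and the slow-relaxation regime

No parameter values or time units are published, so the defaults are the
package's own choice, fixed once by requiring that a single constant-signal
run reproduces *all* of the qualitative claims made for the pathological
scenario simultaneously:

1. stage-wise production flux ordered SMC > MCI > AD with flux(AD) < 5 % of
   flux(SMC) ("zero at AD", operationalised with the 5 % threshold because a
   strict zero is only asymptotic);
2. `m` non-decreasing (saturation, never a late decline);
3. `c` strictly decreasing over the whole horizon;
4. rescue: after the signal is removed, `m` and `c` return to within 1 % of
   baseline.

A systematic scan of the parameter space shows these cannot all hold when the
relaxation times are comparable to the progression horizon: replenishment
pulls `m` back down once the flux decays (violating 2) and capacity recovery
eventually outpaces depletion (violating 3).  They hold jointly only in the
*slow-relaxation regime*, where `τ_m` and `τ_c` are long compared with the
simulated progression window — which is also the natural reading of the
disease narrative: progression happens precisely because depletion outruns
replenishment.  The defaults are

| parameter | default | meaning |
|---|---|---|
| `τ_m` | 1000 | replenishment time constant (model time units) |
| `τ_c` | 1000 | capacity recovery time constant |
| `α` | 3.0 | capacity depletion per unit production flux |
| `c0` | 1.0 | healthy baseline capacity |
| `m0` | 0.05 | healthy circulating fraction ("small but not zero") |
| `I` | 0.1 | constant pathological signal level |
| horizon | 40 | pathological simulation window |
| `h` | 0.01 | RK4 step (pathological); 0.05 for the long rescue run |

with stage times H = 0, SMC = 8, MCI = 20, AD = 35 (ordering is all that is
constrained; the spacing is illustrative and overridable).  Under these
defaults flux(AD)/flux(SMC) ≈ 0.036 and the terminal flux is ≈ 0.4 % of the
peak.  The model time unit is abstract "progression time"; nothing in the
package depends on identifying it with years.  The rescue scenario's default
horizon is `t_off + 6·max(τ_m, τ_c)` so the exponential return to baseline
(factor e⁻⁶ ≈ 0.25 %) is complete within the run.

### Numerics

Integration is classical fixed-step RK4, with the signal evaluated at
`t`, `t + h/2` and `t + h`; for the rescue scenario the switch-off time is
required to sit on the step grid, so the discontinuity never falls inside a
step and the local order is preserved.  If the horizon is not a multiple of
`h` a single shorter final step lands exactly on it.  After each step the
state is clamped to `m ∈ [0, 1]`, `c ∈ [0, c0]` (a logged safety net; with
valid parameters and `I ≥ 0` the dynamics stay inside the box up to
roundoff).  With the signal off the equations decouple into two linear
relaxations with exact exponential solutions; the test suite uses this closed
form as the integrator's oracle (agreement to 1e−8 at `h = min(τ)/100`,
empirical convergence order ≥ 3.9).  Stage lookups use the nearest grid
point, ties broken toward the earlier point.

## The synthetic cohort generator

The study's subject-level data are not public, so the generator stands in for
them.  What it emulates — and the only quantities the study prints — are
group-level means: sample sizes 15/10/14/14 (HC/SMC/MCI/AD); monocyte subset
means (classical 88/80/80/74 %, intermediate 3/5/6/7 %, non-classical
4/8/8/9 %); a stage-ordered chemotaxis decline with MCP-1 dose response; ROS
responder fractions anchored at 2.5 % basal, 60 % E. coli and 20 % PMA in
healthy subjects, with patient groups elevated at rest and blunted under
stimulation; and cytokine MFI panels that encode only the *direction* of the
reported effects (proinflammatory stimulation strongest at MCI, weakest at
AD).

Distributions, and what is a design default rather than a reported value:

- **Subset composition** — logistic-normal: additive-log-ratio coordinates
  centred on the configured composition with per-coordinate SD
  `subset_logratio_sd` (default 0.15).  Chosen over a Dirichlet because the
  degenerate limit is exact and dispersion is controlled independently of the
  means.  The printed subset means do not sum to 100 % (gating leaves a
  remainder), so a 3-part mean vector summing to < 100 is completed with an
  implicit "other/ungated" component; rows therefore satisfy
  classical + intermediate + non-classical ≤ 100, with equality when the
  configured means use the full simplex.  The back-transform makes the
  sample mean differ from the configured means by O(sd²) ≈ 0.2 percentage
  points at the default dispersion — well inside every tolerance used.
- **Chemotaxis counts** — negative binomial with size parameter 10
  (variance = μ + μ²/10); means HC 100, SMC/MCI 70, AD 50 at baseline with
  1.5×/1.8× MCP-1 scaling in HC and attenuated (1.3×/1.5×) scaling in the
  patient groups.  The study prints no counts, only ordering and
  significance; these encode that ordering.
- **ROS responder fractions** — binomial over 5,000 counted cells per assay.
- **MFIs** — lognormal with unit log-SD.

No dispersion of any panel is reported (error bars are figure-only), so all
dispersions are design defaults.  Consequences for interpretation: passing
tests demonstrate that the pipeline recovers the *configured* group structure
at the configured noise, not that the study's actual effect sizes would be
detected at the study's actual (unknown) variability.  The generator also
simulates no covariates (age, sex, APOE), no measurement batch effects and no
within-subject correlation between panels — each panel is drawn
independently given the group.

Everything is reproducible from a single integer seed; the pipeline derives
per-stage substream seeds by hashing `"<seed>:<stream-name>"` (SHA-256, low
31 bits), so a stage can be re-run in isolation with the exact stream the
pipeline used.

## Group statistics

One-way fixed-effects ANOVA, Tukey and Dunnett multiple comparisons, and
pooled/Welch/paired t-tests are implemented directly from their defining
formulas.  The family-wise adjusted p-values are computed by seeded
Monte-Carlo simulation of the null maximum statistic — group-mean errors
drawn with the design's sizes, a shared χ²-distributed error variance, and
for Dunnett the correlation induced by the shared control — rather than by
quadrature of the studentized-range / multivariate-t distributions.  The MC
route was chosen because it is verifiable against independent closed-form
implementations (scipy's `tukey_hsd` and `dunnett` serve as oracles in the
test suite) and handles unbalanced designs (Tukey–Kramer) without
special-casing.  At the default 200,000 draws the MC standard error of an
adjusted p near 0.05 is ≈ 0.0005; the documented tolerance is ±0.005.
P-values are bit-for-bit reproducible given (seed, n_mc).

Tests are two-sided throughout; the pooled variant is the default t-test.
The analysis plan (which endpoint gets which test) is configuration, not
inference: the study names Tukey and Dunnett only in figure legends without a
consistent endpoint mapping, so the default plan applies Tukey across groups
to every phenotype/function endpoint and unpaired within-group t-tests to the
stimulated-vs-basal ROS contrasts, with Dunnett available for vs-control
designs.  No correction is applied across endpoints (matching the source
analyses); this is a deliberate limitation — with ~10 endpoints per cohort,
family-wise error across endpoints is not controlled.

MFI normalisation is the stimulated/unstimulated fold change.

## Calibration

The bridge from model to data is deliberately minimal: the *inflammatory
share* (intermediate + non-classical %) is predicted as `a_m + b_m · m(t_s)`
and the *relative chemotaxis* (group-mean basal counts normalised to HC) as
`c(t_s)/c0`, at the four stage times.  The study never defines which
empirical quantity `m` corresponds to; the affine map is one defensible
choice and is isolated behind `ObservableMap` so alternatives can be swapped.
Default map coefficients (`a_m = 6`, `b_m = 27`) are anchored so the default
pathological trajectory spans the configured share range (≈ 7 % at H to
≈ 16 % at AD).

The loss is a weighted stage-wise SSE; weights default to 1 per share
(percent²) and 100 per relative-chemotaxis entry to balance the scales.
`fit` scans a full-factorial grid (8 points per free dimension, vectorised
over candidates) and refines the best 3 points with bounded Nelder-Mead
(loss tolerance 1e−10); the seed controls only a small jitter on the
refinement starts, so the procedure is deterministic given (data, seed).
The calibration forward model uses `h = 0.5`; for these slow dynamics the
RK4 error at that step is far below every tolerance in use, and the batched
grid integrator performs the identical arithmetic to the scalar path.

**Identifiability.**  Eight data points (4 stages × 2 observables) cannot
identify many parameters; `τ_m` and `τ_c` are always fixed.  Even the default
free set `{α, level, a_m, b_m}` is sloppy: in the slow-relaxation regime
`c ≈ 1 − α(m − m0)` and `m(t) ≈ M(I·t; α)`, so the signal level trades off
almost freely against the affine share map, and recovery experiments at the
reference noise level (SD 0.5 percentage points on shares, 0.02 on relative
chemotaxis) show median relative errors of 40–60 % for `level` and `b_m`.
The canonical parameter-recovery study therefore profiles the mechanistic
pair `{α, level}` with the observation map fixed, where the same experiment
gives median relative errors of ≈ 3 % (α) and ≈ 8 % (level) over 20
replicates.  Zero-noise self-consistency is verified on the full 4-parameter
set.  No uncertainty quantification is attempted on fitted parameters.

## Known limitations

- The ODE algebra is a documented reconstruction, not transcribed equations;
  all quantitative model outputs are conditional on it and on illustrative
  parameter defaults.
- The coupling between marrow capacity and monocyte chemotaxis is asserted,
  not mechanistic, exactly as in the verbal model.
- The generator reproduces group means only; dispersions, covariates and
  cross-panel correlations are invented defaults, so statistical-power
  results on synthetic cohorts do not transfer to the real population.
- The deterministic mean-field ODE is the only realisation; no stochastic
  jump-process version of the underlying state diagram is provided.
- Calibration to a default synthetic cohort is a compromise fit: the default
  pathological scenario nearly exhausts capacity while the configured cohort
  chemotaxis only halves by AD, so jointly fitting both observables settles
  between them (visible in `examples/calibrate_model.py`).
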