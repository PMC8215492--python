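# marrow-reservoir

An idealised **bone-marrow reservoir model** of proinflammatory monocyte
production across the clinical spectrum of Alzheimer's disease (healthy
elderly → subjective memory complaint → mild cognitive impairment → AD),
together with a **synthetic immunophenotyping cohort generator**, the
**group-comparison statistics pipeline** used for stage-wise observations,
and a **model-to-data calibration bridge**.

It is written for researchers in neuroimmunology and biostatistics who want
to (a) explore the reservoir-depletion hypothesis quantitatively, (b) test
analysis pipelines against cohorts with a known, study-anchored group
structure, or (c) calibrate the model's mechanistic parameters against
stage-wise observations.

## The model

Two state variables evolve under an exogenous signal `I(t)`:

```
flux  = c · I · (1 − m)            production flux of proinflammatory cells
dm/dt = flux − (m − m0)/τ_m        mobilised fraction m; reservoir is 1 − m
dc/dt = (c0 − c)/τ_c − α · flux    production/migration capacity c
```

Production is proportional to the remaining reservoir `1 − m`, so under a
sustained signal it *saturates*; the synthesis flux depletes the capacity `c`
through the factor `α`, while `τ_m` and `τ_c` set the (slow) relaxation back
to the healthy baselines `m0` and `c0`.  Integration is classical fixed-step
4th-order Runge-Kutta.  Two scenarios are built in: **pathological**
(constant signal: flux rises by the SMC stage, declines through MCI, and is
near zero at AD while capacity falls monotonically) and **rescue** (the
signal is removed at `t_off` and both variables return to baseline).  The
algebraic form is a reconstruction from a verbal model description — see
`docs/methods.md` for the full account and the parameter defaults.

Around the model, the package generates subject-level cohorts matching the
study's printed group structure (sample sizes 15/10/14/14; classical /
intermediate / non-classical monocyte subset means 88/3/4 % in healthy
controls through 74/7/9 % at AD; stage-ordered chemotaxis decline; ROS
responder fractions 2.5 % basal vs 60 % under E. coli), analyses them with
one-way ANOVA plus Tukey/Dunnett multiple comparisons and t-tests (seeded
Monte-Carlo family-wise p-values), and fits the model's mechanistic
parameters to the stage-wise observables.

## Worked example

```sh
python examples/simulate_scenarios.py
```

prints

```
pathological scenario, stage summary:
stage       t      m      c   flux
    H  0.0000 0.0500 1.0000 0.0950
  SMC  8.0000 0.3290 0.1630 0.0109
  MCI 20.0000 0.3764 0.0209 0.0013
   AD 35.0000 0.3812 0.0063 0.0004

flux(AD) / flux(SMC) = 0.036  (production ~zero at AD)

rescue scenario: at t = 6010, m = 0.0507 (baseline 0.05), c = 0.9978 (baseline 1.0)
-> removing the signal returns both state variables to healthy values.
```

Reading the numbers: the mobilised fraction `m` climbs from its healthy
baseline 0.05 and saturates near 0.38 — the reservoir stops yielding cells —
while the capacity `c` collapses from 1.0 to below 0.01 and the production
flux at the AD stage is ≈ 4 % of its SMC value.  In the rescue run the signal
is switched off at t = 10 and both variables relax back to their baselines.

The other examples follow the same pattern, one per capability:
`examples/generate_cohort.py` (a 53-subject default cohort and its group
means), `examples/analyze_cohort.py` (ANOVA + Tukey with significance
stars), and `examples/calibrate_model.py` (recovering the depletion factor
`α` and signal level from stage-wise cohort means).

A thin CLI wraps the same functionality:

```sh
marrow-reservoir generate --seed 1 --out cohort.csv
marrow-reservoir simulate --scenario pathological --out traj.csv
marrow-reservoir analyze --cohort cohort.csv --out stats.csv
marrow-reservoir run --config config.yaml --seed 1 --out results/
```

## Layout

- `src/marrow_reservoir/model.py` — reservoir ODEs, RK4, scenarios, stages
- `src/marrow_reservoir/cohort.py` — synthetic cohort generator
- `src/marrow_reservoir/stats.py` — ANOVA, Tukey, Dunnett, t-tests, stars
- `src/marrow_reservoir/calibrate.py` — observable maps, loss, fitting
- `src/marrow_reservoir/config.py`, `pipeline.py`, `cli.py` — configuration,
  end-to-end pipeline, command-line interface
- `docs/methods.md` — model assumptions, defaults, numerics, limitations
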