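# netguide

Idiographic network-guided treatment personalization for intensive
longitudinal (EMA) data, with single-case evaluation.

## The problem

Process-based therapies would like to pick, for each individual patient,
the intervention targeting the process that drives the rest of their
symptom network. Given a baseline of ecological momentary assessments
(here: six psychological-inflexibility facets, pain interference,
motivation and pain intensity, each rated 0–100 up to five times a day),
the question is: *which node, if reduced, would most reduce the others?*
— and, afterwards, *did the matched intervention actually help?*

`netguide` implements that full chain:

1. **Continuous-time VAR (Ornstein–Uhlenbeck) networks.** The p-node
   process follows `dx = A (x − μ) dt + G dW`, observed with noise at
   irregular response times. The drift matrix `A` (entry `A[i,j]` =
   instantaneous effect of node *j* on node *i*, per hour) is estimated
   by maximum likelihood through an exact Kalman filter over the actual
   timestamps — no equal-spacing assumption. Lagged effects at any
   interval Δ are `Φ(Δ) = e^{AΔ}`.
2. **Centrality-guided two-stage selection.** Total effect centrality
   `TEC_j(Δ) = Σ_{i≠j} Φ(Δ)[i,j]` at Δ = the median assessment interval
   ranks the three facet composites (stage 1: composites + interference);
   the most/least central composites define the MCNI/LCNI treatment
   phases, and two three-node facet networks (stage 2) order the sessions
   within each phase. Indirect effect centrality (IEC = total minus
   single-edge direct effects) and a grid of discrete-time alternatives
   (detrended, normal-scores-transformed graphical VAR; penalized and
   unpenalized contemporaneous partial-correlation networks; strength /
   expected influence / betweenness / closeness) are available for
   retrospective comparison.
3. **Single-case evaluation.** Tau-U ("A vs B + Trend B − Trend A")
   with exact S-statistics and an additive null SD, visual-analysis
   metrics (phase contrast, >30 % overlap rule, last-5-vs-first-5
   immediacy), and the 0.87-point minimal-important-difference flag for
   the 0–10 BPI interference scale.
4. **Synthetic EMA generator.** A 7-node OU ground truth with a planted
   hub (so the correct guidance answer is known), the study's prompt
   schedule (8/11/14/17/20 h with 0–3 h response jitter, one once-daily
   item), 14–20-day randomized baselines, sporadic missingness, and
   ramped phase-onset intervention effects that reach the outcome only
   through the network couplings.

## Worked example

```python
import numpy as np
from netguide import (default_registry, default_truth, make_schedule,
                      simulate_ema, guide_treatment, evaluate_sced,
                      GuidanceConfig)
from netguide.synth import default_interventions

registry = default_registry()
truth = default_truth(registry)
truth.interventions = default_interventions(truth, registry, shift=30.0)
sched = make_schedule(baseline_days=20, seed=3)
series, sidecar = simulate_ema(truth, sched, seed=3, registry=registry)

base = series.data.index[(series.phase == "baseline").to_numpy()]
baseline = type(series)(series.participant,
                        series.data.loc[base].dropna(how="all"),
                        series.phase.loc[base])
plan = guide_treatment(baseline, registry,
                       GuidanceConfig(measurement_noise="zero"), seed=3)
print(plan.mcni_composite, plan.mcni_facet_order)
print(evaluate_sced(series, ["interference"])[["contrast", "tau", "p", "band"]])
```

prints (numbers from this exact seed):

```
awareness ('LPMA', 'SAC')
          contrast       tau             p             band
0  baseline-phase1 -0.257640  6.118355e-07  moderately high
1  baseline-phase2 -0.299339  6.846306e-09  moderately high
2    phase1-phase2 -0.023947  6.746627e-01            small
```

— on this seed the fitted baseline network recovers the planted
most-central composite (awareness, hub facet LPMA delivered first), and
the trend-corrected Tau-U shows the planted interference reduction in
both intervention phases relative to baseline. Recovery from a single
short baseline is itself stochastic: `analysis/05_recovery_experiment.py`
quantifies it (~100 %, by construction, when guidance scores the
generating matrix; a clear majority of replicates at 150 baseline
occasions, rising with 600; chance level under a no-ordering null).

The numbered scripts under `analysis/` run the full study pipeline on a
simulated six-participant cohort: `01_simulate_cohort.py` (randomized
multiple-baseline design), `02_guide_treatment.py`,
`03_evaluate_effects.py`, `04_alternative_guidance.py` (the
retrospective method grid for a participant subset) and
`05_recovery_experiment.py` (how often fitted guidance recovers the
planted hub, by baseline length). A `netguide` CLI
(`simulate | guide | evaluate | run`) wraps the same library calls.

## Layout

```
src/netguide/     ema.py (registry, I/O, composites, interpolation)
                  ctvar.py (OU model, exact discretization, Kalman
                            likelihood, ML fit + parametric bootstrap)
                  centrality.py (effect matrices, TEC/IEC, intervals)
                  dtnet.py (detrend + normal scores, graphical VAR,
                            EBIC-selected glasso, DT centralities)
                  guidance.py (two-stage selection, design randomization,
                               alternative-method grid)
                  sced.py (Tau-U, visual metrics, BPI flags)
                  synth.py (schedule, planted-hub truth, generator,
                            recovery experiment)
                  pipeline.py / cli.py (orchestration)
analysis/         numbered narrative drivers (see above)
tests/            pytest suite incl. acceptance checks
docs/methods.md   model, assumptions, parameter choices, limitations
```
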