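# Methods

## Data model

EMA records are long-format tables (participant, timestamp, phase, item,
value) on a 0–100 visual-analogue scale, pivoted internally to a wide
time-indexed frame. Timestamps are continuous hours since study start
and represent *response* times (prompts at 8, 11, 14, 17, 20 h with a
0–3 h response window), so inter-occasion gaps are irregular by design:
roughly 3 h within a day, ~12 h overnight, giving a median assessment
interval near 3.5 h. Phases run baseline → phase1 → phase2 and must be
contiguous.

The item registry fixes nine items: the interference outcome, once-daily
motivation, pain intensity, and six psychological-inflexibility facets
(experiential avoidance EA, fusion, lack of present-moment awareness
LPMA, self-as-content SAC, lack of values clarity LV, inaction), paired
into three composites — openness (EA + Fusion), awareness (LPMA + SAC),
engagement (LV + Inaction). A composite is the arithmetic mean of its
two facets, which keeps the 0–100 scale; when one member is missing the
observed member is used alone and the occasion flagged, so isolated
facet missingness does not cascade into the network stage.

Missing values are interpolated linearly in *clock time* (not occasion
index) between the nearest observed neighbours of the same phase;
leading/trailing gaps within a phase carry the nearest value, and
nothing is ever interpolated across a phase boundary, because all
downstream analyses are phase-wise. Interpolation is idempotent and the
identity on complete data; the original missingness mask is preserved.

## Continuous-time VAR (Ornstein–Uhlenbeck) model

The latent p-vector follows `dx = A (x − μ) dt + G dW`, observed as
`y = x + e` with diagonal measurement-noise variances R. Convention
(pinned throughout): `A[i, j]` is the instantaneous effect of node j on
node i, so lagged effects and centralities are column sums over
receivers. Stationarity requires all eigenvalues of A to have negative
real part; the stationary covariance solves `A S + S Aᵀ + Q = 0`
(solved directly via the Lyapunov solver).

Exact discretization over a gap dt: `Φ(dt) = e^{A·dt}` (scaling-and-
squaring matrix exponential; inside the likelihood a one-off
eigendecomposition of A evaluates all gaps at once, with an automatic
fall-back to per-gap `expm` when A is defective) and innovation
covariance `Q_dt = S − Φ S Φᵀ`. Because discretization is exact at any
gap, irregular spacing costs nothing.

**Likelihood.** A Kalman filter over the actual timestamps gives the
exact Gaussian log-likelihood; missing components at an occasion are
marginalized by dropping rows of the observation, so a fully missing
occasion is exactly neutral. When R = 0 and the series is complete, the
filter reduces to a product of transition densities, which we evaluate
in a single batched pass — this fast path is what makes the replicated
recovery experiments affordable.

**Estimation.** Maximum likelihood over (A, μ, chol Q, log R) with
L-BFGS-B. Data are standardized per node internally and estimates
mapped back, making the fit exactly equivariant to affine rescaling.
Start values: drift from the matrix logarithm of a lag regression on
near-median gaps (fall-back: diagonal −1/h), Q from the Lyapunov
identity at the sample covariance, μ at the sample mean. Stability is
enforced by penalizing iterates whose leading eigenvalue real part
exceeds −1e−4. Non-convergence flags the result rather than raising.
Default minimum series length is 30 occasions.

**Uncertainty.** Parametric bootstrap: simulate B datasets from the fit
at the observed timestamps, refit each warm-started at the point
estimate, and keep the replicate drift matrices. Centrality intervals
are the 25th–75th replicate percentiles — a deliberate likelihood-based
stand-in for a Bayesian 50 % posterior interval, reported alongside the
point estimate. Selection always ranks by the point estimate; ties
break by the same index at twice the delta-time, then lexicographically,
so every ranking is deterministic. R defaults to freely estimated; a
config switch fixes R = 0 (used by the desk-scale recovery experiments,
where it roughly halves the parameter count and removes the sequential
filter).

## Centrality

Total effect centrality at lag Δ: `TEC_j(Δ) = Σ_{i≠j} Φ(Δ)[i, j]`; the
outcome is always a receiver but never a candidate. Indirect effect
centrality removes single-edge direct effects: for the pair j → i the
direct effect is `e^{Ã·Δ}[i, j]` with Ã keeping A's diagonal plus the
single entry `A[i, j]`; IEC sums the remainders. This direct-effect
blocking convention is stated explicitly because competing definitions
exist; it is a documented package convention, and both indices are
evaluated over Δ-grids for profile analyses. Default Δ is the median
inter-occasion interval of the analyzed series, computed after
interpolation.

## Discrete-time alternatives

Per item: OLS detrend in clock time, then the rank-based normal-scores
transform `Φ⁻¹((rank − 0.5)/n)` (invariant to monotone re-expression).
Lag-1 VAR uses only within-day consecutive occasion pairs — overnight
lags are excluded, the standard EMA convention. Contemporaneous
networks are partial correlations from the VAR-residual precision,
`ρ[i,j] = −K[i,j]/√(K_ii K_jj)`. The penalized path runs per-node L1
regressions for the temporal part and the graphical lasso for the
precision, both selected by EBIC (γ = 0.5) over a 50-point log-spaced
grid with min/max ratio 0.01; this two-stage scheme replaces the joint
algorithm of the original graphical-VAR formulation, a documented
divergence. The unpenalized path is OLS plus the inverse sample
covariance (erroring, with a pointer to the penalized path, when that
covariance is singular). DT centralities: strength Σ|ρ|, expected
influence Σρ, betweenness and closeness on edge lengths 1/|ρ| with
closeness = 1/Σ(shortest distances) and 0 for nodes that cannot reach
the whole graph. Temporal DT matrices are reported but never drive
guidance by default (short single-subject series leave them
underpowered).

## Two-stage guidance

Stage 1 fits the 4-node CT-VAR on {openness, awareness, engagement,
interference} and ranks composites by TEC at the median interval:
argmax → MCNI, argmin → LCNI (always distinct; the outcome is excluded
from candidacy). Stage 2 fits two 3-node facet networks (the chosen
composite's two facets + interference): most central facet first in the
MCNI phase, least central facet first in the LCNI phase. Keeping the
networks at 3–4 nodes is intentional — small idiographic networks are
the regime where estimates are usable at these series lengths. Baseline
length is randomized uniformly over 14–20 days and phase order by a fair
coin, both seed-deterministic. Each facet maps to two fixed session
content identifiers. A redacted export (session ids without node names)
supports blinded delivery. The retrospective grid evaluates ~40
alternative matching procedures (CT TEC/IEC at 4 and 7 variables,
smaller delta-times, strongest lagged path to interference, penalized /
unpenalized DT contemporaneous paths and centralities, highest baseline
facet mean, strongest baseline facet–outcome correlation); any method
failing on a given dataset yields an NA cell, never a pipeline failure.

## Single-case evaluation

Tau-U combines the cross-phase dominance S (sign sum over all A×B
pairs) with within-phase Kendall trend corrections; the reported variant
is `S = S_AB + S_trendB − S_trendA` with denominator
`nA·nB + nB(nB−1)/2 + nA(nA−1)/2`. Ties contribute zero everywhere.
The null SD is the additive `√(Var S_AB + Var S_trendA + Var S_trendB)`
— the three components are exactly uncorrelated under an exchangeable
null (the shared-element covariances ±1/3 cancel over pair positions),
which the tests confirm against a permutation distribution (within 3 %)
and by type-I-error calibration. Interpretation bands: |τ| < 0.2 small,
0.2–0.6 moderately high, 0.6–0.8 high, > 0.8 very high. One structural
consequence worth knowing: the full variant's denominator caps a pure
sustained level shift at |τ| ≈ nA·nB/denominator ≈ 0.5 for two-week
phases — large shifts reach the upper bands only through the dominance
variant or via within-phase trends (e.g. a ramped onset). Missing data
are either interpolated (default, interpolated points then count as
ordinary points) or excluded (sensitivity analysis). Each intervention
phase is one SCED phase.

Visual metrics per contrast: overlap = share of later-phase points
inside the earlier phase's [min, max] (flagged when > 30 %); immediacy =
|mean(last 5 of earlier) − mean(first 5 of later)|, undefined below 5
points; per-phase mean/SD/OLS slope. BPI interference (0–10): change
≥ 0.87 flags meaningful improvement (symmetrically, worsening).

## Synthetic ground truth

The generator exists so that every pipeline stage can be tested against
a known answer. Seven nodes (six facets + interference) follow an OU
network with decay 0.5/h, stationary SD ≈ 19 scale units, means 30–50,
and measurement noise SD 5. Outgoing couplings per facet (per hour,
onto every other node): LPMA 0.14 (the planted hub), SAC 0.04, LV 0.05,
Inaction 0.03, EA 0.016, Fusion 0.008, plus weak outcome feedback
0.015. These magnitudes were fixed once, at design time, so that the
planted composite ordering (awareness > engagement > openness, TEC at
Δ = 3 h: 0.49 / 0.23 / 0.07) is strict and identifiable from desk-scale
baselines; the within-awareness hub (LPMA) and within-openness minimum
(fusion) are likewise strict. A composite-level 4-node model is induced
by projection (`A₄ = L A₇ L⁺` with L averaging facet pairs); exact
aggregation is impossible whenever one facet is a hub — the aggregation
condition forces within-composite columns to have equal summed effects
— so the projected model is an approximation whose planted ordering is
asserted at construction. A null variant gives every facet the same
coupling (guidance should then succeed at chance, 1/3).

Interventions are constant inputs on the targeted facets' equations
(`c_j = −shift·|a_jj|`, ramped linearly over 3 days, piecewise-constant
per gap), so the equilibrium moves by `−A⁻¹c`: the targeted facets drop
by roughly the nominal shift and interference responds *only through
the couplings* — a pure mean shift would not propagate at all, which is
why the input formulation is used. Default cohort effect size is 15
scale units (a moderate, realistic EMA effect); the large-effect
scenario used for evaluation sanity checks is 60 (realized interference
drop ≈ 35 points ≈ 1.9 SD). Motivation and pain intensity are noisy
affine reads of the latent state (motivation = 95 − 0.9·mean(facets),
SD 6, once daily; pain = 8 + 0.85·interference, SD 6) — declared
generator artifacts, not empirical claims. Whole occasions go missing
with probability 0.05 by default; values are clipped to [0, 100] with
the clipping rate logged (< 1 % at default settings).

What the generator does *not* emulate: carry-over or decay of
intervention effects between phases, time-varying networks, floor
effects from skewed real-world distributions, response-time
autocorrelation in compliance. Passing tests therefore demonstrate that
the machinery is correct and calibrated under the stated model, not
that real EMA data satisfy that model.

## Problem sizes and numerics

Desk-scale defaults: recovery experiments use 150-occasion baselines
(about 30 days) with up to 100 replicates, 600 occasions for the
more-data comparison at fewer replicates, bootstrap B = 20 for the
2-node parameter-recovery study and B = 0 during replicated guidance
runs; these sizes keep each experiment in the minutes range while
leaving the binomial error small relative to the effects tested.
Numerical tolerances: Lyapunov/semigroup identities at 1e−10, effect
matrices vs ODE integration at 1e−8, state-space vs closed-form AR(1)
likelihood at 1e−6. Cholesky factorizations receive a 1e−12 jitter;
innovation-covariance failures reject the optimizer iterate rather than
crash. All randomness flows through explicit seeds; identical
config + seed reruns are bit-identical (the pipeline log stores only
relative paths for this reason).

## Known limitations

- The likelihood-based fit with bootstrap intervals stands in for a
  Bayesian posterior; the "50 % interval" is a bootstrap interquartile
  range, not a credible interval.
- Centrality point estimates from single short baselines are noisy; the
  recovery experiment quantifies exactly how noisy, and rank stability
  (not value stability) is the quantity guidance relies on.
- The two-stage composite-then-facet scheme inherits the composite
  approximation error described above; facet-level 7-node guidance is
  available in the alternative grid but needs longer series.
- Tau-U p-values use the normal approximation; below ~8 points per
  phase they are indicative only.
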