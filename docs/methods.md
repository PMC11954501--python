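# Methods

## Evidence model

A network meta-analysis treats each randomized trial as evidence about
relative effects between the treatments it compares, and ties all trials
together through basic parameters `d_k`: the effect of treatment `k`
versus a common reference on the linear-predictor scale (log hazard
ratio for time-to-event outcomes, log odds ratio for response outcomes,
log discrete-hazard ratio for adverse events). All pairwise effects are
differences `d_j − d_k`; the consistency assumption — that direct and
indirect evidence estimate the same quantity — is what the node-split
module probes.

Networks are built from arm- or contrast-level records. Node identity is
the exact regimen token (drug + dose + schedule), so dose variants are
distinct nodes. Clinically exchangeable arms (e.g. the various
placebo/corticosteroid controls) can be merged through a configured
merge map; a trial whose arms all collapse onto one node carries no
contrast and is dropped with a warning. Trials not connected to the
reference cannot inform the model and are excluded with a warning rather
than failing the run. Multi-arm trials stay single trials contributing
all contrasts against their baseline arm — splitting them into pseudo
two-arm trials would double-count the shared arm.

## Effect derivation

Published summaries are converted to a log effect and standard error:

* HR with 95% CI: `log_effect = ln HR`, `se = (ln hi − ln lo)/(2·1.96)`.
* 2×2 responder tables: Woolf log odds ratio with
  `se = sqrt(Σ 1/cell)`; when any cell is zero, 0.5 is added to all four
  cells first (Gart correction — triggered only by an empty cell).
* Percentages: counts are recovered as `round(pct·n/100)`, halves
  rounding away from zero.

When both a reported HR+CI and a digitized curve exist for a trial, the
reported HR wins.

## Kaplan–Meier reconstruction

For trials publishing only a KM plot, digitized click-points and the
number-at-risk table are inverted into pseudo individual-patient data.
Within each interval between risk-table times, a censoring count is
iterated until the implied at-risk number at the next risk time matches
the published one; censoring times are spread evenly within the
interval, and event counts at each click-point follow from the
product-limit recursion. A click exactly at a risk-table time is
attributed to the preceding interval (the published at-risk number
refers to just after any drop at that time). In the final interval,
which no later risk number constrains, the censoring rate of the
preceding follow-up is assumed; if the publication reports the total
event count, the final interval is instead tuned to match it, with any
residual rounding absorbed by relabelling the latest records. Survival
rises up to 1e-6 (digitization noise) are clamped flat; larger rises are
rejected.

The log-HR is then estimated by a two-group Cox proportional-hazards
partial likelihood with Efron tie handling, Newton–Raphson with step
tolerance 1e-8 (≤50 iterations), SE from the inverse observed
information. A monotone likelihood (all events on one side of every risk
set) is detected and refit with the Jeffreys/Firth penalty
`½ ln I(β)`, flagged by a warning.

## Bayesian NMA

Likelihoods: normal/identity on contrast-level log-HRs
(`y_ik ~ N(δ_ik, se_ik²)`) and binomial/logit on arm-level counts
(`r_ik ~ Bin(n_ik, p_ik)`, `logit p_ik = μ_i + δ_ik`). Fixed effect:
`δ_ik = d_k − d_b(i)`. Random effects: `δ_ik ~ N(d_k − d_b(i), τ²)`
with a common τ; the contrasts of a multi-arm trial are jointly normal
with covariance τ²/2, handled exactly through the joint prior (inverse
`(2/τ²)(I − J/(p+1))`, log-determinant `p ln(τ²/2) + ln(p+1)`).
Contrast-level likelihood correlation in multi-arm trials would need a
baseline variance the publications rarely report; absent that, contrasts
are treated as independent in the likelihood with a logged warning.

Priors: `d, μ ~ N(0, 100²)` (vague on the log scale);
`τ² ~ LogNormal(−3.95, 1.79²)`, the empirically derived informative
prior for pharmacological comparisons on mortality/major-morbidity
outcomes — equivalently `ln τ ~ N(−1.975, 0.895²)`, which is how the
sampler parameterizes it. Both hyperparameters are configurable.

### Sampling

The sampler is a Metropolis-within-Gibbs scheme, vectorized across
chains (and across replicate datasets in simulation studies):

* **Normal-likelihood models.** The fixed-effect posterior is fully
  conjugate and is sampled exactly. The random-effects model uses a
  partially collapsed Gibbs sweep: an adaptive random-walk Metropolis
  step on `ln τ` targeting the δ-marginalized conditional
  (`y ~ N(Xd, V + Σ(τ))`), an exact multivariate-normal draw of `d`
  from the same marginalized model, then a conjugate draw of δ from its
  full conditional. Collapsing δ removes the τ–δ funnel that makes
  uncollapsed samplers mix pathologically as τ → 0.
* **Binomial models.** No conjugacy exists, so every parameter takes a
  per-coordinate random-walk Metropolis update.

Metropolis step sizes adapt toward 44% acceptance during burn-in
(Robbins–Monro, gain `min(0.25, 2/(1+t)^0.6)`) and are frozen for the
sampling phase, keeping the kept draws Markovian. Chains start
dispersed: effects jittered around zero, `ln τ` drawn from its prior,
binomial baselines at empirical logits. All draws derive from one seeded
generator; results are bit-reproducible given (seed, chains, schedule).

Defaults: 4 chains, thin 1, and the full-scale schedule of 60 000
burn-in plus 60 000 sampling iterations. Unit tests and the bundled
calibration studies use shorter schedules (stated per study below);
the convergence gates are checked in every case.

### Diagnostics and fit

Rank-normalized split R-hat and bulk/tail ESS (via arviz) are computed
for `d`, `τ`, `μ` and any split parameter; a fit passes only if every
R-hat < 1.05 and both ESS > 400. Per-trial latent δ's are summarized but
not gated — they are data-local nuisance parameters whose conjugate
updates mix by construction. Absolute fit is the posterior-mean total
residual deviance (normal: `Σ((y−θ)/se)²`; binomial: the saturated
deviance), compared with the number of unconstrained data points;
relative fit is DIC = mean deviance + pD with pD = mean deviance minus
deviance at the posterior means (for the binomial model, at the
posterior-mean arm probabilities).

## Ranking

Each posterior draw orders the treatments in the declared benefit
direction (hazard-type efficacy outcomes: lower is better; response
odds: higher is better; adverse-event hazards: lower is better). Rank
probabilities are empirical frequencies; ties — measure-zero for
continuous posteriors but present in degenerate inputs — are broken by a
seeded uniform permutation. SUCRA is the normalized area under the
cumulative ranking curve; p-best is the first rank-probability column.
League tables are ordered by descending SUCRA, each cell the median
ratio (column vs row) with its 95% CrI and a flag when the CrI excludes
1.

## Consistency

A comparison is splittable when it has direct trial evidence and the
network still connects its endpoints after the direct trials are set
aside. Node-splitting refits the model with the direct evidence loading
on its own parameter ω; the indirect estimate comes from the remaining
network parameterization, and `p = 2·min(P(ω−indirect > 0),
P(ω−indirect < 0))` is the two-sided tail probability. Splitting never
drops data — only the parameterization changes.

## Penalized-likelihood safety model

Adverse events are rare and follow-up differs across trials, so safety
outcomes use a fixed-effect binomial GLM with complementary log-log link
and `ln f_i` offset (f in months): under constant hazards
`p = 1 − exp(−f·rate)`, so `exp(d)` estimates a rate ratio. Estimation
is Newton–Raphson with Fisher scoring; the default Firth/Jeffreys
penalty `½ ln det I(θ)` enters through hat-value-adjusted scores,
removes the leading-order MLE bias and keeps zero-cell estimates finite.
Convergence: max |adjusted score| < 1e-8 within 100 iterations; an
unpenalized fit drifting beyond |log dHR| > 10 is flagged as a monotone
likelihood rather than reported as converged. A trial without reported
follow-up gets the cross-trial median imputed, with a warning surfaced
in the result and the manifest. Wald 95% CIs come from the inverse
information; pairwise contrasts use the delta method on the full
covariance. Random-effects safety models are deliberately out of scope.

## Synthetic data

The generators emulate the statistical shape of a sparse oncology
evidence base: star-plus-random-chords topologies (most comparisons
informed by a single trial), contrast SEs uniform on 0.1–0.3, per-arm
sizes 100–400, control response levels logit-uniform on (−2, −0.5),
adverse-event rates 0.0005–0.002 per month with follow-up 12–36 months
(rare-event mode caps every arm probability at 2%), and exponential
survival with administrative censoring digitized at 100 click-points
with risk tables every 6 months. Effects default to a ±0.5 log-scale
spread; between-trial heterogeneity defaults to τ = 0.2, a moderate
value for oncology HRs. One master seed drives fixed per-component
substreams, so adding a generator never perturbs existing draws.
Paper-shaped fixtures reproduce published network dimensions (13/14,
20/18, 26/25, 7/6, 12/11 trials/treatments).

What the generators do *not* emulate: patient-level covariates and
effect modification, non-proportional hazards, informative censoring,
outcome correlation within trials, and reporting artifacts beyond KM
digitization noise. Passing tests therefore demonstrate that the
machinery recovers known truth under the stated generative models, not
that any particular clinical dataset satisfies those models.

## Study sizes used by the bundled checks

The calibration studies are sized to give stable Monte-Carlo behaviour:
the random-effects recovery study uses 20 replicate networks of 12
trials over 5 treatments at a 10 000/10 000 schedule; node-split
calibration uses 200 consistent triangles (fixed-effect, exact
sampling); the rare-event bias study uses 200 replicate networks; the
published-size convergence check runs the 20-trial/18-treatment fixture
(the acceptance script at the full 60 000/60 000 schedule, the test
suite at 10 000/20 000 — both pass the same gates). Replicate fits are
batched through the vectorized sampler, which is why these studies run
in seconds to minutes on one CPU.

## Known limitations

* The binomial sampler's per-coordinate random walk needs longer
  schedules than the collapsed normal-model sampler on large arm-based
  networks; the ESS gates make any shortfall visible.
* Node-splitting of a comparison inside a multi-arm trial follows the
  simple rule of reparameterizing every contrast on that pair; more
  refined multi-arm split conventions exist.
* The KM reconstruction assumes non-informative censoring spread evenly
  within intervals, as the inversion requires.
* Contrast-level inputs cannot recover likelihood-level multi-arm
  correlation without a reported baseline variance (warned, see above).
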