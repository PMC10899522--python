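# Methods

## Task model and conventions

A trial is a (role, frame, exchange-ratio, budget) tuple; its choice set is
the `T + 1` whole-token splits of the budget (tokens are discrete objects, so
no finer granularity is modelled). Payoffs are in signed cents:
`M_s = r_s T_s`, `M_o = r_o T_o` in the gain frame, negated in the loss
frame. The negative-cents convention is what makes the selfish rule
frame-dependent — maximizing `M_s` means keeping 100% of tokens in gain and
0% in loss — while the payoff-equalizing kept fraction
`r_o / (r_s + r_o)` is frame-invariant, since both payoffs flip sign
together. Conditions are indexed `k = 1..4` as first/gain, first/loss,
third/gain, third/loss; role never alters the payoff arithmetic (in
third-party the "self" payoff belongs to the represented dictator).

One deliberate reading: the general-inequity model (M3) penalizes the
*magnitude* `|M_s − M_o|`. The model is defined as aversion to inequity
without dissociating its direction, and the absolute value is the only form
that makes `ω` a pure inequity weight; anyone comparing against a
signed-difference variant should note this choice.

## Behavioral metrics and the mixed ANOVA

Deviations are computed on kept fractions so rounds with different budgets
are commensurable; both deviations live in [0, 1]. Selfish deviation is
`|1 − c|` (gain) / `|0 − c|` (loss); equal deviation is
`|r_o/(r_s+r_o) − c|`. A worked example at `T = 3`, `T_s = 1`: the kept
fraction is 33.3%, so the loss-frame selfish deviation is 33.3% and the
gain-frame selfish deviation is 66.7% (the complement of the kept
fraction); under ratio 1:3 the equal deviation is |75% − 33.3%| ≈ 41.7%.

The 2×2×2 mixed ANOVA is written out from sums of squares rather than
delegated to a stats library, so that it can be verified cell-by-cell
against an independent brute-force decomposition (and it is, in the test
suite). With two-level factors each within-subject effect reduces to a
per-subject contrast score; each within stratum is a one-way between-groups
layout on that score, with the subject-nested error term, and sphericity
holds trivially. Unequal group sizes are supported via Type III
(unweighted-marginal) sums of squares for within-stratum main effects;
between-group sizes may differ, incomplete within-subject cells may not.
Partial eta squared is `SS_effect / (SS_effect + SS_error)` within the
effect's stratum. Post-hoc simple effects for the role × group interaction
report group differences within each role (subject means over frames,
pooled two-sample SE on N−2 df) and role differences within each group
(paired scores, error pooled across groups); p-values are uncorrected by
default with an optional Bonferroni flag, since no correction is assumed by
the reporting format they mirror.

## Likelihood and hierarchical estimation

The softmax choice rule is evaluated over the trial's full option set with a
log-sum-exp guard; `λ·U` magnitudes up to at least 10⁴ are safe, and the
probability simplex is exact to 1e-12. `λ = 0` (uniform choice) is allowed
for diagnostics; fitting constrains `λ > 0` by a log link.

The hierarchy is non-centered: each individual parameter is
`θ_ik = μ_k + σ_k z_ik` with `z ~ N(0,1)`, and positivity-constrained
parameters (λ always; α, β under M5) are `exp(θ)`. One λ per participant is
shared across conditions — the choice rule's temperature carries no
condition subscript, and freeing it per condition would confound
temperature shifts with weight shifts. Hyperpriors are `μ ~ Normal(0, 1)`
and `σ ~ half-Cauchy(0, 2)`, applied literally on the sampling scale; the
prior family and scales are configurable (`PriorSpec`). A consequence worth
knowing: group-level means far outside the N(0,1) scale (say, 3–4) are
partially shrunk when the data identify them weakly. This is visible for
the disadvantageous-inequity weight β in first-party conditions, where
agents who keep at least the equal split rarely experience disadvantageous
inequity; the posterior there is prior-influenced by construction, and the
package reports it as such rather than silently rescaling the prior.
Between-subject groups are always fitted independently — group contrasts
compare two separate posteriors.

### Sampling

Sampling is Hamiltonian Monte Carlo with analytic gradients (no autodiff
dependency): the likelihood gradient w.r.t. the per-trial inequity
coefficients and temperature has closed form (softmax expectations of the
inequity branches and utilities), and the chain rule maps it back through
the non-centered transform. Warmup uses dual-averaging step-size adaptation
toward a 0.9 acceptance target, with a diagonal mass matrix estimated from
an intermediate warmup window (regularized toward unity, as short windows
require); sampling draws a uniformly jittered number of leapfrog steps with
nominal integration time 2.0 in mass-standardized coordinates (capped at
128 steps). Divergences (energy error > 1000 or numerical overflow) are
rejected and counted. Initialization jitters prior-scale draws, with the
temperature started low so early utilities cannot saturate the softmax;
initialization retries up to 5 times if the starting density is not finite.
Chain seeds derive deterministically from the master seed, so fits are
exactly reproducible.

The default configuration is 3 chains × 2000 retained draws after 2000
warmup iterations (6000 retained draws). Convergence is assessed by
split-chain Gelman–Rubin R̂ on every coordinate; any R̂ > 1.01 triggers a
warning and flags the fit (`converged = False`) rather than failing —
degenerate zero-variance draws return NaN and are flagged likewise.

## Model comparison

WAIC is `−2(lppd − p_waic)` with the variance-based penalty (draw variance
with ddof = 1, as in the reference R implementation). PSIS-LOO smooths each
observation's largest 20% of importance ratios with a generalized Pareto
fit (Zhang–Stephens profile posterior with the standard weak prior pulling
the shape toward 0.5), truncates smoothed weights at the raw maximum, and
flags trials with shape k > 0.7. A point-mass posterior makes LOOIC equal
WAIC exactly. Weights are Akaike-type, `w ∝ exp(−Δ/2)` on the deviance
scale — the form under which a 10-point score difference corresponds to
roughly 148:1 — with predictive stacking weights available behind a flag
since the two conventions can disagree when models overlap. The winner is
the minimum LOOIC, ties broken by WAIC.

## Inference reporting

HDIs use the shortest-window method on sorted draws (`ceil(mass·n)`-size
windows; mass 1 returns the sample range). The evidence rule: *meaningful*
if the 97.5% HDI excludes zero, *limited* if only the 85% HDI excludes it,
*none* otherwise; every report also carries the posterior mean and 95% HDI
for display. Both the 97.5% and 95% intervals are computed because
reporting conventions differ on which one anchors the rule.

Cross-condition contrasts **sum** the two cells of the collapsed factor
before differencing (role: `(θ₁+θ₂) − (θ₃+θ₄)`; frame:
`(θ₁+θ₃) − (θ₂+θ₄)`). Summing rather than averaging is a ×2 scale choice;
it is the convention under which the package's contrast magnitudes are
defined, and the tests pin it down as an arithmetic identity on fixed
condition means. Cross-group contrasts difference draws index-wise after an
independent within-fit shuffle (fixed seed): this preserves both marginal
posteriors — the two fits are independent, so any pairing is valid — while
avoiding spurious chain-order correlation; unequal draw counts are
resampled to match, with a warning.

The posterior predictive check simulates each participant on their actual
trial schedule from posterior-mean parameters (default) or from `n_rep`
joint posterior draws, then correlates replicate and observed mean kept
fractions per condition across participants and across the 20 within-block
trial positions (averaged over participants; a concatenation variant exists
behind a flag), and reruns the mixed ANOVA on the replicate when both
groups are present ("behavioral recovery"). Across-trial and
across-participant correlations are reported as undefined, not errors, when
either side has zero variance.

## Synthetic-data generator

The generator is the package's stand-in for the experiment: 4 blocks (one
per condition, ordered by a Williams 4×4 Latin square cycled over
participants) × 20 rounds; each of the 5 exchange ratios appears exactly 4
times per block (the only balanced assignment of 5 ratios to 20 rounds);
budgets drawn uniformly from a pool defaulting to {12, 24, 36, 48}, chosen
so the payoff-equalizing split is integral at every design ratio. Agents
choose by the softmax utility models; cohorts draw individual weights from
group-level normals on the sampling scale (so constrained models generate
through the same link the estimator assumes) and λ log-normally with
default median 0.2 /cents and log-SD 0.4 — a moderately deterministic
regime in which adjacent-option utility gaps of a few cents translate into
clear but non-degenerate preferences. Default group sizes are 34 and 31
with condition-specific weight means following the qualitative child/adult
pattern the task is designed to expose (children: α < 0 first-party,
α ≈ 3.3 third-party; adults: α ≈ 1.4–2.1 throughout; β ≈ 2.4–3.9
everywhere; individual SD 0.5). Randomness flows from one master seed
through per-participant substreams, so cohorts are reproducible regardless
of generation order.

What the generator does *not* emulate: response times and within-trial
mouse dynamics, dropout or missed trials, sequential dependencies
(learning, fatigue), and any deviation from the softmax-Fehr–Schmidt
family itself. Passing recovery tests therefore certify the estimation
machinery under the model's own assumptions — they do not certify the model
against real behavior; that is what the PPC and model-comparison stages are
for on empirical data.

## Validation studies and problem sizes

The test suite validates each stage at sizes chosen to keep the full run
desk-scale while leaving clear statistical margins:

* exact oracles — brute-force ANOVA sums of squares (1e-10), two-draw WAIC
  hand arithmetic (1e-12), exhaustive-search HDI (exact, up to 10⁴ draws),
  softmax simplex and λ-limit identities; arviz and emcee serve as
  independent external cross-checks of R̂/WAIC/LOO/HDI and of the posterior
  itself (an ensemble sampler run on the identical log density);
* parameter recovery — 15 participants simulated from the Fehr–Schmidt
  model (α −0.2 first-party / +2 third-party, β 2.5, σ 0.5), 2 chains of
  500 + 500: truth vs posterior-mean correlation for individual α across
  participants ≥ 0.7;
* interval calibration — 10 cohorts of 10 participants on a single
  12-token budget, generating means drawn from the hyperprior, 2 chains of
  300 + 300: 95% HDI coverage of group-level means ≥ 80%;
* model recovery — data from M4 with dissociated weights (α 0.8, β 2.5) is
  won by M4/M5 among all five candidates; data from M1 never lets M2 win
  decisively (10 points);
* qualitative pattern — full-size child-like and adult-like cohorts
  (34 + 31) reproduce the role × group interaction and its post-hoc sign
  pattern through the metrics pipeline.

## Known limitations

* Fixed-length (jittered) HMC, not NUTS: mixing is adequate for the
  hierarchies here but short reduced-scale chains can sit slightly above
  the 1.01 R̂ threshold; such fits are flagged, and production use should
  run the full 3 × 2000 + 2000 configuration.
* The literal N(0,1) hyperprior shrinks weakly identified group means (see
  above); use `PriorSpec(mean_scale=...)` to widen it when that is not
  wanted.
* Groups are modelled independently; there is no joint hierarchical model
  over groups, so group contrasts do not pool variance.
* The pipeline assumes the complete balanced within-subject design;
  participants missing a condition are rejected rather than imputed.
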