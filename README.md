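# fairshare

Inequity-aversion modelling of dictator-game allocations: behavioral
deviation metrics, hierarchical Bayesian estimation of competing
Fehr–Schmidt-family utility models, information-criterion model comparison,
posterior predictive checking, and HDI-based evidence reporting — with a
synthetic-data generator that emulates the full study design so every stage
of the pipeline can be validated end-to-end without participant data.

## The scientific problem

In a modified dictator game, a decision-maker splits a budget of `T` tokens
between themself (`T_s` kept) and an anonymous recipient (`T_o = T - T_s`
sent). Tokens convert to cents through an exchange ratio `r_s : r_o`
(design: 3:1, 2:1, 1:1, 1:2, 1:3), producing payoffs `M_s = r_s T_s` and
`M_o = r_o T_o` — negated in the **loss frame**, where tokens are losses and
the purely selfish optimum flips from keep-everything to keep-nothing.
Decisions are made for oneself (**first-party**) or on behalf of another
dictator (**third-party**), in 4 blocks (one per role × frame condition) of
20 rounds. Two between-subjects groups (e.g. children vs adults) are fitted
and contrasted. This design separates *fairness knowledge* (third-party
behavior) from *fairness behavior* (first-party behavior), and inequity
aversion from *advantage-seeking* (a negative weight on advantageous
inequity).

Two complementary analyses are implemented:

**Model-free metrics.** Each choice, normalized to the kept fraction
`c = T_s / T`, is scored by its deviation from the selfish rule
(`|1 - c|` in gain, `|0 - c|` in loss) and from the payoff-equalizing rule
(`|r_o / (r_s + r_o) - c|`). Per-participant condition means enter a
2 (Role) × 2 (Frame) × 2 (Group) mixed ANOVA with partial-η² effect sizes
and simple-effects post-hocs.

**Computational models.** Five utility models over the payoff pair, indexed
by condition `k ∈ {1..4}`:

| id | utility of (M_s, M_o) | interpretation |
|----|----------------------|----------------|
| M1 | `M_s − α_k·max(M_s−M_o, 0)` | advantageous-inequity concern only |
| M2 | `M_s − β_k·max(M_o−M_s, 0)` | disadvantageous-inequity concern only |
| M3 | `M_s − ω_k·\|M_s−M_o\|` | undissociated inequity aversion |
| M4 | `M_s − α_k·max(M_s−M_o, 0) − β_k·max(M_o−M_s, 0)` | Fehr–Schmidt |
| M5 | M4 with `α_k, β_k > 0` | pure-aversion Fehr–Schmidt |

Choice follows a softmax over the trial's full option set,
`P(j) ∝ exp(λ·U_j)`, with one inverse temperature `λ > 0` per participant.
Parameters are estimated by hierarchical Bayes: individual parameters drawn
from group-level normals `N(μ_k, σ_k)` (non-centered, exponential link for
constrained parameters), hyperpriors `μ ~ N(0,1)`, `σ ~ half-Cauchy(0,2)`,
sampled by the package's Hamiltonian Monte Carlo implementation with
analytic gradients (default 3 chains × 2000 draws after 2000 warmup = 6000
retained draws; split-R̂ < 1.01 required). Models are ranked by PSIS-LOO and
WAIC with Akaike-type weights, and group-level inferences are reported as
posterior means with HDIs and a categorical evidence rule (meaningful /
limited / none).

## Worked example

```python
import pandas as pd
import fairshare as fs
from fairshare.hba import HierarchicalChoiceModel
from fairshare.report import condition_contrast

# Simulate the two-group study design (here 12 + 12 participants).
specs = fs.default_cohort_specs(n_children=12, n_adults=12, seed=7)
parts = [fs.simulate_cohort(s, "M4") for s in specs.values()]
both = fs.ChoiceDataset(pd.concat([p.table for p in parts], ignore_index=True))

# Model-free analysis.
summ = fs.aggregate(both)
print(fs.mixed_anova(summ, "selfish_dev"))

# Hierarchical fit of the Fehr-Schmidt model for one group.
fit = HierarchicalChoiceModel(parts[0], "M4").fit(chains=2, warmup=400,
                                                  samples=400, seed=1)
print(fit.summary().head(4).to_string(index=False))
print(condition_contrast(fit, "alpha", "role")[1])
```

prints (abridged):

```
             group: F(1, 22) = 139.352, p = 5.444e-11, eta_p^2 = 0.864
              role: F(1, 22) = 267.598, p = 8.48e-14, eta_p^2 = 0.924
        role:group: F(1, 22) = 180.747, p = 4.352e-12, eta_p^2 = 0.891
             frame: F(1, 22) = 1.401, p = 0.2491, eta_p^2 = 0.060
  ...
  parameter      mean       sd  hdi_0.95_lo  hdi_0.95_hi     rhat
mu_alpha[1]  0.030696 0.136238    -0.248730     0.261165 1.017373
mu_alpha[2] -0.036568 0.145689    -0.307077     0.238717 1.004866
mu_alpha[3]  2.581892 0.251165     2.132903     3.102192 1.004921
mu_alpha[4]  2.428382 0.280895     1.952919     3.042729 1.019686
alpha role contrast (first - third), group=children:
  (mean = -5.016, 95% HDI: [-6.041, -4.076]) -> meaningful (below 0)
```

The strong `role:group` interaction and the negative first-minus-third α
contrast are the behavioral signature the generator's child-like population
builds in: advantage-seeking for oneself (`μ_α ≈ 0` / negative in
first-party), inequity-averse on others' behalf (`μ_α ≈ 2.5` in
third-party). The condition index `k` orders cells as first/gain,
first/loss, third/gain, third/loss.

The command-line interface mirrors the pipeline stages
(`fairshare simulate | metrics | fit | compare | ppc | report | recover`);
`fairshare report --reduced --out run/` executes the whole chain
(simulate → metrics → fits of M1–M5 per group → LOOIC/WAIC comparison → PPC
→ evidence report) at smoke-test scale and writes every artifact plus a
`manifest.json` with seeds and convergence summaries.

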