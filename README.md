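# aaimpact

Decision-analytic assessment of the evidence behind an FDA **Accelerated
Approval (AA)**: what a single-arm trial's surrogate-endpoint readout implies
about clinical benefit and toxicity, and what each stakeholder — patient,
physician, payer, HTA agency — should *do* about it given their own values.

AA grants market access on a surrogate endpoint that is reasonably likely to
predict clinical benefit, so every downstream decision rests on a small trial
and an uncertain surrogate-to-benefit link. `aaimpact` turns that situation
into an explicit, reproducible calculation:

1. **Inference.** With a Beta(α, β) prior on the surrogate-response
   probability *P* (and likewise on the severe-toxicity probability *Q*),
   observing *s* responders among *n* patients gives the conjugate posterior
   Beta(α+s, β+n−s), with closed-form means, equal-tailed credible intervals,
   and exceedance probabilities Pr(P > p₀ | data) for go/no-go rules.
2. **Outcome mapping.** An elicited linkage converts *P* into the probability
   of clinical benefit, p(E1) = P·Pr(CB|SE) + (1−P)·q, and *Q* into a
   four-category toxicity distribution; under independence the 3×4 joint
   grid collapses into six therapeutic-outcome categories x₁…x₆ (x₆ pools
   every unacceptable combination).
3. **Decision analysis.** A stakeholder's value table v_ij scores each action
   (refuse / accept / defer) against each outcome; the expected utility of
   action a_i is V(a_i) = Σ_j w_j·v_ij and the best-action set A* collects all
   maximizers. Case bounds (expected / worst / best), true-scenario sweeps,
   regret, and cross-stakeholder concordance are built on the same inner
   product.
4. **Simulation.** Monte-Carlo propagation of posterior (P, Q) draws into
   utility distributions and per-action optimality probabilities, plus a
   selection-bias study quantifying how much conditioning on approval
   (an upper-tail event in the response count) inflates the estimate of *P*.

## Worked example

A 50-patient single-arm trial in a cancer with no effective treatment:
15 patients show a positive surrogate effect, none a severe toxicity.
Priors: Beta(1, 9) for *P* (mean 0.10), Beta(2, 8) for *Q* (mean 0.20).

```python
from aaimpact import (elicit_beta_prior, posterior_for, credible_interval,
                      exceedance_probability)

post_p = posterior_for(elicit_beta_prior(0.10, 10), 50, 15)
post_p                                  # BetaParams(alpha=16.0, beta=44.0)
round(post_p.mean, 2)                   # 0.27
ci = credible_interval(post_p, 0.95)
round(ci.lower, 2), round(ci.upper, 2)  # (0.16, 0.38)
round(exceedance_probability(post_p, 0.20), 2)  # 0.88
```

The posterior puts 88% probability on P > 20%, so the trial clears a
"be at least 85% sure of exceeding 20%" success rule. Mapping the posterior
summaries through the linkage (Pr(CB|SE)=0.7, q=0.05) and collapsing:

```python
from aaimpact import example_config, case_bounds, decision_analysis
from aaimpact.report import case_bounds_frame

cfg = example_config()
cfg.reporting.paper_mode = True     # map from 2-dp posterior summaries
print(case_bounds_frame(case_bounds(cfg)).round(3))
```

```
               P      Q  p(E1)  x1 (E1,T1)  x2 (E1,T2)  x3 (E1,T3)  x4 (E2,T1)  x5 (E2,T2)  x6 (other)
case
Expected    0.27  0.030  0.226         0.0       0.109       0.109         0.0       0.376       0.406
Worst Case  0.16  0.090  0.154         0.0       0.070       0.070         0.0       0.385       0.475
Best Case   0.38  0.004  0.297         0.0       0.148       0.148         0.0       0.350       0.354
```

Even in the best case the chance of clinical benefit is ~0.30, and ~0.35 of
the probability lands in the unacceptable pool x₆. Whether to accept the
treatment then depends entirely on the stakeholder's values:

```python
da = decision_analysis(cfg)
print(da.utilities.round(1))
```

```
value_set  Value Set 1              Value Set 2
action          refuse accept defer      refuse accept  defer
Expected          -1.6  -17.2  -1.6      -178.2   -2.9 -178.2
Worst Case         9.7  -29.0   9.7       -92.6 -116.6  -92.6
Best Case        -11.9   -5.6 -11.9      -260.4  101.3 -260.4
```

Under the ruin-averse Value Set 1, accepting is never the expected-case best
action (refuse/defer tie at −1.6 vs −17.2); under Value Set 2, which weights
a clinical benefit ten times more heavily, accepting is the unique best
action in the expected and best cases. Same data, same probabilities —
the decision turns on the value table, which is exactly the point.

## Command line

```sh
aaimpact posterior    --config assessment.json          # posterior summaries + success rule
aaimpact map-outcomes --config assessment.json --paper-mode
aaimpact decide       --config assessment.json          # utilities, best actions, concordance
aaimpact sweep        --config assessment.json          # true-scenario utility table
aaimpact simulate     --config assessment.json --seed 7 # propagation + selection bias
aaimpact report --results out/results.json --format csv # re-render stored results
```

Configs are JSON (or YAML); outputs are CSV, aligned text, or a structured
JSON document embedding the full configuration and seed. `example_config()`
returns the bundled worked-example assessment.

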