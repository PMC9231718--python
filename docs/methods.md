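# Methods

## The model

`aaimpact` implements a statistical decision framework for evaluating what a
surrogate-endpoint trial behind an accelerated approval implies for each
stakeholder. The chain has four stages, each with an explicit probabilistic
model and explicit elicited inputs.

### Beta-binomial inference

The trial is a single arm of `n` exchangeable patients; the number with a
positive surrogate-endpoint effect and the number with a severe toxicity
event are modelled as independent Binomial(n, P) and Binomial(n, Q) draws.
Priors on P and Q are beta distributions, elicited either directly as
(α, β) or as a (mean, strength) pair with α = mean·strength,
β = (1−mean)·strength; strength is the prior's worth in pseudo-patients.
The bundled example uses Beta(1, 9) for P and Beta(2, 8) for Q — pessimistic
priors (means 0.10 and 0.20) with the weight of ten patients.

Posteriors are conjugate: Beta(α+s, β+n−s). Summaries are the posterior
mean, the **equal-tailed** credible interval (quantiles at (1−level)/2 and
1−(1−level)/2, computed by scipy's beta quantile function, absolute accuracy
well below 1e−10), and the exceedance probability Pr(P > p₀ | data) given by
the regularized incomplete beta function. A highest-posterior-density
interval is available (`method="hpd"`) for sensitivity analysis; the
equal-tailed interval is the default and is what every bundled table uses.
Trial success is a posterior-assurance rule: success iff
Pr(P > p₀ | data) ≥ γ. The required assurance γ deliberately has no
default — it encodes a stakeholder's risk tolerance, not a statistical
convention. γ = 1 is representable (and trivially unattainable for p₀ > 0);
p₀ = 0 is representable and trivially attained.

### Surrogate-to-outcome mapping

The surrogate is linked to tangible clinical benefit (CB) by two elicited
conditionals: Pr(CB | SE) (0.7 in the example) and q = Pr(CB | no SE). The
total-probability identity

    p(E1) = P · Pr(CB|SE) + (1 − P) · q

is affine in P, which matters twice: credible bounds on P map directly to
bounds on p(E1), and posterior expectations commute with the mapping. q is
validated only to [0, 1]; values above 0.15 trigger an advisory warning
(benefit without a surrogate signal should be rare for a validated
surrogate), and an inverted linkage (q > Pr(CB|SE)) warns but is legal.

Efficacy has three categories — E1 materially better, E2 similar, E3
inferior — with p(E2) = 1 − p(E1) − p(E3). The inferior-efficacy probability
defaults to 0, which is exact when no effective comparator exists, and is a
first-class input otherwise. Toxicity has four categories T1 (less toxic)
… T4 (intolerable); the structure fixes p(T1) (0 for an add-on regimen,
which cannot reduce the toxicity of the standard it joins), sets p(T4) = Q,
and splits the remaining mass between T2 and T3 by elicited weights
(default equal halves).

The joint 3×4 grid is the outer product of the marginals — efficacy and
toxicity independent. This is a simplifying default, not a claim about
biology (efficacy and toxicity often share a mechanism); a fully specified
12-cell grid can be supplied directly when a dependence model exists. The
twelve cells collapse to six decision-relevant categories: x1–x5 keep the
acceptable combinations ((E1,T1), (E1,T2), (E1,T3), (E2,T1), (E2,T2)) and
x6 pools everything unacceptable — intolerable toxicity, worse toxicity
without materially better efficacy, and all inferior-efficacy outcomes.
x6 is computed as the *sum* of its constituent cells rather than as a
complement, so collapse conserves total mass to the bit.

### Case bounds and the published worked example

The case-bound analysis maps three (P, Q) pairs through the chain: posterior
means (expected case), lower-P with upper-Q bounds (worst case), upper-P
with lower-Q bounds (best case). By the affine linkage and monotone
toxicity structure, the worst case maximizes the unacceptable mass x6
whenever the linkage is non-inverted.

Two numerical modes exist. The default maps full-precision posterior
summaries. `round_inputs=2` ("paper mode" in configs) first rounds the
(P, Q) summaries to reporting precision — 2 decimals, 3 below 0.01 — which
reproduces a hand calculation done from printed posterior summaries: with
P ∈ {0.27, 0.16, 0.38} the plug-in clinical-benefit probabilities are 0.23,
0.15, 0.30 at 2 dp, and the expected-case (E1,T2) cell is
0.23 × 0.485 ≈ 0.11.

One forensic note on reproducing the published version of this worked
example: its worst/best rows print the Q bounds (0.09, 0.004) in the Q
column but leave the toxicity split at the expected case (T2 = T3 = 0.485,
T4 = 0.03) in the cells — every printed cell agrees with that
fixed-toxicity derivation to its rounding precision, while propagating the
Q bounds (as the definition states, and as this package does) moves the
x5/x6 cells by up to 0.035. The acceptance suite checks both facts rather
than forcing either derivation to reproduce numbers the other produced.
The printed scenario and utility tables of the same example are not
reproducible from their own stated inputs at all (rows summing to 1.01,
utilities inconsistent with the stated inner product); tests therefore pin
the *orderings* those tables support — which actions are best where — not
their printed digits.

### Decision analysis

A value table assigns each (action, outcome) pair a real score v_ij on an
arbitrary interval scale; cells may be left **unset** for outcomes with
structural probability zero (e.g. (E1,T1) for an add-on therapy), and
evaluating an unset cell against positive probability is an error naming
the cell — an unvalued outcome that can occur is an elicitation gap, not a
zero. Expected utility is the inner product Σ_j w_j·v_ij; with estimated
probabilities this is V_est and its maximizer set A*, with true scenario
probabilities V_True and A_opt. Best-action sets contain *all* maximizers
under exact full-precision comparison (an optional tolerance widens them to
near-ties); identical value rows — refuse and defer in the bundled tables —
therefore always tie. Utilities are equivariant under positive affine
rescaling v → a·v + b, so best actions are invariant to the scale and
origin each stakeholder happens to use. Regret is V_True(A_opt) − V_True(a).
Concordance across stakeholders sharing an action set is defined as a
non-empty intersection of best-action sets.

The two bundled value sets span the interesting disagreement: Value Set 1
(modest benefit reward, strong aversion to accepting a non-beneficial
treatment) never accepts in the expected case, while Value Set 2 (benefit
weighted 10×) accepts in the expected and best cases. They are
illustrations; real assessments supply elicited tables via the config.

### Simulation studies

`propagate_posterior_uncertainty` draws (P, Q) independently from the two
posteriors (default 10⁴ draws), maps each draw through the outcome chain,
and scores each action, yielding per-action utility means, spreads,
quantiles, Monte-Carlo standard errors, and the fraction of draws on which
each action is optimal (ties split equally by default, `tie_rule="first"`
available; fractions sum to 1 exactly). Because each collapsed probability
is bilinear in (p(E1), Q) and the draws are independent, the expectation of
the sampled utility equals the plug-in utility at the posterior means; the
plug-in value is reported alongside as a built-in oracle check.

`approval_selection_bias` quantifies the winner's curse of granting
approval only on strong early findings: trials are simulated at a known
true P, the posterior-assurance rule is applied to each, and the mean
posterior-mean estimate among approved trials is compared with the
unconditional mean. Approval depends on the data only through the response
count, so the rule is evaluated once per possible count and looked up per
trial — 10⁴ simulated trials cost one binomial draw. Approval is an
upper-tail event in the count, so the conditional mean is never below the
unconditional one; at true P = 0.15, n = 50, Beta(1, 9) prior and rule
(p₀ = 0.20, γ = 0.85), the bias is strictly positive. With zero approvals
the conditional mean is reported as undefined (None), not raised as an
error. All simulations are deterministic given the seed, which is recorded
in every output.

## What the synthetic generator does and does not emulate

`simulate_trial` reproduces the study design of the worked example:
independent per-patient Bernoulli surrogate response and severe toxicity at
fixed true rates, in a homogeneous population. It does not emulate
correlated efficacy/toxicity, patient covariates, accrual over time,
dropout, or between-trial heterogeneity — so passing simulation tests shows
the machinery is correct under the stated model, not that the model
captures any particular real program. Population transportability and
unequal information access among stakeholders are acknowledged sources of
uncertainty with no executable form here.

## Numerical choices

- All probability vectors validate to their simplex within 1e−9 on
  construction; the pipeline itself preserves normalization to 1e−12.
- Reporting rounds to 2 decimals (3 below 0.01); computation never rounds
  except in explicit paper mode.
- Posterior quantiles and tail probabilities come from scipy's regularized
  incomplete beta; no sampling is used where a closed form exists.
- Monte-Carlo defaults: 10⁴ draws, seed 0, explicit everywhere; tests and
  the acceptance study report agreement in units of Monte-Carlo standard
  errors (3 SE) rather than fixed tolerances.
- Default problem sizes (10⁴ draws/simulations, 50–5000 patients in
  recovery checks) were chosen to keep every Monte-Carlo standard error at
  least ~30× smaller than the effects being measured.

## Known limitations

- Independence of efficacy and toxicity is the only built-in coupling.
- The linkage (Pr(CB|SE), q) is elicited, never estimated; no confirmatory
  trial modelling, time-to-event structure, or value-of-information pricing.
- No consensus mechanism across stakeholders: concordance is reported,
  reconciliation is out of scope by design.
- Utilities are taken at face value on an interval scale; no probability
  weighting or risk attitude beyond what the value table encodes.
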