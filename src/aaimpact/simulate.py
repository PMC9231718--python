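"""Synthetic trials, posterior uncertainty propagation, and selection bias.

Three study tools built on the inference/mapping/decision layers:

* ``simulate_trial`` draws a synthetic single-arm trial (independent binomial
  surrogate-response and severe-toxicity counts) at known true (P, Q).
* ``propagate_posterior_uncertainty`` pushes joint posterior draws of (P, Q)
  through the outcome mapping into stakeholder utilities, yielding a full
  utility distribution per action and the probability each action is optimal.
* ``approval_selection_bias`` quantifies the winner's-curse effect of
  granting approval only to trials that clear a posterior success rule: among
  approved trials the posterior-mean estimate of P is biased upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as _beta_dist

from .decisions import ValueTable, expected_value
from .inference import BetaParams, SuccessCriterion, TrialResult
from .outcomes import (
    SurrogateLinkage,
    ToxicityStructure,
    outcome_distribution_from_params,
)

__all__ = [
    "SimulationSettings",
    "UtilityPropagation",
    "SelectionBiasSummary",
    "simulate_trial",
    "propagate_posterior_uncertainty",
    "approval_selection_bias",
]


@dataclass(frozen=True)
class SimulationSettings:
    """Monte-Carlo settings; the seed is recorded in every output."""

    n_draws: int = 10_000
    seed: int = 0
    tie_rule: str = "split"  # 'split' shares optimal-action credit; 'first' takes first in order

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError(f"n_draws must be >= 1, got {self.n_draws}")
        if self.tie_rule not in ("split", "first"):
            raise ValueError(f"tie_rule must be 'split' or 'first', got {self.tie_rule!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_trial(
    true_p: float, true_q: float, n: int, seed: int | np.random.Generator = 0
) -> TrialResult:
    """Draw one synthetic single-arm trial at known true (P, Q).

    Surrogate responses and severe-toxicity events are independent binomials,
    matching the per-patient independence of the illustrative trial design.
    Deterministic given the seed.
    """
    if not (0 <= true_p <= 1 and 0 <= true_q <= 1):
        raise ValueError(f"true_p and true_q must be in [0,1], got {true_p}, {true_q}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return TrialResult(
        n=n,
        se_responders=int(rng.binomial(n, true_p)),
        tox_events=int(rng.binomial(n, true_q)),
    )


@dataclass(frozen=True)
class UtilityPropagation:
    """Posterior utility distributions per action, with optimality fractions."""

    summary: dict[str, dict[str, float]]  # action -> {mean, sd, mc_se, q2.5, median, q97.5}
    prob_optimal: dict[str, float]
    n_draws: int
    seed: int
    plug_in: dict[str, float] = field(default_factory=dict)  # utility at posterior means


def propagate_posterior_uncertainty(
    post_p: BetaParams,
    post_q: BetaParams,
    linkage: SurrogateLinkage,
    structure: ToxicityStructure | None,
    table: ValueTable,
    settings: SimulationSettings = SimulationSettings(),
    p_inferior: float = 0.0,
) -> UtilityPropagation:
    """Monte-Carlo propagation of posterior (P, Q) uncertainty into utilities.

    Draws (P, Q) independently from their posteriors, maps each draw through
    the outcome pipeline, and scores every action.  Because the collapsed
    outcome probabilities are bilinear in (p(E1), Q) and the draws are
    independent, the mean sampled utility converges to the plug-in utility at
    the posterior means — reported alongside as a cross-check.  Optimality
    fractions split ties equally (default) and always sum to 1.
    """
    rng = settings.rng()
    m = settings.n_draws
    p_draws = rng.beta(post_p.alpha, post_p.beta, size=m)
    q_draws = rng.beta(post_q.alpha, post_q.beta, size=m)

    actions = list(table.actions)
    utilities = np.empty((m, len(actions)))
    opt_credit = np.zeros(len(actions))
    for i in range(m):
        dist = outcome_distribution_from_params(
            p_draws[i], q_draws[i], linkage, structure, p_inferior
        )
        for j, a in enumerate(actions):
            utilities[i, j] = expected_value(table.row(a), dist, action=a)
        row = utilities[i]
        winners = np.flatnonzero(row == row.max())
        if settings.tie_rule == "split":
            opt_credit[winners] += 1.0 / len(winners)
        else:
            opt_credit[winners[0]] += 1.0

    summary: dict[str, dict[str, float]] = {}
    for j, a in enumerate(actions):
        u = utilities[:, j]
        q_lo, med, q_hi = np.quantile(u, [0.025, 0.5, 0.975])
        sd = float(u.std(ddof=1)) if m > 1 else 0.0
        summary[a] = {
            "mean": float(u.mean()),
            "sd": sd,
            "mc_se": sd / np.sqrt(m),
            "q2.5": float(q_lo),
            "median": float(med),
            "q97.5": float(q_hi),
        }

    plug_dist = outcome_distribution_from_params(
        post_p.mean, post_q.mean, linkage, structure, p_inferior
    )
    plug_in = {a: expected_value(table.row(a), plug_dist, action=a) for a in actions}

    return UtilityPropagation(
        summary=summary,
        prob_optimal={a: float(opt_credit[j] / m) for j, a in enumerate(actions)},
        n_draws=m,
        seed=settings.seed,
        plug_in=plug_in,
    )


@dataclass(frozen=True)
class SelectionBiasSummary:
    """Conditional-on-approval optimism in the posterior-mean estimate of P.

    ``conditional_mean`` is None when no simulated trial was approved (the
    conditional expectation is then undefined, not an error).
    """

    approval_probability: float
    conditional_mean: float | None
    unconditional_mean: float
    bias: float | None
    true_p: float
    n: int
    n_sims: int
    seed: int

    def __post_init__(self) -> None:
        if not (0 <= self.approval_probability <= 1):
            raise ValueError("approval probability outside [0,1]")


def approval_selection_bias(
    true_p: float,
    n: int,
    prior: BetaParams,
    criterion: SuccessCriterion,
    settings: SimulationSettings = SimulationSettings(),
) -> SelectionBiasSummary:
    """Simulate approval decisions and measure estimator bias among approvals.

    Each simulated trial draws responders ~ Binomial(n, true_P); the trial is
    'approved' when the posterior exceedance P(P > p0) reaches the required
    assurance gamma.  Because approval is an upper-tail event in the response
    count, the mean posterior-mean among approved trials exceeds the
    unconditional mean whenever the rule actually rejects someone.
    """
    if not (0 <= true_p <= 1):
        raise ValueError(f"true_p must be in [0,1], got {true_p}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = settings.rng()

    # Approval depends on the data only through the response count, so decide
    # once per possible count and look decisions up per simulated trial.
    counts = np.arange(n + 1)
    attained = _beta_dist.sf(criterion.p0, prior.alpha + counts, prior.beta + n - counts)
    approved_by_count = attained >= criterion.gamma
    post_mean_by_count = (prior.alpha + counts) / (prior.alpha + prior.beta + n)

    sims = rng.binomial(n, true_p, size=settings.n_draws)
    estimates = post_mean_by_count[sims]
    approved = approved_by_count[sims]

    n_approved = int(approved.sum())
    approval_probability = n_approved / settings.n_draws
    unconditional_mean = float(estimates.mean())
    if n_approved == 0:
        conditional_mean = None
        bias = None
    else:
        conditional_mean = float(estimates[approved].mean())
        bias = conditional_mean - unconditional_mean

    return SelectionBiasSummary(
        approval_probability=approval_probability,
        conditional_mean=conditional_mean,
        unconditional_mean=unconditional_mean,
        bias=bias,
        true_p=true_p,
        n=n,
        n_sims=settings.n_draws,
        seed=settings.seed,
    )
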