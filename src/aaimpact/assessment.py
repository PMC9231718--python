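"""End-to-end assessment pipeline driven by an :class:`AssessmentConfig`.

Each function here corresponds to one stage a stakeholder walks through:
trial counts -> posteriors -> case-bound outcome probabilities -> expected
utilities and best actions -> scenario sweep -> simulation studies.  The CLI
subcommands are thin wrappers over these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from .config import AssessmentConfig
from .decisions import (
    UtilityTable,
    evaluate_actions,
    scenario_sweep,
    stakeholder_concordance,
)
from .inference import (
    BetaParams,
    credible_interval,
    evaluate_success,
    exceedance_probability,
    posterior_for,
)
from .outcomes import CaseTriple, case_bounds_analysis
from .simulate import (
    SimulationSettings,
    approval_selection_bias,
    propagate_posterior_uncertainty,
)

__all__ = [
    "PosteriorAnalysis",
    "posterior_analysis",
    "case_bounds",
    "decision_analysis",
    "sweep_analysis",
    "simulation_study",
]


@dataclass(frozen=True)
class PosteriorAnalysis:
    """Posterior summaries for P (surrogate response) and Q (severe toxicity)."""

    post_p: BetaParams
    post_q: BetaParams
    summary: pd.DataFrame
    success: bool
    attained: float


def posterior_analysis(config: AssessmentConfig) -> PosteriorAnalysis:
    """Beta-binomial update and posterior summaries for both trial endpoints."""
    trial = config.trial_result()
    level = config.interval_level
    post_p = posterior_for(config.prior_p(), trial.n, trial.se_responders)
    post_q = posterior_for(config.prior_q(), trial.n, trial.tox_events)
    crit = config.success_criterion()
    result = evaluate_success(post_p, crit)

    rows = []
    for label, post, events in (
        ("P (surrogate response)", post_p, trial.se_responders),
        ("Q (severe toxicity)", post_q, trial.tox_events),
    ):
        ci = credible_interval(post, level)
        rows.append(
            {
                "parameter": label,
                "events": events,
                "n": trial.n,
                "alpha": post.alpha,
                "beta": post.beta,
                "mean": post.mean,
                f"ci{level:g}_lower": ci.lower,
                f"ci{level:g}_upper": ci.upper,
                f"P(>{crit.p0:g})": exceedance_probability(post, crit.p0),
            }
        )
    summary = pd.DataFrame(rows).set_index("parameter")
    return PosteriorAnalysis(
        post_p=post_p,
        post_q=post_q,
        summary=summary,
        success=result.success,
        attained=result.attained,
    )


def case_bounds(config: AssessmentConfig) -> CaseTriple:
    """Expected/worst/best case outcome distributions from the trial posteriors."""
    pa = posterior_analysis(config)
    round_inputs = config.reporting.precision if config.reporting.paper_mode else None
    return case_bounds_analysis(
        pa.post_p,
        pa.post_q,
        config.surrogate_linkage(),
        config.toxicity_structure(),
        level=config.interval_level,
        p_inferior=config.p_inferior,
        round_inputs=round_inputs,
    )


@dataclass(frozen=True)
class DecisionAnalysis:
    """Per-case expected utilities, best actions, and stakeholder concordance."""

    utilities: pd.DataFrame  # rows = cases, MultiIndex columns (value set, action)
    best_actions: dict[str, dict[str, tuple[str, ...]]]
    concordant_cases: tuple[str, ...]
    cases: CaseTriple


def decision_analysis(config: AssessmentConfig) -> DecisionAnalysis:
    """Evaluate every stakeholder value table on the estimated case bounds."""
    triple = case_bounds(config)
    tables = config.tables()
    dists = triple.cases()

    columns = pd.MultiIndex.from_tuples(
        [(ts, a) for ts, t in tables.items() for a in t.actions],
        names=["value_set", "action"],
    )
    data, best = [], {}
    for case, dist in dists.items():
        row, best[case] = [], {}
        for ts, t in tables.items():
            res = evaluate_actions(t, dist)
            row.extend(res.values[a] for a in t.actions)
            best[case][ts] = res.best
        data.append(row)
    utilities = pd.DataFrame(data, index=list(dists), columns=columns)

    concordance = stakeholder_concordance(tables, dists)
    return DecisionAnalysis(
        utilities=utilities,
        best_actions=best,
        concordant_cases=concordance.concordant,
        cases=triple,
    )


def sweep_analysis(config: AssessmentConfig) -> UtilityTable:
    """Utility table over estimated cases plus the configured true scenarios."""
    return scenario_sweep(
        config.tables(),
        config.scenario_grid(),
        config.surrogate_linkage(),
        config.toxicity_structure(),
        estimated_cases=case_bounds(config),
        p_inferior=config.p_inferior,
    )


@dataclass(frozen=True)
class SimulationStudy:
    """Posterior uncertainty propagation plus the approval selection-bias study."""

    propagation: pd.DataFrame  # rows = (value set, action) utility summaries
    prob_optimal: dict[str, dict[str, float]]
    selection_bias: pd.DataFrame  # one row per assurance level gamma
    seed: int
    extras: dict[str, Any] = field(default_factory=dict)


def simulation_study(config: AssessmentConfig, seed: int = 0) -> SimulationStudy:
    """Run both simulation studies at the configured settings.

    The selection-bias study simulates trials at ``simulation.true_p``
    (default: the posterior mean of P) under the configured prior and success
    rule, and repeats the study across the configured assurance ladder
    ``simulation.gammas`` plus the configured gamma itself.
    """
    sim = config.simulation
    pa = posterior_analysis(config)
    settings = SimulationSettings(n_draws=sim.n_draws, seed=seed, tie_rule=sim.tie_rule)
    linkage = config.surrogate_linkage()
    structure = config.toxicity_structure()

    prop_rows, prob_optimal = [], {}
    for ts, table in config.tables().items():
        prop = propagate_posterior_uncertainty(
            pa.post_p, pa.post_q, linkage, structure, table, settings,
            p_inferior=config.p_inferior,
        )
        prob_optimal[ts] = prop.prob_optimal
        for action, stats in prop.summary.items():
            prop_rows.append(
                {
                    "value_set": ts,
                    "action": action,
                    **stats,
                    "plug_in": prop.plug_in[action],
                    "prob_optimal": prop.prob_optimal[action],
                }
            )
    propagation = pd.DataFrame(prop_rows).set_index(["value_set", "action"])

    true_p = sim.true_p if sim.true_p is not None else pa.post_p.mean
    crit = config.success_criterion()
    gammas = sorted(set(list(sim.gammas) + [crit.gamma]))
    bias_rows = []
    for i, g in enumerate(gammas):
        summary = approval_selection_bias(
            true_p,
            config.trial.n,
            config.prior_p(),
            type(crit)(crit.p0, g),
            SimulationSettings(n_draws=sim.n_draws, seed=seed + i, tie_rule=sim.tie_rule),
        )
        bias_rows.append(
            {
                "gamma": g,
                "approval_probability": summary.approval_probability,
                "conditional_mean": summary.conditional_mean,
                "unconditional_mean": summary.unconditional_mean,
                "bias": summary.bias,
            }
        )
    selection_bias = pd.DataFrame(bias_rows).set_index("gamma")

    return SimulationStudy(
        propagation=propagation,
        prob_optimal=prob_optimal,
        selection_bias=selection_bias,
        seed=seed,
        extras={"true_p": true_p, "n": config.trial.n, "n_draws": sim.n_draws},
    )
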