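"""Assessment configuration: schema, validation, loading and saving.

A single structured text file (JSON, or YAML as a convenience superset)
describes one assessment: the trial counts, the beta priors on P and Q, the
success rule, the surrogate linkage, the toxicity structure, the stakeholder
value tables, the true-scenario grid, and reporting options.  Validation
errors name the offending field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .decisions import ActionSet, Scenario, ScenarioGrid, ValueTable, example_value_tables
from .inference import BetaParams, SuccessCriterion, TrialResult, elicit_beta_prior
from .outcomes import OUTCOME_LABELS, SurrogateLinkage, ToxicityStructure

__all__ = [
    "AssessmentConfig",
    "ConfigError",
    "load_assessment_config",
    "save_assessment_config",
    "example_config",
]


class ConfigError(ValueError):
    """A configuration file failed to parse or validate."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TrialSpec(_Model):
    n: int = Field(ge=1)
    se_responders: int = Field(ge=0)
    tox_events: int = Field(ge=0)

    @model_validator(mode="after")
    def _counts_within_n(self) -> "TrialSpec":
        if self.se_responders > self.n:
            raise ValueError(f"se_responders={self.se_responders} exceeds n={self.n}")
        if self.tox_events > self.n:
            raise ValueError(f"tox_events={self.tox_events} exceeds n={self.n}")
        return self

    def to_result(self) -> TrialResult:
        return TrialResult(self.n, self.se_responders, self.tox_events)


class PriorSpec(_Model):
    """Either (mean, strength) elicitation or direct (alpha, beta) entry."""

    mean: Optional[float] = Field(default=None, gt=0, lt=1)
    strength: Optional[float] = Field(default=None, gt=0)
    alpha: Optional[float] = Field(default=None, gt=0)
    beta: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _one_parameterization(self) -> "PriorSpec":
        by_mean = self.mean is not None or self.strength is not None
        by_ab = self.alpha is not None or self.beta is not None
        if by_mean and by_ab:
            raise ValueError("give either (mean, strength) or (alpha, beta), not both")
        if by_mean and (self.mean is None or self.strength is None):
            raise ValueError("mean and strength must be given together")
        if by_ab and (self.alpha is None or self.beta is None):
            raise ValueError("alpha and beta must be given together")
        if not (by_mean or by_ab):
            raise ValueError("prior needs (mean, strength) or (alpha, beta)")
        return self

    def to_params(self) -> BetaParams:
        if self.alpha is not None:
            return BetaParams(self.alpha, self.beta)
        return elicit_beta_prior(self.mean, self.strength)


class PriorsSpec(_Model):
    p: PriorSpec
    q: PriorSpec


class SuccessSpec(_Model):
    p0: float = Field(ge=0, lt=1)
    gamma: float = Field(gt=0, le=1)

    def to_criterion(self) -> SuccessCriterion:
        return SuccessCriterion(self.p0, self.gamma)


class LinkageSpec(_Model):
    p_cb_given_se: float = Field(ge=0, le=1)
    q: float = Field(ge=0, le=1)

    def to_linkage(self) -> SurrogateLinkage:
        return SurrogateLinkage(self.p_cb_given_se, self.q)


class ToxicitySpec(_Model):
    p_t1: float = Field(default=0.0, ge=0, le=1)
    split: tuple[float, float] = (0.5, 0.5)

    def to_structure(self) -> ToxicityStructure:
        return ToxicityStructure(self.p_t1, tuple(self.split))


class ScenarioSpec(_Model):
    name: str
    p: float = Field(ge=0, le=1)
    q: float = Field(ge=0, le=1)

    def to_scenario(self) -> Scenario:
        return Scenario(self.name, self.p, self.q)


class SimulationSpec(_Model):
    n_draws: int = Field(default=10_000, ge=1)
    true_p: Optional[float] = Field(default=None, ge=0, le=1)
    true_q: Optional[float] = Field(default=None, ge=0, le=1)
    gammas: list[float] = Field(default_factory=lambda: [0.5, 0.7, 0.9])
    tie_rule: str = "split"


class ReportingSpec(_Model):
    precision: int = Field(default=2, ge=0, le=10)
    paper_mode: bool = False  # round posterior (P, Q) summaries before mapping


class AssessmentConfig(_Model):
    """Validated description of one accelerated-approval impact assessment."""

    trial: TrialSpec
    priors: PriorsSpec
    success: SuccessSpec
    linkage: LinkageSpec
    toxicity: ToxicitySpec = ToxicitySpec()
    interval_level: float = Field(default=0.95, gt=0, lt=1)
    p_inferior: float = Field(default=0.0, ge=0, le=1)
    value_tables: dict[str, dict[str, list[Optional[float]]]] = Field(default_factory=dict)
    actions: list[str] = Field(default_factory=lambda: list(("refuse", "accept", "defer")))
    categories: list[str] = Field(default_factory=lambda: list(OUTCOME_LABELS))
    scenarios: list[ScenarioSpec] = Field(default_factory=list)
    simulation: SimulationSpec = SimulationSpec()
    reporting: ReportingSpec = ReportingSpec()

    @model_validator(mode="after")
    def _tables_consistent(self) -> "AssessmentConfig":
        if len(self.actions) < 2:
            raise ValueError("actions: need at least 2 action labels")
        if len(set(self.actions)) != len(self.actions):
            raise ValueError("actions: labels must be unique")
        if len(self.categories) != 6:
            raise ValueError("categories: exactly 6 outcome labels required")
        for name, rows in self.value_tables.items():
            if set(rows) != set(self.actions):
                raise ValueError(
                    f"value_tables[{name!r}]: rows {sorted(rows)} do not match actions {self.actions}"
                )
            for action, row in rows.items():
                if len(row) != 6:
                    raise ValueError(
                        f"value_tables[{name!r}][{action!r}]: need 6 values, got {len(row)}"
                    )
        return self

    # -- domain-object accessors -------------------------------------------

    def trial_result(self) -> TrialResult:
        return self.trial.to_result()

    def prior_p(self) -> BetaParams:
        return self.priors.p.to_params()

    def prior_q(self) -> BetaParams:
        return self.priors.q.to_params()

    def success_criterion(self) -> SuccessCriterion:
        return self.success.to_criterion()

    def surrogate_linkage(self) -> SurrogateLinkage:
        return self.linkage.to_linkage()

    def toxicity_structure(self) -> ToxicityStructure:
        return self.toxicity.to_structure()

    def scenario_grid(self) -> ScenarioGrid:
        return ScenarioGrid(tuple(s.to_scenario() for s in self.scenarios))

    def tables(self) -> dict[str, ValueTable]:
        if not self.value_tables:
            return example_value_tables()
        actions = ActionSet(tuple(self.actions))
        return {
            name: ValueTable(
                {a: list(rows[a]) for a in self.actions},
                actions=actions,
                categories=tuple(self.categories),
                name=name,
            )
            for name, rows in self.value_tables.items()
        }


def load_assessment_config(path: str | Path) -> AssessmentConfig:
    """Load and fully validate a JSON/YAML assessment configuration.

    Raises :class:`ConfigError` naming the file and the offending field on
    parse failure or any invariant violation.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"{path}: no such file")
    text = path.read_text()
    try:
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: parse failure: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return AssessmentConfig.model_validate(raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"field {loc}: {err['msg']}")
        raise ConfigError(f"{path}: invalid configuration: " + "; ".join(lines)) from exc


def save_assessment_config(config: AssessmentConfig, path: str | Path) -> Path:
    """Write a validated config as JSON with all defaults resolved."""
    path = Path(path)
    path.write_text(json.dumps(config.model_dump(mode="json"), indent=2, sort_keys=True) + "\n")
    return path


def example_config() -> AssessmentConfig:
    """The bundled worked example: 15/50 surrogate responders, 0/50 toxicity.

    Priors Beta(1,9) on P and Beta(2,8) on Q (means 0.10 and 0.20, strength
    10), success rule P(P > 0.20) >= 0.85, linkage P(CB|SE)=0.7 with q=0.05,
    add-on toxicity structure with an equal T2/T3 split, the two bundled
    value sets, and six true scenarios crossing P in {0.4, 0.3, 0.1} with
    Q in {0.03, 0.1}.
    """
    scenarios = [
        ScenarioSpec(name=f"True Scenario {i + 1}", p=p, q=q)
        for i, (p, q) in enumerate(
            [(0.4, 0.03), (0.4, 0.1), (0.3, 0.03), (0.3, 0.1), (0.1, 0.03), (0.1, 0.1)]
        )
    ]
    vt = {
        name: {a: list(t.row(a)) for a in t.actions}
        for name, t in example_value_tables().items()
    }
    return AssessmentConfig(
        trial=TrialSpec(n=50, se_responders=15, tox_events=0),
        priors=PriorsSpec(
            p=PriorSpec(mean=0.10, strength=10), q=PriorSpec(mean=0.20, strength=10)
        ),
        success=SuccessSpec(p0=0.20, gamma=0.85),
        linkage=LinkageSpec(p_cb_given_se=0.7, q=0.05),
        scenarios=scenarios,
        value_tables=vt,
    )
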