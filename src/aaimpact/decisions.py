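"""Stakeholder value tables, expected utilities, optimal actions, and sweeps.

Each stakeholder scores every (action, therapeutic outcome) pair with a value
v_ij.  Given outcome probabilities w1..w6 (estimated) or W1..W6 (true), the
expected value of action a_i is the inner product sum_j w_j * v_ij; the best
action set collects every maximizer (A* under estimated probabilities, A_opt
under true ones).  Structurally impossible outcomes may carry an *unset*
value cell, which is legal only while the paired probability is exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .outcomes import (
    OUTCOME_LABELS,
    CaseTriple,
    SurrogateLinkage,
    ToxicityStructure,
    TherapeuticOutcomeDistribution,
    outcome_distribution_from_params,
)

__all__ = [
    "DEFAULT_ACTIONS",
    "UNSET",
    "ActionSet",
    "ValueTable",
    "DecisionResult",
    "Scenario",
    "ScenarioGrid",
    "ConcordanceReport",
    "expected_value",
    "evaluate_actions",
    "regret_profile",
    "scenario_sweep",
    "stakeholder_concordance",
    "value_set_1",
    "value_set_2",
    "example_value_tables",
]

DEFAULT_ACTIONS = ("refuse", "accept", "defer")

#: Sentinel for a value cell left unset because the outcome cannot occur.
UNSET = None


@dataclass(frozen=True)
class ActionSet:
    """Ordered, unique action labels a stakeholder chooses among."""

    labels: tuple[str, ...] = DEFAULT_ACTIONS

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("need at least 2 actions")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"action labels must be unique, got {self.labels}")

    def __iter__(self):
        return iter(self.labels)

    def __len__(self) -> int:
        return len(self.labels)


class ValueTable:
    """A stakeholder's value matrix over actions x outcome categories.

    ``values[action]`` is a sequence of six entries, each a finite number or
    ``None`` (unset, for outcomes with structural probability zero).  The
    category labels default to the six collapsed therapeutic outcomes.
    """

    def __init__(
        self,
        values: dict[str, list[float | None]],
        actions: ActionSet | None = None,
        categories: tuple[str, ...] = OUTCOME_LABELS,
        name: str = "",
    ) -> None:
        self.actions = actions or ActionSet(tuple(values.keys()))
        self.categories = tuple(categories)
        self.name = name
        if set(values.keys()) != set(self.actions.labels):
            raise ValueError(
                f"value rows {sorted(values)} do not match actions {self.actions.labels}"
            )
        self._rows: dict[str, tuple[float | None, ...]] = {}
        for action in self.actions:
            row = tuple(values[action])
            if len(row) != len(self.categories):
                raise ValueError(
                    f"row for {action!r} has {len(row)} entries, need {len(self.categories)}"
                )
            for v in row:
                if v is not None and not np.isfinite(v):
                    raise ValueError(f"value for {action!r} must be finite or unset, got {v}")
            self._rows[action] = tuple(None if v is None else float(v) for v in row)

    def row(self, action: str) -> tuple[float | None, ...]:
        return self._rows[action]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[np.nan if v is None else v for v in self._rows[a]] for a in self.actions],
            index=list(self.actions),
            columns=list(self.categories),
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ValueTable) and self._rows == other._rows

    def __repr__(self) -> str:
        return f"ValueTable(name={self.name!r}, actions={self.actions.labels})"


@dataclass(frozen=True)
class DecisionResult:
    """Expected value per action, with the set of all maximizers."""

    values: dict[str, float]
    best: tuple[str, ...]
    tie: bool
    source: str  # 'estimated' -> A*, 'true' -> A_opt

    @property
    def best_value(self) -> float:
        return self.values[self.best[0]]


@dataclass(frozen=True)
class Scenario:
    """A hypothesized true state of nature (P, Q), optionally overriding the linkage."""

    name: str
    p: float
    q: float
    linkage: SurrogateLinkage | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 and 0 <= self.q <= 1):
            raise ValueError(f"scenario {self.name!r}: P and Q must be in [0,1]")


@dataclass(frozen=True)
class ScenarioGrid:
    scenarios: tuple[Scenario, ...]

    def __iter__(self):
        return iter(self.scenarios)

    def __len__(self) -> int:
        return len(self.scenarios)


@dataclass(frozen=True)
class ConcordanceReport:
    """Best actions per stakeholder with pairwise and overall agreement.

    Two stakeholders *agree* on a distribution when their best-action sets
    share at least one action; full concordance requires a common action in
    every stakeholder's best set.
    """

    best_actions: dict[str, dict[str, tuple[str, ...]]]  # dist -> stakeholder -> best set
    agreement: dict[str, pd.DataFrame]  # dist -> boolean stakeholder x stakeholder
    concordant: tuple[str, ...]  # dist names on which all stakeholders agree


def expected_value(
    values_row, dist: TherapeuticOutcomeDistribution, action: str = "?"
) -> float:
    """Inner product sum_j w_j * v_ij of a value row with outcome probabilities.

    Serves both V_est (estimated w's) and V_True (true W's).  An unset cell
    contributes nothing when its probability is exactly 0 and is an error
    otherwise: a stakeholder cannot leave an outcome unvalued if it can occur.
    """
    total = 0.0
    for j, (v, w) in enumerate(zip(values_row, dist.w, strict=True)):
        if v is None:
            if w != 0.0:
                raise ValueError(
                    f"value cell for action {action!r}, category {OUTCOME_LABELS[j]!r} is "
                    f"unset but the outcome has probability {w}"
                )
            continue
        total += w * v
    return total


def evaluate_actions(
    table: ValueTable, dist: TherapeuticOutcomeDistribution, tie_tol: float = 0.0
) -> DecisionResult:
    """Expected value of every action; best set = all maximizers.

    Comparisons are exact on the full-precision expected values; ``tie_tol``
    optionally widens the best set to actions within that margin of the
    maximum (off by default).
    """
    values = {a: expected_value(table.row(a), dist, action=a) for a in table.actions}
    vmax = max(values.values())
    best = tuple(a for a in table.actions if values[a] >= vmax - tie_tol)
    return DecisionResult(values=values, best=best, tie=len(best) > 1, source=dist.source)


def regret_profile(
    table: ValueTable, true_dist: TherapeuticOutcomeDistribution
) -> dict[str, float]:
    """Per-action regret V_True(A_opt) - V_True(a_i) under the true probabilities."""
    result = evaluate_actions(table, true_dist)
    return {a: result.best_value - v for a, v in result.values.items()}


@dataclass(frozen=True)
class UtilityTable:
    """Sweep output: one row per case/scenario, one column per (value set, action)."""

    utilities: pd.DataFrame  # MultiIndex columns (value set, action)
    best_actions: dict[str, dict[str, tuple[str, ...]]]  # row -> value set -> best set
    distributions: dict[str, TherapeuticOutcomeDistribution] = field(repr=False, default=None)


def scenario_sweep(
    tables: dict[str, ValueTable],
    grid: ScenarioGrid,
    linkage: SurrogateLinkage,
    structure: ToxicityStructure | None = None,
    estimated_cases: CaseTriple | None = None,
    p_inferior: float = 0.0,
) -> UtilityTable:
    """Expected utilities across estimated cases and true scenarios.

    Rows are the estimated expected/worst/best cases (if supplied) followed
    by each true scenario's (P, Q) mapped through the outcome pipeline;
    columns are every (value set, action) pair; each cell is the expected
    value of that action under that row's outcome distribution.
    """
    rows: dict[str, TherapeuticOutcomeDistribution] = {}
    if estimated_cases is not None:
        rows.update(estimated_cases.cases())
    for sc in grid:
        rows[sc.name] = outcome_distribution_from_params(
            sc.p, sc.q, sc.linkage or linkage, structure, p_inferior,
            source="true", context=sc.name,
        )

    columns = pd.MultiIndex.from_tuples(
        [(ts, a) for ts, t in tables.items() for a in t.actions],
        names=["value_set", "action"],
    )
    data: list[list[float]] = []
    best: dict[str, dict[str, tuple[str, ...]]] = {}
    for row_name, dist in rows.items():
        row_vals: list[float] = []
        best[row_name] = {}
        for ts, t in tables.items():
            res = evaluate_actions(t, dist)
            row_vals.extend(res.values[a] for a in t.actions)
            best[row_name][ts] = res.best
        data.append(row_vals)
    utilities = pd.DataFrame(data, index=list(rows), columns=columns)
    return UtilityTable(utilities=utilities, best_actions=best, distributions=rows)


def stakeholder_concordance(
    tables: dict[str, ValueTable],
    dists: TherapeuticOutcomeDistribution | dict[str, TherapeuticOutcomeDistribution],
) -> ConcordanceReport:
    """Compare best actions across stakeholders on one or more distributions."""
    if not tables:
        raise ValueError("need at least one stakeholder value table")
    action_sets = {t.actions.labels for t in tables.values()}
    if len(action_sets) > 1:
        raise ValueError(f"stakeholder tables disagree on the action set: {action_sets}")
    if isinstance(dists, TherapeuticOutcomeDistribution):
        dists = {"case": dists}

    names = list(tables)
    best_actions: dict[str, dict[str, tuple[str, ...]]] = {}
    agreement: dict[str, pd.DataFrame] = {}
    concordant: list[str] = []
    for dname, dist in dists.items():
        best = {s: evaluate_actions(tables[s], dist).best for s in names}
        best_actions[dname] = best
        mat = pd.DataFrame(
            [[bool(set(best[a]) & set(best[b])) for b in names] for a in names],
            index=names, columns=names,
        )
        agreement[dname] = mat
        if set.intersection(*(set(b) for b in best.values())):
            concordant.append(dname)
    return ConcordanceReport(
        best_actions=best_actions, agreement=agreement, concordant=tuple(concordant)
    )


def value_set_1(name: str = "Value Set 1") -> ValueTable:
    """Illustrative patient values: modest reward for benefit, ruin-averse.

    Refuse and defer share a row; missing a truly better treatment costs -100,
    accepting one pays +100, and accepting anything else costs -50.
    """
    refuse = [UNSET, -100, -100, UNSET, 0, 50]
    return ValueTable(
        {"refuse": refuse, "accept": [UNSET, 100, 100, UNSET, -50, -50], "defer": list(refuse)},
        actions=ActionSet(DEFAULT_ACTIONS),
        name=name,
    )


def value_set_2(name: str = "Value Set 2") -> ValueTable:
    """Illustrative values that weight clinical benefit ten times more heavily."""
    refuse = [UNSET, -1000, -1000, UNSET, 0, 100]
    return ValueTable(
        {"refuse": refuse, "accept": [UNSET, 1000, 1000, UNSET, -50, -500], "defer": list(refuse)},
        actions=ActionSet(DEFAULT_ACTIONS),
        name=name,
    )


def example_value_tables() -> dict[str, ValueTable]:
    """The two bundled stakeholder value sets, keyed by name."""
    return {"Value Set 1": value_set_1(), "Value Set 2": value_set_2()}
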