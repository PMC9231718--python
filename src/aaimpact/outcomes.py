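"""Mapping surrogate-level parameters (P, Q) to therapeutic-outcome probabilities.

The chain runs:

    P = Prob(positive surrogate effect)
      --linkage-->  p(E1) = Prob(clinical benefit)
      -->  efficacy categories E1 (materially better), E2 (similar), E3 (inferior)

    Q = Prob(severe toxicity)
      --structure-->  toxicity categories T1 (less), T2 (similar),
                      T3 (worse but manageable), T4 (intolerable)

    (E, T) independent  -->  3x4 joint grid  -->  six collapsed categories:
      x1=(E1,T1)  x2=(E1,T2)  x3=(E1,T3)  x4=(E2,T1)  x5=(E2,T2)
      x6 = everything unacceptable: (E1,T4), (E2,T3), (E2,T4) and all of E3.

Case-bound analysis pushes the posterior mean (expected case), the pessimistic
corner (lower P bound, upper Q bound; worst case) and the optimistic corner
(upper P, lower Q; best case) through this chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .formatting import round_report
from .inference import BetaParams, credible_interval

__all__ = [
    "OUTCOME_LABELS",
    "SurrogateLinkage",
    "EfficacyDistribution",
    "ToxicityDistribution",
    "ToxicityStructure",
    "JointOutcomeGrid",
    "TherapeuticOutcomeDistribution",
    "CaseTriple",
    "clinical_benefit_probability",
    "efficacy_distribution",
    "toxicity_distribution",
    "joint_outcome_distribution",
    "collapse_outcomes",
    "outcome_distribution_from_params",
    "case_bounds_analysis",
]

#: Collapsed therapeutic-outcome categories, in fixed order.
OUTCOME_LABELS = (
    "x1 (E1,T1)",
    "x2 (E1,T2)",
    "x3 (E1,T3)",
    "x4 (E2,T1)",
    "x5 (E2,T2)",
    "x6 (other)",
)

_NORM_TOL = 1e-12

#: Advisory upper bound for q = P(CB | no SE): benefit without a surrogate
#: signal should be rare when the surrogate has experimental validity.
Q_ADVISORY_MAX = 0.15


def _check_prob(x: float, name: str) -> float:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must be in [0,1], got {x}")
    return float(x)


@dataclass(frozen=True)
class SurrogateLinkage:
    """Elicited link between the surrogate endpoint and clinical benefit.

    ``p_cb_given_se`` is the probability of clinical benefit for a surrogate
    responder; ``p_cb_given_nose`` (the 'q' of the linkage equation) for a
    non-responder.  An inverted linkage (q larger than P(CB|SE)) is legal but
    warned about, as is q above the advisory range.
    """

    p_cb_given_se: float
    p_cb_given_nose: float

    def __post_init__(self) -> None:
        _check_prob(self.p_cb_given_se, "p_cb_given_se")
        _check_prob(self.p_cb_given_nose, "p_cb_given_nose")
        if self.p_cb_given_nose > self.p_cb_given_se:
            warnings.warn(
                "linkage is inverted: P(CB|no SE) > P(CB|SE); a positive surrogate "
                "finding then argues against clinical benefit",
                stacklevel=2,
            )
        elif self.p_cb_given_nose > Q_ADVISORY_MAX:
            warnings.warn(
                f"q = P(CB|no SE) = {self.p_cb_given_nose} exceeds the advisory range "
                f"[0, {Q_ADVISORY_MAX}] for a validated surrogate",
                stacklevel=2,
            )


def _check_simplex(values: tuple[float, ...], what: str) -> None:
    for v in values:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{what} probabilities must be in [0,1], got {v}")
    total = sum(values)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{what} probabilities must sum to 1, got {total!r}")


@dataclass(frozen=True)
class EfficacyDistribution:
    """Probabilities over E1 (materially better), E2 (similar), E3 (inferior)."""

    p_e1: float
    p_e2: float
    p_e3: float

    def __post_init__(self) -> None:
        _check_simplex((self.p_e1, self.p_e2, self.p_e3), "efficacy")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_e1, self.p_e2, self.p_e3])


@dataclass(frozen=True)
class ToxicityDistribution:
    """Probabilities over T1 (less), T2 (similar), T3 (manageable worse), T4 (intolerable)."""

    p_t1: float
    p_t2: float
    p_t3: float
    p_t4: float

    def __post_init__(self) -> None:
        _check_simplex((self.p_t1, self.p_t2, self.p_t3, self.p_t4), "toxicity")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_t1, self.p_t2, self.p_t3, self.p_t4])


@dataclass(frozen=True)
class ToxicityStructure:
    """Structural constraints translating Q into the four toxicity categories.

    For an add-on therapy the new regimen cannot be *less* toxic than the
    standard it is added to, so ``p_t1_fixed`` defaults to 0.  The mass not
    assigned to T1 or T4 is split between T2 and T3 by ``split`` (default
    equal halves).
    """

    p_t1_fixed: float = 0.0
    split: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        _check_prob(self.p_t1_fixed, "p_t1_fixed")
        w2, w3 = self.split
        if w2 < 0 or w3 < 0:
            raise ValueError(f"split weights must be non-negative, got {self.split}")
        if abs(w2 + w3 - 1.0) > 1e-9:
            raise ValueError(f"split weights must sum to 1, got {self.split}")


@dataclass(frozen=True)
class JointOutcomeGrid:
    """3x4 joint probabilities over (efficacy category, toxicity category)."""

    cells: np.ndarray

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=float)
        if cells.shape != (3, 4):
            raise ValueError(f"joint grid must be 3x4, got shape {cells.shape}")
        if (cells < -_NORM_TOL).any():
            raise ValueError("joint grid cells must be non-negative")
        if abs(cells.sum() - 1.0) > 1e-9:
            raise ValueError(f"joint grid must sum to 1, got {cells.sum()!r}")
        object.__setattr__(self, "cells", cells)

    def efficacy_marginal(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    def toxicity_marginal(self) -> np.ndarray:
        return self.cells.sum(axis=0)


@dataclass(frozen=True)
class TherapeuticOutcomeDistribution:
    """Probabilities over the six collapsed therapeutic-outcome categories.

    ``source`` tags whether the vector holds true probabilities (W1..W6,
    from a hypothesized state of nature) or estimated ones (w1..w6, from
    trial posteriors).  ``context`` is an opaque label for the patient
    profile the prediction refers to; it is carried through, never used.
    """

    w: tuple[float, float, float, float, float, float]
    source: str = "estimated"
    context: str | None = None

    def __post_init__(self) -> None:
        if len(self.w) != 6:
            raise ValueError(f"need 6 category probabilities, got {len(self.w)}")
        _check_simplex(tuple(self.w), "therapeutic outcome")
        object.__setattr__(self, "w", tuple(float(v) for v in self.w))
        if self.source not in ("estimated", "true"):
            raise ValueError(f"source must be 'estimated' or 'true', got {self.source!r}")

    def as_array(self) -> np.ndarray:
        return np.array(self.w)


@dataclass(frozen=True)
class CaseTriple:
    """Expected / worst / best case outcome distributions with generating (P, Q)."""

    expected: TherapeuticOutcomeDistribution
    worst: TherapeuticOutcomeDistribution
    best: TherapeuticOutcomeDistribution
    pq_expected: tuple[float, float] = field(default=(float("nan"), float("nan")))
    pq_worst: tuple[float, float] = field(default=(float("nan"), float("nan")))
    pq_best: tuple[float, float] = field(default=(float("nan"), float("nan")))
    #: marginal clinical-benefit probability p(E1) per case, before the
    #: toxicity coupling (the w1+w2+w3 sum is p(E1)*(1-p(T4)) under independence)
    pe1: dict = field(default_factory=dict)
    level: float = 0.95

    def cases(self) -> dict[str, TherapeuticOutcomeDistribution]:
        return {"Expected": self.expected, "Worst Case": self.worst, "Best Case": self.best}


def clinical_benefit_probability(p_se: float, linkage: SurrogateLinkage) -> float:
    """Total probability of clinical benefit from the surrogate linkage.

    p(E1) = P(SE) * P(CB|SE) + (1 - P(SE)) * P(CB|no SE); affine in P(SE),
    running from q at P(SE)=0 to P(CB|SE) at P(SE)=1.
    """
    _check_prob(p_se, "p_se")
    return p_se * linkage.p_cb_given_se + (1.0 - p_se) * linkage.p_cb_given_nose


def efficacy_distribution(p_cb: float, p_inferior: float = 0.0) -> EfficacyDistribution:
    """Spread clinical-benefit probability over the three efficacy categories.

    ``p_inferior`` defaults to 0: against no effective comparator, inferior
    efficacy is not a live outcome.  It is a first-class input for
    indications with active comparators.
    """
    _check_prob(p_cb, "p_cb")
    _check_prob(p_inferior, "p_inferior")
    if p_cb + p_inferior > 1.0 + _NORM_TOL:
        raise ValueError(f"p_cb + p_inferior = {p_cb + p_inferior} exceeds 1")
    return EfficacyDistribution(p_cb, 1.0 - p_cb - p_inferior, p_inferior)


def toxicity_distribution(
    p_intolerable: float, structure: ToxicityStructure | None = None
) -> ToxicityDistribution:
    """Spread intolerable-toxicity probability over the four toxicity categories."""
    structure = structure or ToxicityStructure()
    _check_prob(p_intolerable, "p_intolerable")
    if structure.p_t1_fixed + p_intolerable > 1.0 + _NORM_TOL:
        raise ValueError(
            f"p_t1_fixed + p_intolerable = {structure.p_t1_fixed + p_intolerable} exceeds 1"
        )
    rest = 1.0 - structure.p_t1_fixed - p_intolerable
    w2, w3 = structure.split
    return ToxicityDistribution(structure.p_t1_fixed, rest * w2, rest * w3, p_intolerable)


def joint_outcome_distribution(
    eff: EfficacyDistribution, tox: ToxicityDistribution
) -> JointOutcomeGrid:
    """Joint (E, T) grid under independence of efficacy and toxicity.

    Independence is the default coupling; a fully specified 12-cell grid can
    be constructed directly as a :class:`JointOutcomeGrid` when a dependence
    model is available.
    """
    return JointOutcomeGrid(np.outer(eff.as_array(), tox.as_array()))


def collapse_outcomes(
    grid: JointOutcomeGrid, source: str = "estimated", context: str | None = None
) -> TherapeuticOutcomeDistribution:
    """Collapse the 12 (E, T) cells into the six therapeutic-outcome categories.

    Materially less efficacy (all of E3), intolerable toxicity (T4), or worse
    toxicity without materially better efficacy ((E2,T3)) are all unacceptable
    and pooled into x6.  Total mass is preserved exactly: x6 is computed as
    the sum of its constituent cells, so the six categories sum to the same
    float as the twelve cells.
    """
    c = grid.cells
    x6 = c[0, 3] + c[1, 2] + c[1, 3] + c[2, 0] + c[2, 1] + c[2, 2] + c[2, 3]
    return TherapeuticOutcomeDistribution(
        (c[0, 0], c[0, 1], c[0, 2], c[1, 0], c[1, 1], x6), source=source, context=context
    )


def outcome_distribution_from_params(
    p_se: float,
    q_tox: float,
    linkage: SurrogateLinkage,
    structure: ToxicityStructure | None = None,
    p_inferior: float = 0.0,
    source: str = "estimated",
    context: str | None = None,
) -> TherapeuticOutcomeDistribution:
    """Full pipeline (P, Q) -> collapsed six-category distribution."""
    eff = efficacy_distribution(clinical_benefit_probability(p_se, linkage), p_inferior)
    tox = toxicity_distribution(q_tox, structure)
    return collapse_outcomes(joint_outcome_distribution(eff, tox), source=source, context=context)


def case_bounds_analysis(
    post_p: BetaParams,
    post_q: BetaParams,
    linkage: SurrogateLinkage,
    structure: ToxicityStructure | None = None,
    level: float = 0.95,
    p_inferior: float = 0.0,
    round_inputs: int | None = None,
) -> CaseTriple:
    """Expected / worst / best case analysis from the two trial posteriors.

    The expected case maps the posterior means of (P, Q); the worst case the
    lower credible bound of P with the upper bound of Q; the best case the
    upper bound of P with the lower bound of Q.  ``round_inputs`` optionally
    rounds the (P, Q) summaries to that many decimals before mapping, which
    mirrors hand calculations done from printed 2-dp posterior summaries;
    by default everything is carried at full precision.
    """
    ci_p = credible_interval(post_p, level)
    ci_q = credible_interval(post_q, level)
    pq = {
        "expected": (post_p.mean, post_q.mean),
        "worst": (ci_p.lower, ci_q.upper),
        "best": (ci_p.upper, ci_q.lower),
    }
    if round_inputs is not None:
        pq = {
            k: (round_report(p, round_inputs), round_report(q, round_inputs))
            for k, (p, q) in pq.items()
        }

    dists = {
        k: outcome_distribution_from_params(
            p, q, linkage, structure, p_inferior, source="estimated", context=k
        )
        for k, (p, q) in pq.items()
    }
    case_names = {"expected": "Expected", "worst": "Worst Case", "best": "Best Case"}
    pe1 = {
        case_names[k]: clinical_benefit_probability(p, linkage) for k, (p, _) in pq.items()
    }
    return CaseTriple(
        expected=dists["expected"],
        worst=dists["worst"],
        best=dists["best"],
        pq_expected=pq["expected"],
        pq_worst=pq["worst"],
        pq_best=pq["best"],
        pe1=pe1,
        level=level,
    )
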