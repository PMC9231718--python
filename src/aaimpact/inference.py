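"""Conjugate beta-binomial inference for single-arm accelerated-approval trials.

An AA trial in this framework reports two binomial counts out of ``n``
patients: the number showing a positive surrogate-endpoint (SE) effect and
the number experiencing a severe toxicity event.  With beta priors on the
surrogate-response probability P and the severe-toxicity probability Q, the
posteriors are again beta distributions, and every summary a stakeholder
needs — posterior mean, equal-tailed credible interval, exceedance
probability against a go/no-go threshold — has a closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import beta as _beta_dist
from scipy.optimize import brentq

__all__ = [
    "BetaParams",
    "TrialResult",
    "ProbabilityInterval",
    "SuccessCriterion",
    "SuccessResult",
    "elicit_beta_prior",
    "update_beta",
    "posterior_mean",
    "credible_interval",
    "exceedance_probability",
    "evaluate_success",
]


@dataclass(frozen=True)
class BetaParams:
    """Parameters of a Beta(alpha, beta) prior or posterior for a probability.

    ``alpha`` counts pseudo-successes, ``beta`` pseudo-failures; both must be
    strictly positive, which also forces the mean into the open unit interval.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"beta parameters must be positive, got alpha={self.alpha}, beta={self.beta}"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def strength(self) -> float:
        """Total pseudo-count alpha + beta (prior 'sample size')."""
        return self.alpha + self.beta

    def dist(self):
        """The scipy frozen distribution for this parameterization."""
        return _beta_dist(self.alpha, self.beta)


@dataclass(frozen=True)
class TrialResult:
    """Counts from a single-arm trial: surrogate responders and toxicity events."""

    n: int
    se_responders: int
    tox_events: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        for name in ("se_responders", "tox_events"):
            k = getattr(self, name)
            if not (0 <= k <= self.n):
                raise ValueError(f"{name}={k} outside [0, n={self.n}]")


@dataclass(frozen=True)
class ProbabilityInterval:
    """A credible interval for a probability parameter."""

    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not (0 <= self.lower <= self.upper <= 1):
            raise ValueError(
                f"require 0 <= lower <= upper <= 1, got ({self.lower}, {self.upper})"
            )
        if not (0 < self.level < 1):
            raise ValueError(f"level must be in (0,1), got {self.level}")

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class SuccessCriterion:
    """Posterior go/no-go rule: declare success when P(param > p0) >= gamma.

    ``gamma`` (the required assurance) has no default: how 'sure' one must be
    that the response probability clears the threshold is a stakeholder
    choice, not a statistical constant.
    """

    p0: float
    gamma: float

    def __post_init__(self) -> None:
        if not (0 <= self.p0 < 1):
            raise ValueError(f"p0 must be in [0,1), got {self.p0}")
        if not (0 < self.gamma <= 1):
            raise ValueError(f"gamma must be in (0,1], got {self.gamma}")


@dataclass(frozen=True)
class SuccessResult:
    success: bool
    attained: float
    criterion: SuccessCriterion


def elicit_beta_prior(mean: float, strength: float) -> BetaParams:
    """Construct a beta prior from an elicited mean and total pseudo-count.

    ``alpha = mean * strength`` and ``beta = (1 - mean) * strength``, so the
    prior has exactly the requested mean and carries the weight of
    ``strength`` pseudo-observations.  A mean of 0.10 with strength 10 gives
    Beta(1, 9); mean 0.20 with strength 10 gives Beta(2, 8).
    """
    if not (0 < mean < 1):
        raise ValueError(f"prior mean must be in (0,1), got {mean}")
    if not strength > 0:
        raise ValueError(f"prior strength must be positive, got {strength}")
    return BetaParams(mean * strength, (1.0 - mean) * strength)


def update_beta(prior: BetaParams, successes: int, failures: int) -> BetaParams:
    """Conjugate update: Beta(a, b) + (s successes, f failures) -> Beta(a+s, b+f)."""
    if successes < 0 or failures < 0:
        raise ValueError(
            f"counts must be non-negative, got successes={successes}, failures={failures}"
        )
    return BetaParams(prior.alpha + successes, prior.beta + failures)


def posterior_for(prior: BetaParams, n: int, events: int) -> BetaParams:
    """Posterior after observing ``events`` out of ``n`` patients."""
    return update_beta(prior, events, n - events)


def posterior_mean(params: BetaParams) -> float:
    """Mean alpha / (alpha + beta) of the beta distribution."""
    return params.mean


def credible_interval(
    params: BetaParams, level: float = 0.95, method: str = "equal-tailed"
) -> ProbabilityInterval:
    """Posterior credible interval at the given coverage level.

    The default is the equal-tailed interval, whose endpoints are the
    (1-level)/2 and 1-(1-level)/2 beta quantiles.  ``method="hpd"`` gives the
    highest-posterior-density interval instead (shortest interval with the
    requested coverage); it is offered for sensitivity analysis but is never
    the default.
    """
    if not (0 < level < 1):
        raise ValueError(f"level must be in (0,1), got {level}")
    if method == "equal-tailed":
        tail = (1.0 - level) / 2.0
        d = params.dist()
        lower, upper = d.ppf(tail), d.ppf(1.0 - tail)
    elif method == "hpd":
        lower, upper = _hpd_interval(params, level)
    else:
        raise ValueError(f"unknown interval method {method!r}; use 'equal-tailed' or 'hpd'")
    return ProbabilityInterval(float(lower), float(upper), level)


def _hpd_interval(params: BetaParams, level: float) -> tuple[float, float]:
    # Shortest interval [ppf(u), ppf(u+level)] over u in [0, 1-level].
    # The width is unimodal in u for unimodal densities; a fine grid plus a
    # local root solve on the derivative is ample at the tolerances used here.
    d = params.dist()
    if params.alpha <= 1:  # mode at 0: one-sided
        return 0.0, float(d.ppf(level))
    if params.beta <= 1:  # mode at 1
        return float(d.ppf(1.0 - level)), 1.0

    def width(u: float) -> float:
        return d.ppf(u + level) - d.ppf(u)

    import numpy as np

    grid = np.linspace(1e-9, 1.0 - level - 1e-9, 512)
    u0 = grid[np.argmin([width(u) for u in grid])]
    eps = (1.0 - level) / 512
    lo = max(u0 - 2 * eps, 1e-9)
    hi = min(u0 + 2 * eps, 1.0 - level - 1e-9)

    def dwidth(u: float, h: float = 1e-7) -> float:
        return width(min(u + h, 1.0 - level)) - width(max(u - h, 0.0))

    try:
        u_star = brentq(dwidth, lo, hi, xtol=1e-12)
    except ValueError:
        u_star = u0
    return float(d.ppf(u_star)), float(d.ppf(u_star + level))


def exceedance_probability(params: BetaParams, threshold: float) -> float:
    """Posterior probability that the parameter exceeds ``threshold``.

    This is the beta survival function 1 - I_threshold(alpha, beta), the
    quantity a go/no-go rule compares against its required assurance.
    """
    if not (0 <= threshold <= 1):
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    return float(params.dist().sf(threshold))


def evaluate_success(posterior: BetaParams, criterion: SuccessCriterion) -> SuccessResult:
    """Apply a posterior-assurance success rule to a trial posterior."""
    attained = exceedance_probability(posterior, criterion.p0)
    return SuccessResult(success=attained >= criterion.gamma, attained=attained, criterion=criterion)
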