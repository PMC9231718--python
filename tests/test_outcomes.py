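"""Surrogate-to-outcome mapping: worked-example cells, oracles, and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aaimpact import (
    BetaParams,
    EfficacyDistribution,
    JointOutcomeGrid,
    SurrogateLinkage,
    ToxicityDistribution,
    ToxicityStructure,
    case_bounds_analysis,
    clinical_benefit_probability,
    collapse_outcomes,
    efficacy_distribution,
    joint_outcome_distribution,
    toxicity_distribution,
)

probs = st.floats(0, 1, allow_nan=False)


@pytest.mark.parametrize(
    "p_se,q,expected",
    [
        (0.28, 0.05, 0.232),
        (1.0, 0.1, 0.7),  # all responders: q irrelevant
        (0.28, 0.0, 0.196),
        (0.0, 0.05, 0.05),  # no responders: linkage floor
    ],
)
def test_clinical_benefit_linkage(p_se, q, expected):
    link = SurrogateLinkage(0.7, q)
    assert clinical_benefit_probability(p_se, link) == pytest.approx(expected)


@settings(deadline=None, max_examples=50)
@given(probs, probs, st.floats(0, 0.15))
def test_linkage_is_affine_with_known_endpoints(p1, p2, q):
    """p(E1) is affine in P(SE) and interpolates q -> P(CB|SE)."""
    link = SurrogateLinkage(0.7, q)
    f = lambda p: clinical_benefit_probability(p, link)
    assert f(0.0) == pytest.approx(q)
    assert f(1.0) == pytest.approx(0.7)
    mid = 0.5 * (p1 + p2)
    assert f(mid) == pytest.approx(0.5 * (f(p1) + f(p2)), abs=1e-12)
    if p1 <= p2:
        assert f(p1) <= f(p2) + 1e-12  # monotone when linkage non-inverted


def test_inverted_linkage_warns_but_is_legal():
    with pytest.warns(UserWarning, match="inverted"):
        SurrogateLinkage(0.2, 0.5)


def test_q_above_advisory_range_warns():
    with pytest.warns(UserWarning, match="advisory"):
        SurrogateLinkage(0.7, 0.3)


@pytest.mark.parametrize(
    "p_cb,p_inf,expected",
    [(0.23, 0.0, (0.23, 0.77, 0.0)), (1.0, 0.0, (1.0, 0.0, 0.0)), (0.3, 0.2, (0.3, 0.5, 0.2))],
)
def test_efficacy_distribution(p_cb, p_inf, expected):
    eff = efficacy_distribution(p_cb, p_inf)
    assert (eff.p_e1, eff.p_e2, eff.p_e3) == pytest.approx(expected)


def test_efficacy_distribution_rejects_excess_mass():
    with pytest.raises(ValueError):
        efficacy_distribution(0.8, 0.3)


@pytest.mark.parametrize(
    "p_t4,structure,expected",
    [
        (0.03, ToxicityStructure(0.0, (0.5, 0.5)), (0.0, 0.485, 0.485, 0.03)),
        (1.0, ToxicityStructure(0.0, (0.5, 0.5)), (0.0, 0.0, 0.0, 1.0)),
        (0.10, ToxicityStructure(0.0, (0.6, 0.4)), (0.0, 0.54, 0.36, 0.10)),
    ],
)
def test_toxicity_distribution(p_t4, structure, expected):
    tox = toxicity_distribution(p_t4, structure)
    assert (tox.p_t1, tox.p_t2, tox.p_t3, tox.p_t4) == pytest.approx(expected)


def test_toxicity_structure_validation():
    with pytest.raises(ValueError):
        ToxicityStructure(0.0, (0.7, 0.5))
    with pytest.raises(ValueError):
        toxicity_distribution(0.6, ToxicityStructure(0.5, (0.5, 0.5)))


def test_joint_grid_is_product_and_marginals_recover():
    eff = EfficacyDistribution(0.23, 0.77, 0.0)
    tox = ToxicityDistribution(0.0, 0.485, 0.485, 0.03)
    grid = joint_outcome_distribution(eff, tox)
    assert grid.cells[0, 1] == pytest.approx(0.23 * 0.485)  # (E1, T2)
    assert grid.cells.sum() == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(grid.efficacy_marginal(), eff.as_array(), atol=1e-12)
    np.testing.assert_allclose(grid.toxicity_marginal(), tox.as_array(), atol=1e-12)


def test_point_mass_marginals_concentrate_the_grid():
    grid = joint_outcome_distribution(
        EfficacyDistribution(0, 1, 0), ToxicityDistribution(0, 0, 1, 0)
    )
    assert grid.cells[1, 2] == 1.0
    assert grid.cells.sum() == 1.0


def test_collapse_expected_case_grid():
    """Frozen arithmetic: eff (0.23,0.77,0) x tox (0,0.485,0.485,0.03)."""
    grid = joint_outcome_distribution(
        EfficacyDistribution(0.23, 0.77, 0.0), ToxicityDistribution(0.0, 0.485, 0.485, 0.03)
    )
    w = collapse_outcomes(grid).w
    assert w == pytest.approx((0.0, 0.11155, 0.11155, 0.0, 0.37345, 0.40345), abs=1e-12)


def test_collapse_all_inferior_is_unacceptable():
    grid = joint_outcome_distribution(
        EfficacyDistribution(0, 0, 1), ToxicityDistribution(0.25, 0.25, 0.25, 0.25)
    )
    assert collapse_outcomes(grid).w == pytest.approx((0, 0, 0, 0, 0, 1))


def _random_grid(rng):
    cells = rng.dirichlet(np.ones(12)).reshape(3, 4)
    return JointOutcomeGrid(cells)


def test_collapse_against_enumeration_oracle():
    """Brute-force category membership over the 12 cells matches collapse."""
    acceptable = {  # (i, j) -> collapsed index; everything else pools into x6
        (0, 0): 0, (0, 1): 1, (0, 2): 2, (1, 0): 3, (1, 1): 4,
    }
    rng = np.random.default_rng(7)
    for _ in range(200):
        grid = _random_grid(rng)
        expected = np.zeros(6)
        for i in range(3):
            for j in range(4):
                expected[acceptable.get((i, j), 5)] += grid.cells[i, j]
        np.testing.assert_allclose(collapse_outcomes(grid).w, expected, atol=1e-15)


@settings(deadline=None, max_examples=100)
@given(st.lists(st.floats(0.01, 10), min_size=12, max_size=12))
def test_collapse_preserves_mass_exactly(raw):
    cells = np.array(raw).reshape(3, 4)
    cells /= cells.sum()
    grid = JointOutcomeGrid(cells)
    w = collapse_outcomes(grid).w
    # conservation: x6 complements the named categories, bit-for-bit
    assert sum(w) == pytest.approx(cells.sum(), abs=1e-12)
    assert all(0 <= v <= 1 for v in w)


def test_collapsed_probabilities_bilinear_in_pcb_and_q(linkage, structure):
    """Under independence each collapsed w is bilinear in (p_cb, p_t4)."""
    from aaimpact import outcome_distribution_from_params

    def w_of(p_se, q):
        return np.array(outcome_distribution_from_params(p_se, q, linkage, structure).w)

    p0, p1, q0, q1 = 0.1, 0.5, 0.02, 0.2
    for t in (0.25, 0.75):
        # affine in p_se at fixed q
        lhs = w_of(p0 + t * (p1 - p0), q0)
        rhs = (1 - t) * w_of(p0, q0) + t * w_of(p1, q0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)
        # affine in q at fixed p_se
        lhs = w_of(p0, q0 + t * (q1 - q0))
        rhs = (1 - t) * w_of(p0, q0) + t * w_of(p0, q1)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


def test_case_bounds_printed_values(post_p, post_q, linkage, structure):
    """Worst/best-case p(E1) at 2 dp match the worked example (0.15, 0.30)."""
    triple = case_bounds_analysis(post_p, post_q, linkage, structure, 0.95, round_inputs=2)
    assert round(triple.pe1["Worst Case"], 2) == pytest.approx(0.15)
    assert round(triple.pe1["Best Case"], 2) == pytest.approx(0.30)
    assert round(triple.pe1["Expected"], 2) == pytest.approx(0.23)
    # worst-case (E1,T2) cell: 0.154 * 0.455
    assert triple.worst.w[1] == pytest.approx(0.154 * 0.455, abs=1e-9)
    assert round(triple.worst.w[1], 2) == pytest.approx(0.07)


def test_case_bounds_orientation(post_p, post_q, linkage, structure):
    """Worst case pairs the low P bound with the high Q bound, and vice versa."""
    triple = case_bounds_analysis(post_p, post_q, linkage, structure, 0.95)
    p_lo, q_hi = triple.pq_worst
    p_hi, q_lo = triple.pq_best
    assert p_lo < triple.pq_expected[0] < p_hi
    assert q_lo < triple.pq_expected[1] < q_hi
    # pessimism monotonicity: more mass on the unacceptable category
    assert triple.worst.w[5] >= triple.best.w[5]


def test_degenerate_posteriors_collapse_the_cases(linkage, structure):
    huge_p = BetaParams(3e7, 7e7)
    huge_q = BetaParams(1e6, 99e6)
    triple = case_bounds_analysis(huge_p, huge_q, linkage, structure, 0.95)
    np.testing.assert_allclose(triple.worst.w, triple.best.w, atol=1e-3)
    np.testing.assert_allclose(triple.expected.w, triple.best.w, atol=1e-3)
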