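"""Permutation inference: OLS identities, exhaustive enumeration, Smith scheme."""

import math

import numpy as np
import pytest

from heartperm import (
    PermutationConfig,
    PermutationResult,
    ProportionSample,
    interaction_perm_test,
    ols_fit,
    pvalue_from_exceedances,
    smith_orthogonalize,
    summarize_table,
    synergy_call,
    two_group_perm_test,
)

from conftest import make_embryo
from heartperm import records_to_frame


def interaction_sample(yP, yQ, yD):
    y = np.concatenate([yP, yQ, yD])
    ind = np.array([[1, 0]] * len(yP) + [[0, 1]] * len(yQ) + [[1, 1]] * len(yD))
    labels = ["P"] * len(yP) + ["Q"] * len(yQ) + ["D"] * len(yD)
    return ProportionSample(y=y, group_labels=np.array(labels), indicators=ind)


# --- ols_fit ----------------------------------------------------------------

def test_ols_separated_groups():
    X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
    beta = ols_fit(X, [0, 0, 1, 1])
    assert beta[1] == pytest.approx(1.0)


def test_ols_interaction_group_mean_identity():
    s = interaction_sample([0.10, 0.10], [0.20, 0.20], [0.40, 0.40])
    Ip, Iq = s.indicators[:, 0], s.indicators[:, 1]
    beta = ols_fit(np.column_stack([Ip, Iq, Ip * Iq]), s.y)
    assert beta[2] == pytest.approx(0.10)


def test_ols_constant_response():
    X = np.column_stack([np.ones(5), [0, 1, 0, 1, 1]])
    beta = ols_fit(X, np.full(5, 0.3))
    assert beta[1] == pytest.approx(0.0, abs=1e-12)


def test_ols_rank_deficiency_names_columns():
    X = np.column_stack([np.ones(4), [1, 1, 1, 1]])
    with pytest.raises(np.linalg.LinAlgError, match="intercept|dup"):
        ols_fit(X, [0, 1, 0, 1], column_names=["intercept", "dup"])


def test_interaction_coefficient_identity_random_designs(rng):
    """Fitted b3 equals mean(D) − mean(P) − mean(Q) on arbitrary data."""
    for _ in range(100):
        sizes = rng.integers(2, 9, size=3)
        yP, yQ, yD = (rng.random(k) for k in sizes)
        s = interaction_sample(yP, yQ, yD)
        Ip, Iq = s.indicators[:, 0], s.indicators[:, 1]
        beta = ols_fit(np.column_stack([Ip, Iq, Ip * Iq]), s.y)
        closed = yD.mean() - yP.mean() - yQ.mean()
        assert abs(beta[2] - closed) < 1e-10


# --- p-value estimator ------------------------------------------------------

@pytest.mark.parametrize(
    "n,N,expected",
    [(0, 10**6, 1 / 1_000_001), (999, 999, 1.0), (49, 999, 0.05)],
)
def test_pvalue_formula(n, N, expected):
    assert pvalue_from_exceedances(n, N) == pytest.approx(expected)


def test_pvalue_validation_and_monotonicity():
    with pytest.raises(ValueError):
        pvalue_from_exceedances(11, 10)
    ps = [pvalue_from_exceedances(n, 100) for n in range(101)]
    assert all(a < b for a, b in zip(ps, ps[1:]))


# --- two-group test ---------------------------------------------------------

def two_group_sample(yA, yB):
    y = np.concatenate([yA, yB])
    labels = np.array(["A"] * len(yA) + ["B"] * len(yB))
    return ProportionSample(y=y, group_labels=labels,
                            indicators=(labels == "B").astype(float))


def test_exhaustive_separated_groups():
    """All-or-nothing data: only the identity labelling reaches b1=1, p=1/20."""
    res = two_group_perm_test(
        two_group_sample([0, 0, 0], [1, 1, 1]), PermutationConfig(n_permutations=100)
    )
    assert res.exhaustive
    assert res.coefficient == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1 / 20)
    assert res.n_permutations == 19 and res.exceedances == 0


def test_constant_response_p_one_under_geq():
    res = two_group_perm_test(
        two_group_sample([0.3] * 4, [0.3] * 4),
        PermutationConfig(n_permutations=100, tie_rule="geq"),
    )
    assert res.p_value == pytest.approx(1.0)
    assert res.coefficient == pytest.approx(0.0)


def test_degenerate_single_embryo_group_warns():
    with pytest.warns(UserWarning, match="degenerate"):
        res = two_group_perm_test(
            two_group_sample([0.1], [0.2, 0.3, 0.4]), PermutationConfig()
        )
    assert res.degenerate


def test_relabel_complement_identity(rng):
    """Upper-tail exceedances of (A,B) and (B,A) partition the arrangements."""
    y = rng.random(6)
    sA = ProportionSample(
        y=y, group_labels=np.array(list("AAABBB")),
        indicators=np.array([0, 0, 0, 1, 1, 1.0]),
    )
    sB = ProportionSample(
        y=y, group_labels=np.array(list("AAABBB")),
        indicators=np.array([1, 1, 1, 0, 0, 0.0]),
    )
    strict_B = two_group_perm_test(sB, PermutationConfig(tie_rule="strict"))
    geq_A = two_group_perm_test(sA, PermutationConfig(tie_rule="geq"))
    N = strict_B.n_permutations
    assert strict_B.exceedances == N - geq_A.exceedances


def test_monte_carlo_matches_exhaustive(rng):
    """Oracle equivalence: sampled p converges to the enumerated p."""
    N = 10_000
    for _ in range(4):
        y = np.round(rng.random(8), 2)  # rounding induces occasional ties
        s = two_group_sample(y[:4], y[4:])
        cfg = PermutationConfig(n_permutations=N, tie_rule="geq", seed=int(rng.integers(2**31)))
        exact = two_group_perm_test(s, cfg).p_value
        mc = two_group_perm_test(
            s, PermutationConfig(n_permutations=N, tie_rule="geq",
                                 exhaustive_threshold=1, seed=cfg.seed)
        ).p_value
        assert abs(mc - exact) < 3 * math.sqrt(exact * (1 - exact) / N) + 1e-12


def test_two_sided_tail_uses_magnitude():
    s = two_group_sample([1, 1, 1], [0, 0, 0])  # strong effect, negative b1
    upper = two_group_perm_test(s, PermutationConfig(tail="upper", tie_rule="geq"))
    two = two_group_perm_test(s, PermutationConfig(tail="two_sided", tie_rule="geq"))
    assert upper.coefficient == pytest.approx(-1.0)
    assert two.p_value < upper.p_value


# --- Smith orthogonalization ------------------------------------------------

def test_smith_identity_on_orthogonal_input():
    Z = np.array([[1.0, 0], [1, 0], [0, 1], [0, 1]])
    g = np.array([1.0, -1, 0, 0])
    np.testing.assert_allclose(smith_orthogonalize(Z, g), g, atol=1e-12)


def test_smith_annihilates_span_and_test_refuses():
    Z = np.column_stack([np.ones(6), np.arange(6.0)])
    g = 2 * Z[:, 0] - 3 * Z[:, 1]
    assert np.linalg.norm(smith_orthogonalize(Z, g)) < 1e-10
    # a saturated two-group interaction design: D group empty -> error first;
    # span-degenerate case surfaces as non-identifiable interaction
    y = np.array([0.1, 0.2, 0.3, 0.4])
    ind = np.array([[1, 0], [1, 0], [0, 1], [1, 1.0]])
    s = ProportionSample(y=y, group_labels=np.array(["P", "P", "Q", "D"]), indicators=ind)
    res = interaction_perm_test(s, PermutationConfig(tie_rule="geq"))
    assert isinstance(res, PermutationResult)  # identifiable with all groups present


def test_smith_matches_dense_projector_oracle(rng):
    """g⊥ agrees with the explicit hat-matrix projection on random designs,
    and balanced designs give constant g⊥ within groups."""
    for _ in range(20):
        n, k = int(rng.integers(6, 30)), int(rng.integers(1, 4))
        Z = rng.normal(size=(n, k))
        g = rng.normal(size=n)
        gp = smith_orthogonalize(Z, g)
        P = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
        np.testing.assert_allclose(gp, g - P @ g, atol=1e-9)
        assert np.abs(Z.T @ gp).max() < 1e-8

    m = 4
    Ip = np.array([1.0] * m + [0.0] * m + [1.0] * m)
    Iq = np.array([0.0] * m + [1.0] * m + [1.0] * m)
    gp = smith_orthogonalize(np.column_stack([Ip, Iq]), Ip * Iq)
    for grp in (slice(0, m), slice(m, 2 * m), slice(2 * m, 3 * m)):
        assert np.ptp(gp[grp]) < 1e-12


# --- interaction permutation test -------------------------------------------

def test_interaction_zero_noise_synergy_is_extreme():
    res = interaction_perm_test(
        interaction_sample([0.10] * 3, [0.20] * 3, [0.40] * 3),
        PermutationConfig(n_permutations=100),
    )
    assert res.exhaustive and res.scheme == "smith"
    assert res.coefficient == pytest.approx(0.10)
    # observed statistic is the maximum over all 9!/(3!6!)-style arrangements
    assert res.exceedances == 0
    assert res.p_value == pytest.approx(1 / 84)


def test_interaction_additive_data_has_zero_coefficient():
    res = interaction_perm_test(
        interaction_sample([0.1] * 4, [0.2] * 4, [0.3] * 4),
        PermutationConfig(tie_rule="geq"),
    )
    assert res.coefficient == pytest.approx(0.0, abs=1e-12)
    assert res.p_value > 0.5


def test_interaction_constant_response():
    """Constant y in the intercept-free model: b3 = −ȳ (the double group
    cannot equal the sum of the singles), and the observed statistic is the
    permutation minimum, so p = 1 under the inclusive tie rule."""
    res = interaction_perm_test(
        interaction_sample([0.2] * 3, [0.2] * 3, [0.2] * 3),
        PermutationConfig(tie_rule="geq"),
    )
    assert res.coefficient == pytest.approx(-0.2)
    assert res.p_value == pytest.approx(1.0)
    # with an intercept (controls included) the additive fit absorbs the
    # constant: b3 = yD − yP − yQ + yC = 0
    y = np.full(12, 0.2)
    ind = np.array([[0, 0]] * 3 + [[1, 0]] * 3 + [[0, 1]] * 3 + [[1, 1]] * 3)
    labels = np.array(["C"] * 3 + ["P"] * 3 + ["Q"] * 3 + ["D"] * 3)
    s = ProportionSample(y=y, group_labels=labels, indicators=ind)
    res_i = interaction_perm_test(s, PermutationConfig(tie_rule="geq"), with_intercept=True)
    assert res_i.coefficient == pytest.approx(0.0, abs=1e-12)


def test_interaction_empty_group_rejected():
    y = np.array([0.1, 0.2, 0.3, 0.4])
    ind = np.array([[1, 0], [1, 0], [0, 1], [0, 1.0]])
    s = ProportionSample(y=y, group_labels=np.array(["P", "P", "Q", "Q"]), indicators=ind)
    with pytest.raises(ValueError, match="double_het.*empty"):
        interaction_perm_test(s, PermutationConfig())


def test_interaction_controls_require_intercept():
    y = np.array([0.0, 0.1, 0.2, 0.4])
    ind = np.array([[0, 0], [1, 0], [0, 1], [1, 1.0]])
    s = ProportionSample(
        y=y, group_labels=np.array(["C", "P", "Q", "D"]), indicators=ind
    )
    with pytest.raises(ValueError, match="intercept"):
        interaction_perm_test(s, PermutationConfig())
    res = interaction_perm_test(s, PermutationConfig(tie_rule="geq"), with_intercept=True)
    # with intercept: b3 = yD − yP − yQ + yC
    assert res.coefficient == pytest.approx(0.4 - 0.1 - 0.2 + 0.0)


def test_interaction_monte_carlo_matches_exhaustive(rng):
    y = rng.random(12)
    s = interaction_sample(y[:4], y[4:8], y[8:])
    N = 10_000
    exact = interaction_perm_test(
        s, PermutationConfig(n_permutations=N, tie_rule="geq")
    )
    assert exact.exhaustive
    mc = interaction_perm_test(
        s, PermutationConfig(n_permutations=N, tie_rule="geq",
                             exhaustive_threshold=1, seed=3),
    )
    p = exact.p_value
    assert abs(mc.p_value - p) < 3 * math.sqrt(p * (1 - p) / N) + 1e-12


def test_permutation_unit_is_the_embryo():
    """Adding hemisegments to one embryo changes its Y_j, never the number
    of exchangeable units."""
    others = [make_embryo(f"e{i}", genotype="A") for i in range(1, 3)]
    others += [make_embryo(f"m{i}", genotype="B") for i in range(3)]
    flat_others = [r for embryo in others for r in embryo]
    defect = {("A2", "L"): {"tin_cc": 3}}

    # e0 scored over 8 hemisegments vs fully over all 14
    e0_partial = make_embryo("e0", genotype="A", overrides=defect)[:8]
    e0_full = make_embryo("e0", genotype="A", overrides=defect)

    samples = []
    for e0 in (e0_partial, e0_full):
        summary = summarize_table(records_to_frame(flat_others + e0))
        samples.append(ProportionSample.two_group(summary, "tin_symmetric", "B", "A"))
    s1, s2 = samples

    assert len(s1.y) == len(s2.y) == 6
    r1 = two_group_perm_test(s1, PermutationConfig(tie_rule="geq"))
    r2 = two_group_perm_test(s2, PermutationConfig(tie_rule="geq"))
    assert r1.n_permutations == r2.n_permutations  # same arrangement space
    assert r1.coefficient != r2.coefficient        # but Y_j moved


# --- synergy call -----------------------------------------------------------

def _result(coef, p):
    return PermutationResult(
        coefficient=coef, exceedances=0, n_permutations=999, p_value=p,
        exhaustive=False, scheme="smith", seed=0,
    )


@pytest.mark.parametrize(
    "coef,p,expected",
    [
        (0.08, 0.012, "synergistic"),
        (0.05, 0.069, "not_synergistic"),   # borderline stays non-synergistic
        (-0.02, 0.001, "not_synergistic"),  # negative b3 never synergistic
    ],
)
def test_synergy_call(coef, p, expected):
    assert synergy_call(_result(coef, p), alpha=0.05) == expected
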