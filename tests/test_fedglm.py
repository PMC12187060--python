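"""IRLS GLM: local contributions, pooled oracle agreement, federation identity."""

import numpy as np
import pytest
import statsmodels.api as sm

from fedomop import (
    DataError,
    DisclosureSettings,
    GLMSpec,
    RankDeficiencyError,
    SiteServer,
    UsageError,
    WideDataset,
    fed_fit,
    irls_local_contribution,
    parse_formula,
    pooled_glm_fit,
)

import pandas as pd


# --- local contributions ---------------------------------------------------


def test_gaussian_contribution_is_plain_sums():
    X = np.ones((3, 1))
    y = np.array([1.0, 2.0, 3.0])
    info, score, deviance, n = irls_local_contribution(X, y, np.zeros(1), "gaussian_identity")
    assert info == pytest.approx(np.array([[3.0]]))
    assert score == pytest.approx(np.array([6.0]))
    assert deviance == pytest.approx(14.0)  # sum of squares at beta=0
    assert n == 3


def test_binomial_at_zero_beta_has_quarter_weights():
    rng = np.random.default_rng(1)
    X = np.column_stack([np.ones(20), rng.normal(size=20)])
    y = (rng.random(20) < 0.5).astype(float)
    info, score, _, _ = irls_local_contribution(X, y, np.zeros(2), "binomial_logit")
    assert np.allclose(info, 0.25 * X.T @ X)


def test_contribution_matches_naive_loop_oracle():
    """Vectorized statistics equal a literal elementwise re-computation."""
    rng = np.random.default_rng(7)
    n, p = 40, 3
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    y = (rng.random(n) < 0.4).astype(float)
    beta = rng.normal(size=p) * 0.3

    info, score, deviance, _ = irls_local_contribution(X, y, beta, "binomial_logit")

    info_o = np.zeros((p, p))
    score_o = np.zeros(p)
    dev_o = 0.0
    for i in range(n):
        eta = float(X[i] @ beta)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        z = eta + (y[i] - mu) / w
        for a in range(p):
            score_o[a] += w * z * X[i, a]
            for b in range(p):
                info_o[a, b] += w * X[i, a] * X[i, b]
        dev_o += -2 * (y[i] * np.log(mu) + (1 - y[i]) * np.log(1 - mu))
    assert np.allclose(info, info_o)
    assert np.allclose(score, score_o)
    assert deviance == pytest.approx(dev_o)


def test_non_binary_outcome_rejected():
    with pytest.raises(DataError):
        irls_local_contribution(np.ones((3, 1)), np.array([0.0, 1.0, 2.0]), np.zeros(1))


# --- pooled fits -----------------------------------------------------------


def _grouped_design():
    # exposed: 30 cases / 10 non-cases; unexposed: 20 cases / 40 non-cases
    x = np.array([1] * 40 + [0] * 60, dtype=float)
    y = np.array([1] * 30 + [0] * 10 + [1] * 20 + [0] * 40, dtype=float)
    return np.column_stack([np.ones(100), x]), y


def test_saturated_logistic_recovers_cross_product_ratio():
    X, y = _grouped_design()
    result = pooled_glm_fit(X, y, GLMSpec(outcome="y", predictors=("x",)))
    assert result.odds_ratios[1] == pytest.approx((30 * 40) / (10 * 20), rel=1e-6)


def test_intercept_only_binomial_is_logit_of_mean():
    rng = np.random.default_rng(3)
    y = (rng.random(50) < 0.3).astype(float)
    X = np.ones((50, 1))
    result = pooled_glm_fit(X, y, GLMSpec(outcome="y", predictors=()))
    mean = y.mean()
    assert result.coefficients[0] == pytest.approx(np.log(mean / (1 - mean)), rel=1e-8)


def test_gaussian_reaches_closed_form_in_one_iteration():
    rng = np.random.default_rng(4)
    X = np.column_stack([np.ones(30), rng.normal(size=30)])
    y = 2.0 + 0.5 * X[:, 1] + rng.normal(size=30)
    result = pooled_glm_fit(
        X, y, GLMSpec(outcome="y", predictors=("x",), family="gaussian_identity")
    )
    closed_form = np.linalg.solve(X.T @ X, X.T @ y)
    assert np.allclose(result.coefficients, closed_form, atol=0, rtol=0)
    assert result.iterations == 1
    assert result.converged


def test_pooled_fit_matches_statsmodels_reference():
    """Random logistic instances agree with an independent implementation to
    1e-8."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = int(rng.integers(80, 300))
        p = int(rng.integers(1, 4))
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
        beta_true = rng.normal(size=p + 1)
        prob = 1.0 / (1.0 + np.exp(-(X @ beta_true)))
        y = (rng.random(n) < prob).astype(float)
        # run both to full convergence so the comparison is MLE vs MLE
        spec = GLMSpec(
            outcome="y", predictors=tuple(f"x{j}" for j in range(p)), tolerance=1e-12
        )
        result = pooled_glm_fit(X, y, spec)
        reference = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-12)
        assert np.max(np.abs(result.coefficients - reference.params)) < 1e-8
        assert np.max(np.abs(result.standard_errors - reference.bse)) < 1e-6


def test_binomial_deviance_never_increases():
    rng = np.random.default_rng(13)
    n = 500
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
    prob = 1.0 / (1.0 + np.exp(-(X @ np.array([-1.0, 0.8, -0.5, 1.2]))))
    y = (rng.random(n) < prob).astype(float)
    beta = np.zeros(4)
    deviances = []
    for _ in range(10):
        info, score, deviance, _ = irls_local_contribution(X, y, beta)
        deviances.append(deviance)
        beta = np.linalg.solve(info, score)
    assert all(b <= a + 1e-12 for a, b in zip(deviances, deviances[1:]))


def test_collinear_design_names_the_columns():
    rng = np.random.default_rng(5)
    x = rng.normal(size=60)
    X = np.column_stack([np.ones(60), x, x])  # duplicated predictor
    y = (rng.random(60) < 0.5).astype(float)
    spec = GLMSpec(outcome="y", predictors=("dup_a", "dup_b"))
    with pytest.raises(RankDeficiencyError) as err:
        pooled_glm_fit(X, y, spec)
    assert "dup_a" in str(err.value) and "dup_b" in str(err.value)


# --- federation identity ---------------------------------------------------


def _sites_from_partition(X, y, labels, names):
    sites = []
    settings = DisclosureSettings(subset_threshold=1, glm_ratio_limit=1.0)
    for part in sorted(set(labels)):
        mask = labels == part
        df = pd.DataFrame(X[mask, 1:], columns=list(names))
        df.insert(0, "person_id", np.nonzero(mask)[0] + 1)
        df["y"] = y[mask]
        site = SiteServer(f"s{part}", None, settings)
        site._bind("d", WideDataset(data=df))
        sites.append(site)
    return sites


@pytest.mark.parametrize("family", ["binomial_logit", "gaussian_identity"])
def test_federated_equals_pooled_for_random_partitions(family):
    rng = np.random.default_rng(17)
    n, p = 600, 3
    names = tuple(f"x{j}" for j in range(p))
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
    if family == "binomial_logit":
        prob = 1.0 / (1.0 + np.exp(-(X @ np.array([-0.5, 1.0, -0.7, 0.3]))))
        y = (rng.random(n) < prob).astype(float)
    else:
        y = X @ np.array([1.0, 2.0, -1.0, 0.5]) + rng.normal(size=n)
    spec = GLMSpec(outcome="y", predictors=names, family=family)
    pooled = pooled_glm_fit(X, y, spec)
    for seed in range(3):
        labels = np.random.default_rng(seed).integers(0, 4, size=n)
        sites = _sites_from_partition(X, y, labels, names)
        fed = fed_fit(sites, "d", spec)
        tol = 1e-8 * (1 + np.abs(pooled.coefficients))
        assert np.all(np.abs(fed.coefficients - pooled.coefficients) <= tol)
        assert np.allclose(fed.standard_errors, pooled.standard_errors, rtol=1e-8)
        assert fed.n_total == n


def test_single_site_federation_is_bitwise_pooled():
    rng = np.random.default_rng(19)
    n = 200
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    prob = 1.0 / (1.0 + np.exp(-(X @ np.array([0.2, -0.8]))))
    y = (rng.random(n) < prob).astype(float)
    spec = GLMSpec(outcome="y", predictors=("x0",))
    pooled = pooled_glm_fit(X, y, spec)
    sites = _sites_from_partition(X, y, np.zeros(n, dtype=int), ("x0",))
    fed = fed_fit(sites, "d", spec)
    assert np.array_equal(fed.coefficients, pooled.coefficients)
    assert np.array_equal(fed.standard_errors, pooled.standard_errors)
    assert fed.deviance == pooled.deviance


def test_site_order_does_not_matter():
    rng = np.random.default_rng(23)
    n = 400
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    prob = 1.0 / (1.0 + np.exp(-(X @ np.array([0.1, 0.6, -0.4]))))
    y = (rng.random(n) < prob).astype(float)
    labels = rng.integers(0, 3, size=n)
    names = ("x0", "x1")
    spec = GLMSpec(outcome="y", predictors=names)
    sites = _sites_from_partition(X, y, labels, names)
    forward = fed_fit(sites, "d", spec)
    backward = fed_fit(sites[::-1], "d", spec)
    assert np.allclose(forward.coefficients, backward.coefficients, atol=1e-12)
    assert np.allclose(forward.standard_errors, backward.standard_errors, atol=1e-12)


def test_wald_summaries_are_consistent():
    X, y = _grouped_design()
    result = pooled_glm_fit(X, y, GLMSpec(outcome="y", predictors=("x",)))
    assert np.all(result.ci_low <= result.odds_ratios)
    assert np.all(result.odds_ratios <= result.ci_high)
    assert np.all((0 <= result.p_values) & (result.p_values <= 1))
    # Wald CI reconstruction
    zcrit = 1.959963984540054
    assert result.ci_high[1] == pytest.approx(
        np.exp(result.coefficients[1] + zcrit * result.standard_errors[1])
    )


def test_formula_parsing():
    outcome, predictors = parse_formula("copd ~ tobacco_use + history_of_asthma")
    assert outcome == "copd"
    assert predictors == ("tobacco_use", "history_of_asthma")
    assert parse_formula("y ~ 1") == ("y", ())
    with pytest.raises(UsageError):
        parse_formula("no_tilde_here")
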