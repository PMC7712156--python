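import numpy as np
import pytest
from scipy import linalg as sla
from scipy import stats as sps

from metapanel import (auroc, fit_fda, fit_kde, project, threshold_at_beta)
from metapanel.fda import FdaError


def random_instance(rng, n=None, k=None):
    n = n or int(rng.integers(8, 41))
    k = k or int(rng.integers(1, 7))
    n1 = max(2, n // 2)
    X = rng.standard_normal((n, k))
    X[:n1] += rng.standard_normal(k)
    labels = np.array(["ASD"] * n1 + ["TD"] * (n - n1))
    return X, labels


def leading_generalized_eigvec(S_B, S_W):
    """Independent oracle: leading eigenvector of the (S_B, S_W) pencil."""
    vals, vecs = sla.eigh(S_B, S_W)
    v = vecs[:, -1]
    return vals[-1], v / np.linalg.norm(v)


def test_single_feature_sign():
    X = np.array([[3.0], [4.0], [1.0], [2.0]])
    model = fit_fda(X, ["ASD", "ASD", "TD", "TD"])
    assert model.W == pytest.approx([1.0])
    assert model.positive_label == "ASD"


def test_matches_eigen_oracle():
    rng = np.random.default_rng(42)
    for _ in range(30):
        X, labels = random_instance(rng)
        model = fit_fda(X, labels)
        eigval, v = leading_generalized_eigvec(model.S_B, model.S_W)
        if v @ model.W < 0:
            v = -v
        assert np.allclose(model.W, v, atol=1e-8)
        assert model.J == pytest.approx(eigval, abs=1e-8)


def test_degenerate_separation():
    X = np.array([[1.0, 2.0], [3.0, 0.0], [1.0, 2.0], [3.0, 0.0]])
    with pytest.raises(FdaError, match="degenerate separation"):
        fit_fda(X, ["ASD", "ASD", "TD", "TD"])


def test_orientation_positive_class_higher():
    rng = np.random.default_rng(1)
    X, labels = random_instance(rng, n=24, k=3)
    model = fit_fda(X, labels)
    scores = project(model, X)
    assert scores[labels == "ASD"].mean() > scores[labels == "TD"].mean()
    assert np.linalg.norm(model.W) == pytest.approx(1.0)


def test_affine_equivariance_preserves_separation():
    rng = np.random.default_rng(2)
    X, labels = random_instance(rng, n=30, k=4)
    base = auroc(project(fit_fda(X, labels), X), labels)
    scale = rng.uniform(0.5, 3.0, size=4)
    shift = rng.standard_normal(4)
    Xt = X * scale + shift
    transformed = auroc(project(fit_fda(Xt, labels), Xt), labels)
    assert transformed == pytest.approx(base, abs=1e-12)


def test_projection_examples():
    X = np.array([[3.0, 1.0], [1.0, 2.0], [0.0, 1.0], [-1.0, 0.0]])
    model = fit_fda(X, ["ASD", "ASD", "TD", "TD"])
    scores = project(model, X)
    mu_pos = model.class_means["ASD"]
    assert mu_pos @ model.W == pytest.approx(scores[:2].mean())
    with pytest.raises(FdaError, match="feature misalignment"):
        project(model, np.ones((2, 3)))


def test_kde_integrates_to_one():
    rng = np.random.default_rng(3)
    for scores in (rng.standard_normal(20), rng.exponential(size=15)):
        d = fit_kde(scores)
        lo, hi = d.support
        x = np.linspace(lo, hi, 4001)
        integral = np.trapezoid(d.pdf(x), x)
        assert integral == pytest.approx(1.0, abs=1e-3)


def test_kde_cdf_centered_on_large_normal_sample():
    rng = np.random.default_rng(4)
    d = fit_kde(rng.standard_normal(100_000))
    assert d.cdf(0.0) == pytest.approx(0.5, abs=0.01)


def test_kde_close_to_ecdf_on_bimodal_sample():
    rng = np.random.default_rng(5)
    scores = np.concatenate([rng.normal(-2, 0.5, 5000), rng.normal(2, 0.5, 5000)])
    d = fit_kde(scores)
    grid = np.linspace(-4, 4, 200)
    ecdf = np.searchsorted(np.sort(scores), grid, side="right") / len(scores)
    assert np.max(np.abs(d.cdf(grid) - ecdf)) < 0.05


def test_kde_matches_scipy_gaussian_kde_with_same_bandwidth():
    """Cross-check the analytic kernel sums against scipy's KDE."""
    rng = np.random.default_rng(6)
    scores = rng.standard_normal(50)
    d = fit_kde(scores)
    gk = sps.gaussian_kde(scores, bw_method=d.bandwidth / scores.std(ddof=1))
    x = np.linspace(-3, 3, 25)
    assert np.allclose(d.pdf(x), gk(x), atol=1e-12)
    assert d.cdf(1.0) == pytest.approx(gk.integrate_box_1d(-np.inf, 1.0), abs=1e-9)


def test_degenerate_scores():
    with pytest.raises(FdaError, match="degenerate scores"):
        fit_kde(np.ones(10))


def test_threshold_quantiles():
    rng = np.random.default_rng(7)
    d = fit_kde(rng.standard_normal(100_000))
    assert threshold_at_beta(d, 0.05).threshold == pytest.approx(-1.645, abs=0.05)
    for beta in (0.01, 0.05, 0.1, 0.2, 0.5):
        t = threshold_at_beta(d, beta).threshold
        assert d.cdf(t) == pytest.approx(beta, abs=1e-3)
    assert (threshold_at_beta(d, 0.01).threshold
            < threshold_at_beta(d, 0.2).threshold)


def test_threshold_median_at_half():
    rng = np.random.default_rng(8)
    d = fit_kde(rng.standard_normal(5000))
    t = threshold_at_beta(d, 0.5).threshold
    assert d.cdf(t) == pytest.approx(0.5, abs=1e-3)


def test_classification_invariant_to_weight_scale():
    """Doubling the (pre-normalization) weights rescales scores and the
    matching threshold identically, leaving classification unchanged."""
    rng = np.random.default_rng(9)
    X, labels = random_instance(rng, n=30, k=3)
    model = fit_fda(X, labels)
    scores = project(model, X)
    d = fit_kde(scores)
    t = threshold_at_beta(d, 0.1).threshold
    scaled_scores = 2.0 * scores
    d2 = fit_kde(scaled_scores)
    t2 = threshold_at_beta(d2, 0.1).threshold
    assert np.array_equal(scores >= t, scaled_scores >= t2)
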