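"""Two-class Fisher discriminant analysis with KDE score densities.

The discriminant seeks the weight vector W maximizing the scatter ratio

    J(W) = (Wᵀ S_B W) / (Wᵀ S_W W),

with class-size-weighted between-class scatter
S_B = Σ_k n_k (x̄_k − x̄)(x̄_k − x̄)ᵀ and within-class scatter
S_W = Σ_k n_k Σ_{i∈k} (x_i − x̄_k)(x_i − x̄_k)ᵀ.  For two classes the
maximizer has the closed form W ∝ S_W⁻¹ (x̄₊ − x̄₋) — the leading
generalized eigenvector of (S_B, S_W) — which is used in the hot path; W is
normalized to unit length and oriented so the positive (treated) class has
the larger mean score.

Discriminant-score distributions are smoothed with a Gaussian-kernel
density (robust Silverman bandwidth).  The classification threshold is the
β-quantile of the positive class's score density: a sample scoring at or
above the threshold is called positive, so β is the Type II
(false-negative) error of the rule on that density.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr


class FdaError(ValueError):
    pass


@dataclass
class FdaModel:
    """A fitted two-class Fisher discriminant."""

    metabolites: list[str] | None    # feature names, None for anonymous matrices
    W: np.ndarray                    # unit-norm weights, positive-class-oriented
    class_means: dict[str, np.ndarray]
    global_mean: np.ndarray
    S_B: np.ndarray
    S_W: np.ndarray
    J: float
    positive_label: str
    negative_label: str

    def to_json(self, path=None):
        d = {
            "metabolites": self.metabolites,
            "W": self.W.tolist(),
            "J": self.J,
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
            "class_means": {k: v.tolist() for k, v in self.class_means.items()},
        }
        if path is None:
            return json.dumps(d, indent=1)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def _scatter_matrices(X: np.ndarray, pos_mask: np.ndarray):
    """Class-size-weighted between- and within-class scatter matrices."""
    mu = X.mean(axis=0)
    Xp, Xn = X[pos_mask], X[~pos_mask]
    n_p, n_n = len(Xp), len(Xn)
    mu_p, mu_n = Xp.mean(axis=0), Xn.mean(axis=0)
    dp, dn = mu_p - mu, mu_n - mu
    S_B = n_p * np.outer(dp, dp) + n_n * np.outer(dn, dn)
    Cp = Xp - mu_p
    Cn = Xn - mu_n
    S_W = n_p * (Cp.T @ Cp) + n_n * (Cn.T @ Cn)
    return mu, mu_p, mu_n, S_B, S_W


def _solve_w(S_W: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Solve S_W W = d, ridge-regularizing only on singularity."""
    try:
        W = np.linalg.solve(S_W, d)
        if np.all(np.isfinite(W)):
            return W
    except np.linalg.LinAlgError:
        pass
    k = S_W.shape[0]
    eps = 1e-8 * np.trace(S_W) / k
    if eps <= 0:
        eps = 1e-12
    try:
        W = np.linalg.solve(S_W + eps * np.eye(k), d)
    except np.linalg.LinAlgError as exc:
        raise FdaError("singular within-class scatter") from exc
    if not np.all(np.isfinite(W)):
        raise FdaError("singular within-class scatter")
    return W


def fit_fda(X, labels, positive_label: str = "ASD",
            metabolites: list[str] | None = None) -> FdaModel:
    """Fit the two-class Fisher discriminant.

    ``X`` is a samples × features matrix (ndarray or DataFrame; a DataFrame
    also supplies feature names).  ``labels`` must contain exactly two
    classes with ≥ 2 samples each; ``positive_label`` names the class whose
    mean score is oriented upward (falls back to the lexicographically
    larger label when absent).
    """
    if isinstance(X, pd.DataFrame):
        metabolites = metabolites or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise FdaError("degenerate labels: need exactly two classes")
    if positive_label not in classes:
        positive_label = classes[-1]
    negative_label = [c for c in classes if c != positive_label][0]
    pos_mask = labels == positive_label
    if pos_mask.sum() < 2 or (~pos_mask).sum() < 2:
        raise FdaError("degenerate labels: need >= 2 samples per class")

    mu, mu_p, mu_n, S_B, S_W = _scatter_matrices(X, pos_mask)
    d = mu_p - mu_n
    if np.allclose(d, 0.0):
        raise FdaError("degenerate separation: identical class means")

    W = _solve_w(S_W, d)
    norm = np.linalg.norm(W)
    if norm == 0 or not np.isfinite(norm):
        raise FdaError("degenerate separation")
    W = W / norm
    if (X[pos_mask] @ W).mean() < (X[~pos_mask] @ W).mean():
        W = -W
    num = float(W @ S_B @ W)
    den = float(W @ S_W @ W)
    J = num / den if den > 0 else np.inf
    return FdaModel(
        metabolites=metabolites, W=W,
        class_means={positive_label: mu_p, negative_label: mu_n},
        global_mean=mu, S_B=S_B, S_W=S_W, J=J,
        positive_label=positive_label, negative_label=negative_label,
    )


def project(model: FdaModel, X) -> np.ndarray:
    """Project samples onto the discriminant axis: score_i = Wᵀ x_i."""
    if isinstance(X, pd.DataFrame):
        if model.metabolites is not None:
            if list(X.columns) != list(model.metabolites):
                if set(X.columns) >= set(model.metabolites):
                    X = X[model.metabolites]
                else:
                    raise FdaError("feature misalignment")
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.W):
        raise FdaError("feature misalignment")
    return X @ model.W


# ---------------------------------------------------------------------------
# Kernel density of discriminant scores
# ---------------------------------------------------------------------------

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass
class Density:
    """Gaussian-kernel density of a score sample with analytic PDF/CDF."""

    scores: np.ndarray
    bandwidth: float

    def pdf(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        u = (x[..., None] - self.scores) / self.bandwidth
        out = np.exp(-0.5 * u * u).mean(axis=-1) / (self.bandwidth * _SQRT_2PI)
        return out if out.shape else float(out)

    def cdf(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        u = (x[..., None] - self.scores) / self.bandwidth
        out = ndtr(u).mean(axis=-1)
        return out if out.shape else float(out)

    @property
    def support(self) -> tuple[float, float]:
        lo = float(self.scores.min() - 10 * self.bandwidth)
        hi = float(self.scores.max() + 10 * self.bandwidth)
        return lo, hi

    def grid(self, n: int = 512) -> pd.DataFrame:
        lo, hi = self.support
        x = np.linspace(lo, hi, n)
        return pd.DataFrame({"score": x, "pdf": self.pdf(x), "cdf": self.cdf(x)})


def silverman_bandwidth(scores: np.ndarray) -> float:
    """Robust Silverman rule: 0.9 · min(s, IQR/1.34) · n^(−1/5)."""
    n = len(scores)
    s = np.std(scores, ddof=1)
    q75, q25 = np.percentile(scores, [75, 25])
    iqr = q75 - q25
    spread = min(s, iqr / 1.34) if iqr > 0 else s
    return float(0.9 * spread * n ** (-0.2))


def fit_kde(scores, bandwidth: float | None = None) -> Density:
    """Gaussian-kernel density estimate of a score sample."""
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(scores)) < 2:
        raise FdaError("degenerate scores: need >= 2 distinct values")
    h = bandwidth if bandwidth is not None else silverman_bandwidth(scores)
    if h <= 0:
        raise FdaError("degenerate scores: zero bandwidth")
    return Density(scores=scores, bandwidth=float(h))


@dataclass
class ThresholdSpec:
    """Score threshold at the β-quantile of the positive-class density."""

    beta: float
    threshold: float


def threshold_at_beta(density: Density, beta: float, tol: float = 1e-6) -> ThresholdSpec:
    """Invert the KDE CDF at β by monotone bisection (CDF tolerance 1e-6).

    Classification rule: score ≥ threshold → positive class, so the
    positive density's mass below the threshold (the Type II error) is β.
    """
    if not (0.0 < beta < 1.0):
        raise FdaError("beta must be in (0, 1)")
    lo, hi = density.support
    # widen until the quantile is bracketed (ndtr(±10) leaves ~1e-23 outside)
    while density.cdf(lo) > beta:
        lo -= 10 * density.bandwidth
    while density.cdf(hi) < beta:
        hi += 10 * density.bandwidth
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c = density.cdf(mid)
        if abs(c - beta) < tol:
            return ThresholdSpec(beta=beta, threshold=float(mid))
        if c < beta:
            lo = mid
        else:
            hi = mid
    return ThresholdSpec(beta=beta, threshold=float(0.5 * (lo + hi)))
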