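"""Exhaustive discriminant-panel search and leave-one-out cross-validation.

The search fits a Fisher discriminant to every 2-, 3- and 4-metabolite
subset of the screened candidates on week-0 data and ranks subsets by
empirical AUROC of their discriminant scores (ties broken by the scatter
ratio J, then by canonical subset order, so results are deterministic and
independent of candidate input order).  The top four-metabolite panels are
greedily augmented with each remaining candidate to form five-metabolite
panels, deduplicated, and re-ranked.

Because the within-class scatter of any subset is a submatrix of the full
within-class scatter, the search precomputes the full-candidate scatter
matrices once and solves all subset discriminants as small batched linear
systems.

Cross-validation leaves one individual out, refits the discriminant and
the positive-class score KDE on the remainder, places the threshold at
each β-quantile, and classifies the held-out sample.  A held-out sample is
called positive exactly when the training positive-density CDF at its
score is ≥ β, which is equivalent to comparing the score against the
β-quantile threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .dataset import StudyDataset
from .fda import FdaError, _scatter_matrices, _solve_w, fit_kde
from .univariate import _auroc_matrix


class SearchError(ValueError):
    pass


@dataclass
class ModelRecord:
    """A candidate panel with its fitted separability."""

    metabolites: tuple[str, ...]     # canonically sorted
    auroc: float
    J: float


@dataclass
class CvReport:
    """Leave-one-out cross-validation outcome for one panel."""

    metabolites: tuple[str, ...]
    rates: dict[float, dict[str, float]]         # β → {"tpr": .., "tnr": ..}
    folds: pd.DataFrame = field(repr=False)      # per held-out sample

    def balanced_accuracy(self, beta: float) -> float:
        r = self.rates[beta]
        return 0.5 * (r["tpr"] + r["tnr"])


# ---------------------------------------------------------------------------
# Batched subset evaluation
# ---------------------------------------------------------------------------

class SubsetEvaluator:
    """Week-0 data prepared for batched subset discriminant fits."""

    def __init__(self, dataset: StudyDataset, positive_label: str = "ASD"):
        week0 = dataset.select(week=0)
        self.metabolites = list(week0.values.columns)
        self.X = week0.values.to_numpy(dtype=float)
        labels = week0.labels
        self.pos_mask = labels == positive_label
        if self.pos_mask.sum() < 2 or (~self.pos_mask).sum() < 2:
            raise SearchError("degenerate labels: need >= 2 samples per class")
        _, mu_p, mu_n, self.SB_full, self.SW_full = _scatter_matrices(self.X, self.pos_mask)
        self.d_full = mu_p - mu_n
        self.col = {m: j for j, m in enumerate(self.metabolites)}

    def evaluate(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """AUROC and J for a (B, k) array of column-index subsets."""
        idx = np.asarray(idx)
        B, k = idx.shape
        Sw = self.SW_full[idx[:, :, None], idx[:, None, :]]
        Sb = self.SB_full[idx[:, :, None], idx[:, None, :]]
        d = self.d_full[idx]
        try:
            W = np.linalg.solve(Sw, d[..., None])[..., 0]
        except np.linalg.LinAlgError:
            W = np.empty((B, k))
            for b in range(B):
                W[b] = _solve_w(Sw[b], d[b])
        bad = ~np.all(np.isfinite(W), axis=1)
        for b in np.nonzero(bad)[0]:
            W[b] = _solve_w(Sw[b], d[b])
        scores = np.einsum("nbk,bk->bn", self.X[:, idx], W)
        auc = _auroc_matrix(scores, self.pos_mask)
        num = np.einsum("bk,bkl,bl->b", W, Sb, W)
        den = np.einsum("bk,bkl,bl->b", W, Sw, W)
        with np.errstate(divide="ignore", invalid="ignore"):
            J = np.where(den > 0, num / den, np.inf)
        return auc, J


def _rank(idx: np.ndarray, auc: np.ndarray, J: np.ndarray, top_n: int,
          metabolites: list[str]) -> list[ModelRecord]:
    """Sort by AUROC desc, J desc, then canonical subset order; truncate."""
    # subsets are generated in lexicographic order, so a stable lexsort with
    # the running index as final key yields canonical tie-breaking
    order = np.lexsort((np.arange(len(auc)), -J, -auc))[:top_n]
    return [
        ModelRecord(
            metabolites=tuple(metabolites[j] for j in idx[i]),
            auroc=float(auc[i]),
            J=float(J[i]),
        )
        for i in order
    ]


def exhaustive_search(dataset: StudyDataset, candidates: list[str], k: int,
                      top_n: int = 1000, max_combinations: int | None = None,
                      seed: int = 0, chunk: int = 20000,
                      evaluator: SubsetEvaluator | None = None) -> list[ModelRecord]:
    """Fit and rank every k-subset of ``candidates`` on week-0 data.

    When the number of combinations exceeds ``max_combinations`` (if set),
    a seeded uniform subsample of subsets is evaluated instead.
    """
    if k > len(candidates):
        raise SearchError("not enough candidates")
    ev = evaluator or SubsetEvaluator(dataset)
    cand = sorted(candidates)
    missing = [c for c in cand if c not in ev.col]
    if missing:
        raise SearchError(f"unknown candidates: {missing[:5]}")
    cols = np.array([ev.col[c] for c in cand])

    total = comb(len(cand), k)
    if max_combinations is not None and total > max_combinations:
        rng = np.random.default_rng(seed)
        picks = {tuple(np.sort(rng.choice(len(cand), size=k, replace=False)))
                 for _ in range(max_combinations)}
        all_combos = sorted(picks)
    else:
        all_combos = combinations(range(len(cand)), k)

    idx_all, auc_all, J_all = [], [], []
    buf: list[tuple[int, ...]] = []

    def flush():
        if not buf:
            return
        idx = cols[np.array(buf)]
        auc, J = ev.evaluate(idx)
        idx_all.append(np.array(buf))
        auc_all.append(auc)
        J_all.append(J)
        buf.clear()

    for combo in all_combos:
        buf.append(combo)
        if len(buf) >= chunk:
            flush()
    flush()
    if not idx_all:
        raise SearchError("not enough candidates")
    local_idx = np.vstack(idx_all)
    auc = np.concatenate(auc_all)
    J = np.concatenate(J_all)
    return _rank(local_idx, auc, J, top_n, cand)


def augment_to_five(dataset: StudyDataset, top4: list[ModelRecord],
                    candidates: list[str], top_n: int = 1000,
                    evaluator: SubsetEvaluator | None = None) -> list[ModelRecord]:
    """Extend each top four-metabolite panel by every remaining candidate.

    Identical five-subsets arising from different parents are deduplicated
    before fitting; results are ranked like the exhaustive search.
    """
    if not top4:
        raise SearchError("nothing to augment")
    ev = evaluator or SubsetEvaluator(dataset)
    cand = sorted(candidates)
    subsets: set[tuple[str, ...]] = set()
    for rec in top4:
        base = set(rec.metabolites)
        for c in cand:
            if c not in base:
                subsets.add(tuple(sorted(base | {c})))
    subset_list = sorted(subsets)
    idx = np.array([[ev.col[m] for m in s] for s in subset_list])
    auc_all, J_all = [], []
    for start in range(0, len(idx), 20000):
        a, j = ev.evaluate(idx[start:start + 20000])
        auc_all.append(a)
        J_all.append(j)
    auc = np.concatenate(auc_all)
    J = np.concatenate(J_all)
    order = np.lexsort((np.arange(len(auc)), -J, -auc))[:top_n]
    return [ModelRecord(metabolites=subset_list[i], auroc=float(auc[i]), J=float(J[i]))
            for i in order]


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------

DEFAULT_BETAS = (0.01, 0.05, 0.1, 0.2)


def loo_cv(dataset: StudyDataset, subset: list[str],
           betas: tuple[float, ...] = DEFAULT_BETAS,
           positive_label: str = "ASD") -> CvReport:
    """Leave-one-out cross-validation of one panel on week-0 data.

    Each fold refits the discriminant and the positive-class score KDE on
    the remaining samples, thresholds at each β, and classifies the
    held-out sample (score ≥ threshold → positive).
    """
    week0 = dataset.select(week=0)
    X = week0.values[list(subset)].to_numpy(dtype=float)
    labels = week0.labels
    pos_mask = labels == positive_label
    n = len(X)
    if pos_mask.sum() < 2 or (~pos_mask).sum() < 2:
        raise SearchError("fold degeneracy: need >= 2 samples per class")
    if len(subset) >= min(pos_mask.sum(), (~pos_mask).sum()):
        raise SearchError("panel larger than the smallest class")

    rows = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        if pos_mask[keep].sum() < 2 or (~pos_mask[keep]).sum() < 2:
            raise SearchError("fold degeneracy")
        Xtr = X[keep]
        ptr = pos_mask[keep]
        _, mu_p, mu_n, _, S_W = _scatter_matrices(Xtr, ptr)
        d = mu_p - mu_n
        if np.allclose(d, 0.0):
            raise SearchError("fold degeneracy: identical class means")
        W = _solve_w(S_W, d)
        W = W / np.linalg.norm(W)
        if (Xtr[ptr] @ W).mean() < (Xtr[~ptr] @ W).mean():
            W = -W
        density = fit_kde(Xtr[ptr] @ W)
        score = float(X[i] @ W)
        cdf = float(density.cdf(score))
        row = {"sample_id": week0.sample_ids[i],
               "label": labels[i], "score": score, "cdf": cdf}
        for beta in betas:
            row[f"pred_{beta:g}"] = positive_label if cdf >= beta else "other"
        rows.append(row)
    folds = pd.DataFrame(rows)

    rates = {}
    is_pos = folds["label"] == positive_label
    for beta in betas:
        pred_pos = folds[f"pred_{beta:g}"] == positive_label
        tpr = float((pred_pos & is_pos).sum() / is_pos.sum())
        tnr = float((~pred_pos & ~is_pos).sum() / (~is_pos).sum())
        rates[beta] = {"tpr": tpr, "tnr": tnr}
    return CvReport(metabolites=tuple(sorted(subset)), rates=rates, folds=folds)


def select_best(reports: list[CvReport], beta: float = 0.05) -> list[CvReport]:
    """All reports tied at the maximum balanced accuracy at ``beta``."""
    if not reports:
        raise SearchError("nothing to select")
    best = max(r.balanced_accuracy(beta) for r in reports)
    return [r for r in reports if r.balanced_accuracy(beta) == best]


# ---------------------------------------------------------------------------
# End-to-end search helper
# ---------------------------------------------------------------------------

def search_pipeline(dataset: StudyDataset, candidates: list[str],
                    ks: tuple[int, ...] = (2, 3, 4), top_n: int = 1000,
                    cv_top_n: int = 1000, betas: tuple[float, ...] = DEFAULT_BETAS,
                    selection_beta: float = 0.05,
                    max_combinations: int | None = None, seed: int = 0) -> dict:
    """Exhaustive search per k, augmentation to five, CV and selection.

    Returns a dict with per-k rankings (``by_k``), the five-metabolite
    ranking (``five``), CV reports for the top ``cv_top_n`` five-metabolite
    panels (``cv_reports``) and the tied best panels (``best``).
    """
    ev = SubsetEvaluator(dataset)
    by_k = {k: exhaustive_search(dataset, candidates, k, top_n=top_n,
                                 max_combinations=max_combinations, seed=seed,
                                 evaluator=ev)
            for k in ks}
    five = augment_to_five(dataset, by_k[max(ks)], candidates, top_n=top_n,
                           evaluator=ev)
    cv_reports = [loo_cv(dataset, list(rec.metabolites), betas=betas)
                  for rec in five[:cv_top_n]]
    best = select_best(cv_reports, beta=selection_beta)
    return {"by_k": by_k, "five": five, "cv_reports": cv_reports, "best": best}


def records_table(records: list[ModelRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "rank": np.arange(1, len(records) + 1),
        "metabolites": ["|".join(r.metabolites) for r in records],
        "auroc": [r.auroc for r in records],
        "J": [r.J for r in records],
    })


def appearance_frequency(records: list[ModelRecord]) -> pd.Series:
    """Fraction of ranked panels containing each metabolite."""
    counts: dict[str, int] = {}
    for rec in records:
        for m in rec.metabolites:
            counts[m] = counts.get(m, 0) + 1
    freq = pd.Series(counts, dtype=float) / max(len(records), 1)
    return freq.sort_values(ascending=False)
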