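"""Per-metabolite screening and change testing.

Four analyses:

* **AUROC screen** — rank-based (Mann–Whitney) area under the ROC curve of
  each metabolite for separating the two cohorts at week 0, used
  orientation-free (``max(A, 1−A)`` ≥ 0.5) since a metabolite can be
  elevated in either cohort.  Metabolites with AUROC strictly above the
  threshold (default 0.6) become panel candidates.
* **Paired change test** — week 0 vs week 18 within the treated cohort:
  Anderson–Darling normality at both time points routes to a paired t-test
  (normal at both) or a Wilcoxon signed-rank test.
* **Leave-n-out FDR** — the stability statistic: the proportion of all
  leave-n-out subject subsets (n = 1, 2, 3) whose rerun change test is
  non-significant.
* **Correlation panel** — Pearson correlations between panel metabolites
  and comparators over the pooled week-0 samples, reported when p < α.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataset import StudyDataset


class UnivariateError(ValueError):
    pass


@dataclass
class UnivariateResult:
    metabolite: str
    auroc_week0: float
    auroc_week18: float | None = None
    change_p: float | None = None
    test_used: str | None = None
    fdr_n1: float | None = None
    fdr_n2: float | None = None
    fdr_n3: float | None = None


@dataclass
class CorrelationRecord:
    metabolite_a: str
    metabolite_b: str
    r: float
    p: float


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def auroc(values, labels) -> float:
    """Orientation-free AUROC by pairwise concordance (ties count ½).

    Computed from the rank-sum statistic: with ranks R over the pooled
    sample, A = (ΣR₁ − n₁(n₁+1)/2) / (n₁n₂); returns max(A, 1−A).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise UnivariateError("degenerate labels: need exactly two non-empty classes")
    mask1 = labels == classes[0]
    n1, n2 = int(mask1.sum()), int((~mask1).sum())
    ranks = sps.rankdata(values)
    a = (ranks[mask1].sum() - n1 * (n1 + 1) / 2) / (n1 * n2)
    return float(max(a, 1.0 - a))


def _auroc_matrix(X: np.ndarray, pos_mask: np.ndarray) -> np.ndarray:
    """Row-wise orientation-free AUROC for a models × samples score matrix."""
    n1 = int(pos_mask.sum())
    n2 = X.shape[1] - n1
    ranks = sps.rankdata(X, axis=1)
    a = (ranks[:, pos_mask].sum(axis=1) - n1 * (n1 + 1) / 2) / (n1 * n2)
    return np.maximum(a, 1.0 - a)


# ---------------------------------------------------------------------------
# Paired change test with normality routing
# ---------------------------------------------------------------------------

_AD_LEVELS = np.array([15.0, 10.0, 5.0, 2.5, 1.0])  # % levels scipy reports


def _anderson_normal(x: np.ndarray, alpha: float) -> bool:
    """True when the Anderson–Darling test does NOT reject normality at
    ``alpha`` (interpolated p-value where scipy provides it, otherwise the
    tabulated critical value closest to ``alpha``)."""
    try:
        res = sps.anderson(x, dist="norm", method="interpolate")
        return bool(res.pvalue >= alpha)
    except TypeError:  # older scipy without the method parameter
        res = sps.anderson(x, dist="norm")
        idx = int(np.argmin(np.abs(_AD_LEVELS - alpha * 100)))
        return bool(res.statistic < res.critical_values[idx])


def paired_change_test(week0, week18, normality_alpha: float = 0.05) -> tuple[float, str]:
    """Two-sided paired test of change, routed by normality at both weeks.

    Returns ``(p, test_used)`` with ``test_used`` in ``{"paired_t",
    "wilcoxon", "degenerate"}``.  All-zero differences give p = 1.0.
    """
    w0 = np.asarray(week0, dtype=float)
    w18 = np.asarray(week18, dtype=float)
    if w0.shape != w18.shape:
        raise UnivariateError("paired vectors must have equal length")
    if len(w0) < 4:
        raise UnivariateError("insufficient samples: need n >= 4 pairs")
    diffs = w18 - w0
    if np.all(diffs == 0):
        return 1.0, "degenerate"

    normal = _anderson_normal(w0, normality_alpha) and _anderson_normal(w18, normality_alpha)
    if normal:
        p = sps.ttest_rel(w18, w0).pvalue
        return float(p), "paired_t"
    # signed-rank convention: drop zero differences; exact null for small n,
    # continuity-corrected normal approximation otherwise
    nz = diffs[diffs != 0]
    method = "exact" if len(nz) <= 25 else "approx"
    try:
        res = sps.wilcoxon(w18, w0, zero_method="wilcox", alternative="two-sided",
                           correction=True, method=method)
    except ValueError:
        res = sps.wilcoxon(w18, w0, zero_method="wilcox", alternative="two-sided",
                           correction=True, method="approx")
    return float(res.pvalue), "wilcoxon"


def leave_n_out_fdr(week0, week18, n: int, alpha: float = 0.05,
                    normality_alpha: float = 0.05, max_subsets: int = 20000,
                    seed: int = 0) -> float:
    """Proportion of leave-n-out subject subsets whose rerun change test is
    non-significant (p ≥ alpha).

    All C(N, n) subsets are enumerated when that count is at most
    ``max_subsets``; otherwise a seeded uniform subsample of subsets is
    used.
    """
    w0 = np.asarray(week0, dtype=float)
    w18 = np.asarray(week18, dtype=float)
    N = len(w0)
    if N - n < 4:
        raise UnivariateError("insufficient samples: N - n must be >= 4")
    total = comb(N, n)
    if total <= max_subsets:
        drops = combinations(range(N), n)
        count = total
    else:
        rng = np.random.default_rng(seed)
        drops = (tuple(np.sort(rng.choice(N, size=n, replace=False)))
                 for _ in range(max_subsets))
        count = max_subsets
    keep_all = np.ones(N, dtype=bool)
    n_nonsig = 0
    for drop in drops:
        keep = keep_all.copy()
        keep[list(drop)] = False
        p, _ = paired_change_test(w0[keep], w18[keep], normality_alpha)
        if p >= alpha:
            n_nonsig += 1
    return n_nonsig / count


# ---------------------------------------------------------------------------
# Screening and change analysis over a dataset
# ---------------------------------------------------------------------------

def screen_candidates(dataset: StudyDataset, threshold: float = 0.6) -> list[UnivariateResult]:
    """Week-0 AUROC per metabolite; keep those strictly above ``threshold``.

    Sorted by AUROC descending, ties broken by metabolite id.  Week-18
    AUROC (treated week-18 vs control week-0) is filled in when follow-up
    samples exist.
    """
    week0 = dataset.select(week=0)
    labels = week0.labels
    X = week0.values.to_numpy(dtype=float)
    pos = labels == "ASD"
    if pos.all() or not pos.any():
        raise UnivariateError("degenerate labels: need both cohorts at week 0")
    a0 = _auroc_matrix(X.T, pos)

    a18 = None
    try:
        asd18 = dataset.select(cohort="ASD", week=18)
        td0 = dataset.select(cohort="TD", week=0)
        X18 = np.vstack([asd18.values.to_numpy(float), td0.values.to_numpy(float)])
        pos18 = np.arange(X18.shape[0]) < asd18.n
        a18 = _auroc_matrix(X18.T, pos18)
    except Exception:
        pass

    results = []
    for j, met in enumerate(dataset.metabolite_ids):
        if a0[j] > threshold:
            results.append(UnivariateResult(
                metabolite=met,
                auroc_week0=float(a0[j]),
                auroc_week18=float(a18[j]) if a18 is not None else None,
            ))
    results.sort(key=lambda r: (-r.auroc_week0, r.metabolite))
    return results


def change_tests(dataset: StudyDataset, results: list[UnivariateResult],
                 alpha: float = 0.05, fdr_ns: tuple[int, ...] = (1, 2, 3),
                 normality_alpha: float = 0.05) -> list[UnivariateResult]:
    """Fill pre/post change p-values and leave-n-out FDRs in place.

    Pairs treated-cohort week-0 and week-18 samples by subject.
    """
    asd0 = dataset.select(cohort="ASD", week=0)
    asd18 = dataset.select(cohort="ASD", week=18)
    id0 = {s: i for s, i in zip(asd0.meta["subject_id"], asd0.sample_ids)}
    id18 = {s: i for s, i in zip(asd18.meta["subject_id"], asd18.sample_ids)}
    subjects = [s for s in id0 if s in id18]
    rows0 = [id0[s] for s in subjects]
    rows18 = [id18[s] for s in subjects]
    for res in results:
        w0 = dataset.values.loc[rows0, res.metabolite].to_numpy(float)
        w18 = dataset.values.loc[rows18, res.metabolite].to_numpy(float)
        res.change_p, res.test_used = paired_change_test(w0, w18, normality_alpha)
        for n in fdr_ns:
            fdr = leave_n_out_fdr(w0, w18, n, alpha=alpha, normality_alpha=normality_alpha)
            setattr(res, f"fdr_n{n}", fdr)
    return results


def results_table(results: list[UnivariateResult]) -> pd.DataFrame:
    """Ranked results in the layout of the published candidate table."""
    return pd.DataFrame({
        "rank": np.arange(1, len(results) + 1),
        "metabolite": [r.metabolite for r in results],
        "auroc_week0": [r.auroc_week0 for r in results],
        "auroc_week18": [r.auroc_week18 for r in results],
        "change_p": [r.change_p for r in results],
        "test_used": [r.test_used for r in results],
        "fdr_n1": [r.fdr_n1 for r in results],
        "fdr_n2": [r.fdr_n2 for r in results],
        "fdr_n3": [r.fdr_n3 for r in results],
    })


# ---------------------------------------------------------------------------
# Correlation panel
# ---------------------------------------------------------------------------

def correlation_panel(dataset: StudyDataset, panel: list[str], comparators: list[str],
                      alpha: float = 0.05) -> list[CorrelationRecord]:
    """Pearson correlations between panel and comparator metabolites over
    the pooled week-0 samples; records with two-sided p < alpha only.

    p-values use the t transform on n − 2 degrees of freedom.  Pairs with a
    zero-variance member are skipped with a warning.
    """
    week0 = dataset.select(week=0).values
    records = []
    for a in panel:
        xa = week0[a].to_numpy(float)
        for b in comparators:
            xb = week0[b].to_numpy(float)
            if np.std(xa) == 0 or np.std(xb) == 0:
                warnings.warn(f"zero-variance metabolite in pair ({a}, {b}); skipped")
                continue
            r, p = sps.pearsonr(xa, xb)
            if p < alpha:
                records.append(CorrelationRecord(a, b, float(r), float(p)))
    return records


def pearson_p(r: float, n: int) -> float:
    """Closed-form two-sided p for a Pearson r at sample size n."""
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(t, n - 2))
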