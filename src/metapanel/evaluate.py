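"""Longitudinal evaluation of a fitted panel across treatment weeks.

After the discriminant panel and its week-0 threshold are frozen, the
treated cohort's follow-up samples (weeks 3, 10, 18 — scaled by the same
control week-0 factors) are projected onto the discriminant axis.  Per
week the positive-class score density is re-fitted and the Type II error
is the mass of that week's density below the fixed week-0 threshold: a
cohort drifting toward the controls pushes mass below the threshold and
the Type II error rises from its initial β.

A complementary per-sample *deviation score* summarizes raw metabolite
displacement from the control cohort:

    D_i = Σ_m |x_{i,m} − median_TD(m)| / σ_TD(m),

summed over the panel metabolites, with median and σ taken from the
control week-0 reference.  Medians and quartiles of D per week quantify
how far the treated cohort sits from the controls, and by how much that
gap closes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import StudyDataset, WEEKS
from .fda import Density, FdaModel, ThresholdSpec, fit_kde, project
from .preprocess import ReferenceStats


class EvaluationError(ValueError):
    pass


def deviation_score(X, stats: ReferenceStats, panel: list[str]) -> np.ndarray:
    """Per-sample summed TD-referenced deviation over the panel.

    ``X`` is a samples × panel DataFrame (or array in panel column order).
    """
    med = stats.median[panel].to_numpy(dtype=float)
    sd = stats.sd[panel].to_numpy(dtype=float)
    if np.any(sd == 0) or np.any(~np.isfinite(sd)):
        raise EvaluationError("degenerate reference spread")
    if isinstance(X, pd.DataFrame):
        X = X[panel].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    return (np.abs(X - med) / sd).sum(axis=1)


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    """(median, q25, q75) with the inclusive linear-interpolation rule."""
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return float(q50), float(q25), float(q75)


@dataclass
class WeekSummary:
    week: int
    scores: np.ndarray
    density: Density | None
    type2_error: float | None
    deviation: np.ndarray
    deviation_quartiles: tuple[float, float, float]
    per_metabolite: pd.DataFrame = field(repr=False)


@dataclass
class TrajectoryReport:
    panel: tuple[str, ...]
    threshold: ThresholdSpec
    weeks: dict[int, WeekSummary]
    td_reference: WeekSummary

    def type2_by_week(self) -> dict[int, float]:
        return {w: s.type2_error for w, s in self.weeks.items()}

    def to_frame(self) -> pd.DataFrame:
        """Table with per-metabolite deviation rows, a panel row, and the
        per-week Type II error, mirroring the published layout."""
        weeks = sorted(self.weeks)
        rows = []
        for m in self.panel:
            row = {"quantity": m}
            for w in weeks:
                pm = self.weeks[w].per_metabolite
                r = pm.loc[pm["metabolite"] == m].iloc[0]
                row[f"ASD_week{w}"] = f"{r['median']:.2f} ({r['q25']:.2f}, {r['q75']:.2f})"
            tdr = self.td_reference.per_metabolite
            r = tdr.loc[tdr["metabolite"] == m].iloc[0]
            row["TD_week0"] = f"{r['median']:.2f} ({r['q25']:.2f}, {r['q75']:.2f})"
            rows.append(row)
        row = {"quantity": "panel deviation score"}
        for w in weeks:
            m, lo, hi = self.weeks[w].deviation_quartiles
            row[f"ASD_week{w}"] = f"{m:.2f} ({lo:.2f}, {hi:.2f})"
        m, lo, hi = self.td_reference.deviation_quartiles
        row["TD_week0"] = f"{m:.2f} ({lo:.2f}, {hi:.2f})"
        rows.append(row)
        row = {"quantity": "type II error"}
        for w in weeks:
            row[f"ASD_week{w}"] = f"{100 * self.weeks[w].type2_error:.0f}%"
        row["TD_week0"] = "-"
        rows.append(row)
        return pd.DataFrame(rows)


def _week_summary(week: int, X: pd.DataFrame, panel: list[str],
                  stats: ReferenceStats, model: FdaModel | None,
                  threshold: ThresholdSpec | None) -> WeekSummary:
    dev = deviation_score(X, stats, panel)
    per_term = np.abs(X[panel].to_numpy(float) - stats.median[panel].to_numpy(float)) \
        / stats.sd[panel].to_numpy(float)
    per_met = pd.DataFrame({
        "metabolite": panel,
        "median": np.percentile(per_term, 50, axis=0),
        "q25": np.percentile(per_term, 25, axis=0),
        "q75": np.percentile(per_term, 75, axis=0),
    })
    scores = np.array([])
    density = None
    type2 = None
    if model is not None:
        scores = project(model, X[list(model.metabolites)])
        density = fit_kde(scores)
        if threshold is not None:
            type2 = float(density.cdf(threshold.threshold))
    return WeekSummary(week=week, scores=scores, density=density,
                       type2_error=type2, deviation=dev,
                       deviation_quartiles=_quartiles(dev), per_metabolite=per_met)


def score_trajectory(model: FdaModel, dataset: StudyDataset, stats: ReferenceStats,
                     threshold: ThresholdSpec,
                     weeks: tuple[int, ...] = WEEKS) -> TrajectoryReport:
    """Evaluate the frozen panel and threshold across study weeks.

    The threshold stays fixed at its week-0 value; only the treated
    cohort's score density is re-fitted per week.  Weeks with no samples
    are omitted with a warning.
    """
    import warnings

    panel = list(model.metabolites)
    summaries: dict[int, WeekSummary] = {}
    for w in weeks:
        try:
            view = dataset.select(cohort="ASD", week=w)
        except Exception:
            warnings.warn(f"week {w} missing; omitted from trajectory")
            continue
        summaries[w] = _week_summary(w, view.values, panel, stats, model, threshold)
    if not summaries:
        raise EvaluationError("no treated samples in any requested week")
    td = dataset.select(cohort="TD", week=0)
    td_summary = _week_summary(0, td.values, panel, stats, model, None)
    return TrajectoryReport(panel=tuple(panel), threshold=threshold,
                            weeks=summaries, td_reference=td_summary)


# ---------------------------------------------------------------------------
# Shift summaries over univariate results
# ---------------------------------------------------------------------------

def shift_summary(records: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Summaries of how a ranked metabolite set shifted after treatment.

    ``records`` needs columns ``auroc_week0``, ``auroc_week18`` and
    ``change_p`` (NaN = not significant / not reported).  Returns percent
    of the set with a significant pre/post change, and the count/percent
    whose week-18 AUROC is strictly below week 0.
    """
    if len(records) == 0:
        raise EvaluationError("nothing to summarize")
    n = len(records)
    p = pd.to_numeric(records["change_p"], errors="coerce")
    n_sig = int((p < alpha).sum())
    lower = records["auroc_week18"] < records["auroc_week0"]
    n_lower = int(lower.sum())
    return {
        "n": n,
        "n_significant": n_sig,
        "pct_significant": 100.0 * n_sig / n,
        "n_lower_auroc": n_lower,
        "pct_lower_auroc": 100.0 * n_lower / n,
    }


def percent_reduction(dev_w0: float, dev_w18: float, td_ref: float = 0.0,
                      method: str = "raw") -> float:
    """Percent decrease of a treated-vs-control gap between two weeks.

    Methods (the field reports such reductions in several natural ways, so
    the choice is explicit in the output of any caller):

    * ``raw`` — 100 · (dev_w0 − dev_w18) / dev_w0
    * ``excess`` — same, after subtracting the control-cohort reference
      level ``td_ref`` from both weeks (reduction of the *excess* gap)
    """
    if method == "raw":
        return 100.0 * (dev_w0 - dev_w18) / dev_w0
    if method == "excess":
        return 100.0 * ((dev_w0 - td_ref) - (dev_w18 - td_ref)) / (dev_w0 - td_ref)
    raise EvaluationError(f"unknown method {method!r}")
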