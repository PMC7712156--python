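"""Preprocessing: detection-limit retention, imputation, reference scaling.

Three steps, applied impute → filter → normalize:

1. **Imputation** — each missing cell of a metabolite is replaced by the
   minimum observed value of that metabolite divided by √2, the standard
   below-detection-limit convention for vendor-integrated abundances.
2. **Detection-limit filter** — a metabolite is retained only if at least
   ``floor(min_fraction × N)`` of its N week-0 measurements lie strictly
   above its detection limit (the minimum recorded value).  At the default
   40% and the design size N = 38 the qualifying count is 15.
3. **Reference normalization** — every metabolite is divided by its control
   (TD) week-0 median, so the TD week-0 median is exactly 1.0; the same
   per-metabolite factors apply to all weeks.  The post-scaling TD median
   and standard deviation are kept as :class:`ReferenceStats` for the
   downstream deviation score.

Because imputed values (min/√2) sit strictly below the observed minimum,
they never count as above the detection limit and steps 1 and 2 commute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import CohortView, StudyDataset

SQRT2 = np.sqrt(2.0)


class PreprocessError(ValueError):
    pass


@dataclass
class ReferenceStats:
    """Per-metabolite TD week-0 median and standard deviation (post-scaling
    units, so ``median`` is 1.0 for every retained metabolite), plus the raw
    scale factors that were divided out."""

    metabolites: list[str]
    median: pd.Series          # post-scaling TD week-0 median (== 1.0)
    sd: pd.Series              # post-scaling TD week-0 sample sd (ddof=1)
    scale: pd.Series           # raw TD week-0 median divided out of each column


@dataclass
class PreprocessReport:
    """Outcome of the detection-limit filter."""

    retained: list[str]
    removed: list[str]
    above_limit_counts: pd.Series
    qualifying_count: int      # floor(min_fraction × N)
    n_samples: int
    min_fraction: float

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.above_limit_counts.index)
        return pd.DataFrame({
            "metabolite": ids,
            "above_detection_limit": self.above_limit_counts.values,
            "retained": [m in set(self.retained) for m in ids],
        })


def impute_missing(dataset: StudyDataset) -> StudyDataset:
    """Fill each missing cell with min_observed(metabolite) / √2."""
    values = dataset.values.copy()
    mins = values.min(axis=0, skipna=True)
    fully_missing = mins.index[mins.isna()]
    if len(fully_missing):
        raise PreprocessError(f"no observed values: {list(fully_missing)[:5]}")
    fill = mins / SQRT2
    return dataset.with_values(values.fillna(fill))


def _above_limit_counts(week0_values: pd.DataFrame) -> pd.Series:
    """Count week-0 measurements strictly above each metabolite's detection
    limit.

    The limit is the minimum recorded value.  For a metabolite with missing
    (censored) cells the recorded minimum after standard min/√2 imputation
    is min_observed/√2, so every observed cell is above the limit; for a
    fully observed metabolite, ties at the minimum are at (not above) the
    limit.  Computing the count this way makes the filter commute with
    imputation.
    """
    arr = week0_values.to_numpy(dtype=float)
    has_missing = np.isnan(arr).any(axis=0)
    with np.errstate(all="ignore"):
        col_min = np.nanmin(arr, axis=0)
    n_observed = (~np.isnan(arr)).sum(axis=0)
    strictly_above = (arr > col_min).sum(axis=0)
    counts = np.where(has_missing, n_observed, strictly_above)
    return pd.Series(counts, index=week0_values.columns, dtype=int)


def filter_detection_limit(dataset: StudyDataset, min_fraction: float = 0.4) -> PreprocessReport:
    """Apply the week-0 detection-limit retention rule.

    A metabolite is retained iff its above-limit count over the N week-0
    samples (both cohorts) is ≥ floor(min_fraction × N).
    """
    week0 = dataset.select(week=0)
    n = week0.n
    if n == 0:
        raise PreprocessError("empty cohort")
    counts = _above_limit_counts(week0.values)
    qualifying = int(np.floor(min_fraction * n))
    keep = counts >= qualifying
    return PreprocessReport(
        retained=list(counts.index[keep]),
        removed=list(counts.index[~keep]),
        above_limit_counts=counts,
        qualifying_count=qualifying,
        n_samples=n,
        min_fraction=min_fraction,
    )


def apply_filter(dataset: StudyDataset, report: PreprocessReport) -> StudyDataset:
    """Drop removed metabolites, preserving column order."""
    keep = [m for m in dataset.metabolite_ids if m in set(report.retained)]
    return dataset.with_values(dataset.values[keep])


def normalize_to_reference(dataset: StudyDataset,
                           reference: CohortView) -> tuple[StudyDataset, ReferenceStats]:
    """Divide every metabolite by its reference-cohort (TD week-0) median.

    The same scale factor applies to all weeks, so follow-up samples are on
    the reference scale too.  Requires strictly positive reference medians.
    """
    ref_values = reference.values[dataset.metabolite_ids]
    scale = ref_values.median(axis=0, skipna=True)
    bad = scale.index[~(scale > 0) | scale.isna()]
    if len(bad):
        raise PreprocessError(f"degenerate reference: non-positive median for {list(bad)[:5]}")
    scaled = dataset.with_values(dataset.values / scale)
    ref_scaled = ref_values / scale
    stats = ReferenceStats(
        metabolites=dataset.metabolite_ids,
        median=ref_scaled.median(axis=0, skipna=True),
        sd=ref_scaled.std(axis=0, ddof=1, skipna=True),
        scale=scale,
    )
    return scaled, stats


def preprocess(dataset: StudyDataset, min_fraction: float = 0.4,
               impute: bool = True) -> tuple[StudyDataset, ReferenceStats, PreprocessReport]:
    """Run the full impute → filter → normalize chain.

    ``impute=False`` supports tables whose missing cells were already
    replaced upstream (vendor-side imputation).
    """
    work = impute_missing(dataset) if impute else dataset
    report = filter_detection_limit(work, min_fraction=min_fraction)
    work = apply_filter(work, report)
    scaled, stats = normalize_to_reference(work, work.select(cohort="TD", week=0))
    return scaled, stats, report
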