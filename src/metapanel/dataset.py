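"""Containers and IO for longitudinal two-cohort metabolomics tables.

The universal currency of the pipeline is a :class:`StudyDataset`: a wide
sample × metabolite matrix of non-negative relative abundances (``NaN``
marks below-detection / missing cells — deliberately distinct from zero)
plus per-sample metadata (subject, cohort, study week).  The treated (ASD)
cohort is sampled at weeks 0, 3, 10 and 18; the control (TD) cohort only at
week 0.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COHORTS = ("ASD", "TD")
WEEKS = (0, 3, 10, 18)

META_COLUMNS = ("subject_id", "cohort", "week")


class StudyDataError(ValueError):
    """Raised when a table violates the study-design invariants."""


@dataclass
class StudyDataset:
    """Sample × metabolite abundance matrix with aligned sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, one column per metabolite, float
        dtype.  ``NaN`` is the explicit missing marker (below detection
        limit); all present values must be ≥ 0.
    meta
        DataFrame indexed by sample id with columns ``subject_id``,
        ``cohort`` (``"ASD"`` or ``"TD"``) and ``week`` (0, 3, 10 or 18).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.meta = self.meta.copy()
        _validate(self.values, self.meta)
        self.meta["week"] = self.meta["week"].astype(int)

    # -- basic views ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame) -> "StudyDataset":
        """Return a new dataset with the same metadata and new values."""
        return StudyDataset(values=values, meta=self.meta)

    def select(self, cohort: str = "all", week: int | str = "all") -> "CohortView":
        """Select samples by cohort and/or week (``"all"`` = no filter)."""
        return select(self, cohort=cohort, week=week)


def _validate(values: pd.DataFrame, meta: pd.DataFrame) -> None:
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise StudyDataError(f"invalid metadata: missing columns {missing_cols}")
    if set(values.index) != set(meta.index):
        raise StudyDataError("invalid metadata: sample ids do not match value rows")
    if len(values) != len(meta):
        raise StudyDataError("invalid metadata: row count mismatch")

    bad_cohort = set(meta["cohort"]) - set(COHORTS)
    if bad_cohort:
        raise StudyDataError(f"invalid metadata: unknown cohort {sorted(bad_cohort)}")
    weeks = pd.to_numeric(meta["week"], errors="coerce")
    if weeks.isna().any() or not set(weeks.astype(int)) <= set(WEEKS):
        raise StudyDataError("invalid metadata: unknown week")

    dup = meta.duplicated(subset=["subject_id", "week"])
    if dup.any():
        offender = meta.index[dup][0]
        raise StudyDataError(f"duplicate sample: {offender}")

    td_late = (meta["cohort"] == "TD") & (weeks.astype(int) != 0)
    if td_late.any():
        raise StudyDataError("invalid metadata: TD samples only exist at week 0")

    arr = values.to_numpy(dtype=float)
    if np.nanmin(arr, initial=0.0) < 0:
        raise StudyDataError("invalid value: negative abundance")


@dataclass
class CohortView:
    """A (cohort, week) selection of a :class:`StudyDataset`.

    Holds a reference to the parent dataset plus the selected sample ids;
    metabolite columns are never copied or reordered.
    """

    dataset: StudyDataset
    cohort: str
    week: int | str
    sample_ids: list[str] = field(repr=False)

    @property
    def values(self) -> pd.DataFrame:
        return self.dataset.values.loc[self.sample_ids]

    @property
    def meta(self) -> pd.DataFrame:
        return self.dataset.meta.loc[self.sample_ids]

    @property
    def labels(self) -> np.ndarray:
        return self.meta["cohort"].to_numpy()

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_k(self) -> dict[str, int]:
        """Sample count per cohort class within the selection."""
        return self.meta["cohort"].value_counts().to_dict()

    @property
    def K(self) -> int:
        return len(self.n_k)


def select(dataset: StudyDataset, cohort: str = "all", week: int | str = "all") -> CohortView:
    """Select samples by cohort and/or week.

    Raises ``StudyDataError("empty cohort")`` when nothing matches.
    """
    mask = pd.Series(True, index=dataset.meta.index)
    if cohort != "all":
        if cohort not in COHORTS:
            raise StudyDataError(f"invalid metadata: unknown cohort {cohort!r}")
        mask &= dataset.meta["cohort"] == cohort
    if week != "all":
        week = int(week)
        if week not in WEEKS:
            raise StudyDataError(f"invalid metadata: unknown week {week!r}")
        mask &= dataset.meta["week"] == week
    ids = list(dataset.meta.index[mask])
    if not ids:
        raise StudyDataError("empty cohort")
    return CohortView(dataset=dataset, cohort=cohort, week=week, sample_ids=ids)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _sep_for(path: str | os.PathLike, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_study(values_path, meta_path, sep: str | None = None) -> StudyDataset:
    """Read a wide abundance table and its sample metadata.

    The abundance table has a leading ``sample_id`` column and one column
    per metabolite; empty cells parse to the missing marker.  The metadata
    table has columns ``sample_id, subject_id, cohort, week``.  Delimiter is
    auto-detected from the extension (``.tsv``/``.tab``/``.txt`` → tab,
    otherwise comma) unless ``sep`` is given.
    """
    values = pd.read_csv(values_path, sep=_sep_for(values_path, sep), index_col=0)
    meta = pd.read_csv(meta_path, sep=_sep_for(meta_path, sep), index_col=0)
    values.index = values.index.astype(str)
    meta.index = meta.index.astype(str)
    values.index.name = None
    meta.index.name = None
    # order metadata rows to match the value matrix
    if set(values.index) == set(meta.index):
        meta = meta.loc[values.index]
    return StudyDataset(values=values, meta=meta)


def read_study_long(path, sep: str | None = None) -> StudyDataset:
    """Read a long-format table (sample_id, subject_id, cohort, week,
    metabolite, value) and convert immediately to the wide canonical form."""
    long = pd.read_csv(path, sep=_sep_for(path, sep))
    values = long.pivot(index="sample_id", columns="metabolite", values="value")
    values.columns.name = None
    meta = (
        long[["sample_id", "subject_id", "cohort", "week"]]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
    )
    return StudyDataset(values=values, meta=meta.loc[values.index])


def write_study(dataset: StudyDataset, values_path, meta_path, sep: str | None = None) -> None:
    """Write a dataset back to a pair of tables (round-trips exactly)."""
    dataset.values.to_csv(values_path, sep=_sep_for(values_path, sep), index_label="sample_id")
    dataset.meta.to_csv(meta_path, sep=_sep_for(meta_path, sep), index_label="sample_id")
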