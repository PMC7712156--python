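"""Machine-readable copies of the published summary tables.

These ship with the package as TSV fixtures: the top-50 univariate
candidate table (week-0 and week-18 AUROC plus pre/post change p-values),
the panel correlation table, and the longitudinal deviation-score /
Type II error table for the two optimal five-metabolite panels (OFM-I and
OFM-A, which share four metabolites and differ in indole vs adenosine).
They serve as reference inputs for shift summaries and consistency checks;
participant-level data were never deposited, so these summaries are the
only published ground truth.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: the two tied optimal five-metabolite panels
OFM_I = ("Imidazole Propionate", "Hydroxyproline", "Theobromine",
         "2-hydroxy-3-methylvalerate", "Indole")
OFM_A = ("Imidazole Propionate", "Hydroxyproline", "Theobromine",
         "2-hydroxy-3-methylvalerate", "Adenosine")

#: week-0 sample sizes of the study design
N_ASD, N_TD = 18, 20


def _read(name: str) -> pd.DataFrame:
    with resources.files("metapanel.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_top50() -> pd.DataFrame:
    """Top-50 candidate metabolites: rank, AUROC at weeks 0/18, change p."""
    return _read("table1_top50.tsv")


def load_correlations() -> pd.DataFrame:
    """Published significant Pearson correlations with the panel
    metabolites (``p_censored`` marks values printed as "<0.001")."""
    return _read("table3_correlations.tsv")


def load_trajectory() -> pd.DataFrame:
    """Published per-week deviation-score quartiles and Type II errors for
    the OFM-I/A panels (long format: quantity, stat, per-week columns)."""
    return _read("table4_trajectory.tsv")
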