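import numpy as np
import pandas as pd
import pytest

from metapanel import StudyDataset, generate_study, preprocess
from metapanel.simulate import SimulationConfig


def make_dataset(values: np.ndarray, cohorts, weeks=None, subjects=None,
                 metabolites=None) -> StudyDataset:
    """Build a small StudyDataset from an array and per-sample labels."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    weeks = weeks if weeks is not None else [0] * n
    subjects = subjects if subjects is not None else [f"S{i}" for i in range(n)]
    metabolites = metabolites if metabolites is not None else [f"M{j}" for j in range(p)]
    ids = [f"{s}_w{w}" for s, w in zip(subjects, weeks)]
    vals = pd.DataFrame(values, index=ids, columns=metabolites)
    meta = pd.DataFrame({"subject_id": subjects, "cohort": cohorts, "week": weeks},
                        index=ids)
    return StudyDataset(values=vals, meta=meta)


def week0_dataset(n_asd, n_td, p, rng, asd_shift=0.0):
    """Random week-0-only two-cohort dataset."""
    values = np.exp(rng.standard_normal((n_asd + n_td, p)))
    values[:n_asd] *= np.exp(asd_shift)
    cohorts = ["ASD"] * n_asd + ["TD"] * n_td
    return make_dataset(values, cohorts)


@pytest.fixture(scope="session")
def sim_study():
    """A default-sized synthetic study shared by read-only tests."""
    return generate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_study():
    """A small planted study, preprocessed, shared by read-only tests."""
    dataset, truth = generate_study(
        SimulationConfig(seed=5, n_metabolites=120, n_discriminating=10,
                         effect_size=2.0))
    scaled, stats, report = preprocess(dataset)
    return {"dataset": dataset, "truth": truth, "scaled": scaled,
            "stats": stats, "report": report}
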