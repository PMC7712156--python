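"""Synthetic longitudinal two-cohort metabolomics study generator.

Emulates the design the pipeline targets: 18 treated (ASD) and 20 control
(TD) children, 669 metabolites measured at week 0, ASD-only follow-up at
weeks 3 (one subject missing), 10 and 18.  Abundances are log-normal with
block-equicorrelated log-scale noise, a planted minority of discriminating
metabolites shifted in the ASD cohort, bottom-quantile (detection-limit
style) censoring, and a responder/non-responder treatment mixture that
moves ASD log-values toward the TD mean on a per-week recovery schedule —
producing the bimodal late-week discriminant-score distributions seen in
real intervention data.

Ground truth (which metabolites discriminate, with what signed effect, and
which subjects respond) is returned alongside the data so recovery can be
tested end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataset import StudyDataset, write_study


class SimulationConfigError(ValueError):
    """Raised for out-of-range generator parameters."""


#: default fraction of the ASD–TD log-mean gap closed at each follow-up week
DEFAULT_RECOVERY_RESPONDER = {3: 0.4, 10: 0.7, 18: 0.8}
DEFAULT_RECOVERY_NONRESPONDER = {3: 0.0, 10: 0.1, 18: 0.1}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    ``effect_size`` is the standardized log-scale shift planted in each
    discriminating metabolite for the ASD cohort at week 0 (unit log-scale
    variance, so it is a Cohen's-d-like quantity).  ``block_size`` /
    ``block_rho`` control within-block equicorrelation of log-abundances.
    ``censor_fraction`` of the lowest week-0 values per metabolite are set
    missing (below detection limit).  ``responder_fraction`` of ASD
    subjects follow the responder recovery schedule; the rest follow the
    non-responder schedule.  ``temporal_sd`` is the fresh log-scale
    measurement noise added at follow-up weeks.
    """

    n_asd: int = 18
    n_td: int = 20
    n_metabolites: int = 669
    n_discriminating: int = 20
    effect_size: float = 1.5
    block_size: int = 5
    block_rho: float = 0.3
    censor_fraction: float = 0.1
    responder_fraction: float = 0.7
    recovery_responder: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RECOVERY_RESPONDER))
    recovery_nonresponder: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RECOVERY_NONRESPONDER))
    week3_dropout: int = 1
    temporal_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.censor_fraction < 0.4):
            raise SimulationConfigError(
                "invalid simulation config: censor_fraction must be in [0, 0.4)")
        if self.n_discriminating > self.n_metabolites:
            raise SimulationConfigError(
                "invalid simulation config: n_discriminating > n_metabolites")
        for sched in (self.recovery_responder, self.recovery_nonresponder):
            lams = [sched[w] for w in sorted(sched)]
            if any(not (0.0 <= l <= 1.0) for l in lams):
                raise SimulationConfigError(
                    "invalid simulation config: recovery fractions must be in [0, 1]")
            if any(b < a for a, b in zip(lams, lams[1:])):
                raise SimulationConfigError(
                    "invalid simulation config: recovery schedule must be non-decreasing")
        if self.n_asd < 2 or self.n_td < 2:
            raise SimulationConfigError(
                "invalid simulation config: need at least 2 subjects per cohort")
        if not (0.0 <= self.responder_fraction <= 1.0):
            raise SimulationConfigError(
                "invalid simulation config: responder_fraction must be in [0, 1]")
        if not (0.0 <= self.block_rho < 1.0):
            raise SimulationConfigError(
                "invalid simulation config: block_rho must be in [0, 1)")
        if self.week3_dropout < 0 or self.week3_dropout > self.n_asd:
            raise SimulationConfigError("invalid simulation config: week3_dropout")


@dataclass
class GroundTruth:
    """Planted structure of a generated study."""

    effects: dict[str, float]          # discriminating metabolite → signed log-scale shift
    responders: dict[str, bool]        # ASD subject → responder flag

    @property
    def discriminating(self) -> list[str]:
        return sorted(self.effects)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"effects": self.effects, "responders": self.responders}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(effects=d["effects"], responders=d["responders"])


def _block_noise(rng: np.random.Generator, n: int, p: int,
                 block_size: int, rho: float) -> np.ndarray:
    """n × p standard-normal noise with equicorrelation rho inside
    consecutive blocks of ``block_size`` metabolites."""
    eps = rng.standard_normal((n, p))
    if rho <= 0 or block_size <= 1:
        return eps
    n_blocks = int(np.ceil(p / block_size))
    shared = rng.standard_normal((n, n_blocks))
    block_of = np.minimum(np.arange(p) // block_size, n_blocks - 1)
    return np.sqrt(rho) * shared[:, block_of] + np.sqrt(1.0 - rho) * eps


def generate_study(config: SimulationConfig) -> tuple[StudyDataset, GroundTruth]:
    """Generate a study and its ground truth; deterministic given the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    p = cfg.n_metabolites

    met_ids = [f"M{i + 1:04d}" for i in range(p)]
    asd_subjects = [f"ASD{i + 1:02d}" for i in range(cfg.n_asd)]
    td_subjects = [f"TD{i + 1:02d}" for i in range(cfg.n_td)]

    # per-metabolite base log-mean; unit log-scale variance throughout
    mu = rng.standard_normal(p)

    # planted discriminating metabolites, half shifted up, half down in ASD
    disc_idx = np.sort(rng.choice(p, size=cfg.n_discriminating, replace=False))
    signs = np.where(np.arange(cfg.n_discriminating) % 2 == 0, 1.0, -1.0)
    delta = np.zeros(p)
    delta[disc_idx] = signs * cfg.effect_size

    # responder mixture on subjects (not samples), so bimodality persists
    n_resp = int(round(cfg.responder_fraction * cfg.n_asd))
    resp_idx = rng.choice(cfg.n_asd, size=n_resp, replace=False)
    responder = np.zeros(cfg.n_asd, dtype=bool)
    responder[resp_idx] = True

    # week 0 log-abundances
    log_asd0 = mu + delta + _block_noise(rng, cfg.n_asd, p, cfg.block_size, cfg.block_rho)
    log_td0 = mu + _block_noise(rng, cfg.n_td, p, cfg.block_size, cfg.block_rho)

    rows: list[np.ndarray] = []
    index: list[str] = []
    meta_rows: list[dict] = []

    def add(sample_id, subject, cohort, week, logvals):
        index.append(sample_id)
        meta_rows.append({"subject_id": subject, "cohort": cohort, "week": week})
        rows.append(np.exp(logvals))

    for i, subj in enumerate(asd_subjects):
        add(f"{subj}_w0", subj, "ASD", 0, log_asd0[i])
    for i, subj in enumerate(td_subjects):
        add(f"{subj}_w0", subj, "TD", 0, log_td0[i])

    # follow-up: move each ASD subject's log-values toward the TD mean by
    # the fraction of the planted gap its schedule closes at that week
    dropout = set(rng.choice(cfg.n_asd, size=cfg.week3_dropout, replace=False))
    for week in (3, 10, 18):
        noise = rng.standard_normal((cfg.n_asd, p)) * cfg.temporal_sd
        for i, subj in enumerate(asd_subjects):
            if week == 3 and i in dropout:
                continue
            lam = (cfg.recovery_responder if responder[i]
                   else cfg.recovery_nonresponder)[week]
            logv = log_asd0[i] - lam * delta + noise[i]
            add(f"{subj}_w{week}", subj, "ASD", week, logv)

    values = pd.DataFrame(np.vstack(rows), index=index, columns=met_ids)

    # detection-limit censoring: the lowest censor_fraction of week-0 values
    # per metabolite are recorded as missing
    n_w0 = cfg.n_asd + cfg.n_td
    n_censor = int(np.floor(cfg.censor_fraction * n_w0))
    if n_censor > 0:
        w0 = values.iloc[:n_w0].to_numpy()
        order = np.argsort(w0, axis=0, kind="stable")
        for j in range(p):
            w0[order[:n_censor, j], j] = np.nan
        values.iloc[:n_w0] = w0

    meta = pd.DataFrame(meta_rows, index=index)
    dataset = StudyDataset(values=values, meta=meta)
    truth = GroundTruth(
        effects={met_ids[j]: float(delta[j]) for j in disc_idx},
        responders={asd_subjects[i]: bool(responder[i]) for i in range(cfg.n_asd)},
    )
    return dataset, truth


def write_simulation(dataset: StudyDataset, truth: GroundTruth, out_dir,
                     config: SimulationConfig | None = None) -> None:
    """Write the generated study as standard tables plus ground-truth JSON."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    write_study(dataset, os.path.join(out_dir, "values.tsv"),
                os.path.join(out_dir, "meta.tsv"))
    truth.to_json(os.path.join(out_dir, "ground_truth.json"))
    if config is not None:
        with open(os.path.join(out_dir, "sim_config.json"), "w") as fh:
            json.dump(asdict(config), fh, indent=1)
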