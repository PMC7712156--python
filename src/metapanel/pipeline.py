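"""End-to-end pipeline orchestration.

Stages (each independently callable through the library or CLI):
simulate/load → preprocess → univariate screen → exhaustive search +
augmentation → leave-one-out cross-validation → longitudinal evaluation.
All artifacts are plain TSV/JSON; a run manifest records the full config,
seed and library versions so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import StudyDataset, read_study
from .evaluate import score_trajectory
from .fda import fit_fda, fit_kde, project, threshold_at_beta
from .preprocess import preprocess
from .search import (DEFAULT_BETAS, appearance_frequency, records_table,
                     search_pipeline)
from .simulate import SimulationConfig, generate_study, write_simulation
from .univariate import change_tests, results_table, screen_candidates

log = logging.getLogger("metapanel")


@dataclass
class PipelineConfig:
    """Configuration shared by all pipeline stages."""

    values_path: str | None = None
    meta_path: str | None = None
    simulate: dict | None = None          # SimulationConfig fields, or None
    min_fraction: float = 0.4
    impute: bool = True
    auroc_threshold: float = 0.6
    ks: tuple[int, ...] = (2, 3, 4)
    top_n: int = 1000
    cv_top_n: int = 1000
    candidate_cap: int | None = None      # keep only the top-N candidates by AUROC
    max_combinations: int | None = None
    betas: tuple[float, ...] = DEFAULT_BETAS
    selection_beta: float = 0.05
    change_test_top: int = 50             # candidates given pre/post change tests
    fdr_ns: tuple[int, ...] = (1,)
    seed: int = 0
    out_dir: str = "metapanel_out"

    def __post_init__(self) -> None:
        self.ks = tuple(int(k) for k in self.ks)
        self.betas = tuple(float(b) for b in self.betas)
        if not (0 < self.min_fraction < 1):
            raise ValueError("min_fraction must be in (0, 1)")
        if not (0.5 <= self.auroc_threshold < 1):
            raise ValueError("auroc_threshold must be in [0.5, 1)")
        if self.selection_beta not in self.betas:
            raise ValueError("selection_beta must be one of betas")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) if str(path).endswith((".yaml", ".yml")) \
                else json.load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _substream(seed: int, name: str) -> int:
    """Derive a deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _load_dataset(cfg: PipelineConfig, out: str):
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        sim.setdefault("seed", _substream(cfg.seed, "simulate"))
        sc = SimulationConfig(**sim)
        dataset, truth = generate_study(sc)
        write_simulation(dataset, truth, os.path.join(out, "simulated"), sc)
        log.info("simulated study: %d samples x %d metabolites",
                 dataset.n_samples, dataset.n_metabolites)
        return dataset, truth
    if not cfg.values_path or not cfg.meta_path:
        raise FileNotFoundError("invalid metadata/path: no input tables or simulation config")
    dataset = read_study(cfg.values_path, cfg.meta_path)
    log.info("loaded study: %d samples x %d metabolites",
             dataset.n_samples, dataset.n_metabolites)
    return dataset, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages, writing artifacts under ``cfg.out_dir``.

    Returns a dict of in-memory stage results.  On error a FAILED marker
    naming the stage is left next to any partial outputs.
    """
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    stage = "setup"
    try:
        stage = "load"
        dataset, truth = _load_dataset(cfg, out)

        stage = "preprocess"
        scaled, stats, report = preprocess(dataset, min_fraction=cfg.min_fraction,
                                           impute=cfg.impute)
        report.to_frame().to_csv(os.path.join(out, "preprocess_report.tsv"),
                                 sep="\t", index=False)
        with open(os.path.join(out, "preprocess_report.json"), "w") as fh:
            json.dump({"retained": len(report.retained), "removed": len(report.removed),
                       "qualifying_count": report.qualifying_count,
                       "n_samples": report.n_samples}, fh, indent=1)
        log.info("preprocess: retained %d, removed %d (qualifying count %d of %d)",
                 len(report.retained), len(report.removed),
                 report.qualifying_count, report.n_samples)

        stage = "univariate"
        results = screen_candidates(scaled, threshold=cfg.auroc_threshold)
        if cfg.change_test_top:
            change_tests(scaled, results[:cfg.change_test_top], fdr_ns=cfg.fdr_ns)
        results_table(results).to_csv(os.path.join(out, "univariate.tsv"),
                                      sep="\t", index=False)
        log.info("univariate: %d candidates above AUROC %.2f",
                 len(results), cfg.auroc_threshold)

        stage = "search"
        candidates = [r.metabolite for r in results]
        if cfg.candidate_cap:
            candidates = candidates[:cfg.candidate_cap]
        ks = tuple(k for k in cfg.ks if k <= len(candidates))
        search = search_pipeline(
            scaled, candidates, ks=ks, top_n=cfg.top_n, cv_top_n=cfg.cv_top_n,
            betas=cfg.betas, selection_beta=cfg.selection_beta,
            max_combinations=cfg.max_combinations,
            seed=_substream(cfg.seed, "search"))
        for k, recs in search["by_k"].items():
            records_table(recs).to_csv(os.path.join(out, f"search_k{k}.tsv"),
                                       sep="\t", index=False)
        records_table(search["five"]).to_csv(os.path.join(out, "search_k5.tsv"),
                                             sep="\t", index=False)
        appearance_frequency(search["five"]).rename("frequency").to_csv(
            os.path.join(out, "appearance_frequency.tsv"), sep="\t",
            index_label="metabolite")
        log.info("search: best fitted AUROC %.3f over %d five-metabolite panels",
                 search["five"][0].auroc, len(search["five"]))

        stage = "crossval"
        rows = []
        for rep in search["cv_reports"]:
            for beta, r in rep.rates.items():
                rows.append({"metabolites": "|".join(rep.metabolites), "beta": beta,
                             "tpr": r["tpr"], "tnr": r["tnr"],
                             "balanced_accuracy": rep.balanced_accuracy(beta)})
        pd.DataFrame(rows).to_csv(os.path.join(out, "crossval.tsv"),
                                  sep="\t", index=False)
        best = search["best"][0]
        log.info("crossval: best panel %s (balanced accuracy %.3f at beta %.2f)",
                 best.metabolites, best.balanced_accuracy(cfg.selection_beta),
                 cfg.selection_beta)

        stage = "evaluate"
        week0 = scaled.select(week=0)
        model = fit_fda(week0.values[list(best.metabolites)], week0.labels)
        asd_scores = project(model, scaled.select(cohort="ASD", week=0)
                             .values[list(best.metabolites)])
        density = fit_kde(asd_scores)
        thr = threshold_at_beta(density, cfg.selection_beta)
        trajectory = score_trajectory(model, scaled, stats, thr)
        trajectory.to_frame().to_csv(os.path.join(out, "trajectory.tsv"),
                                     sep="\t", index=False)
        grids = []
        for w, s in trajectory.weeks.items():
            g = s.density.grid()
            g.insert(0, "week", w)
            grids.append(g)
        pd.concat(grids).to_csv(os.path.join(out, "densities.tsv"),
                                sep="\t", index=False)
        log.info("evaluate: type II error by week %s",
                 {w: round(t, 3) for w, t in trajectory.type2_by_week().items()})

        stage = "manifest"
        manifest = {
            "config": cfg.to_dict(),
            "seed": cfg.seed,
            "versions": {"metapanel": __version__, "numpy": np.__version__,
                         "pandas": pd.__version__},
            "config_hash": hashlib.sha256(
                json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest(),
            "stages": {
                "retained_metabolites": len(report.retained),
                "candidates": len(candidates),
                "five_metabolite_panels": len(search["five"]),
                "cv_panels": len(search["cv_reports"]),
                "best_panels": ["|".join(r.metabolites) for r in search["best"]],
            },
        }
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
    except Exception as exc:
        with open(os.path.join(out, "FAILED"), "w") as fh:
            fh.write(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {"dataset": dataset, "truth": truth, "scaled": scaled, "stats": stats,
            "report": report, "univariate": results, "search": search,
            "model": model, "threshold": thr, "trajectory": trajectory,
            "manifest": manifest}
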