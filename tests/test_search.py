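from itertools import combinations

import numpy as np
import pytest

from metapanel import (auroc, augment_to_five, exhaustive_search, fit_fda,
                       loo_cv, project, select_best)
from metapanel.search import SearchError, appearance_frequency, search_pipeline

from conftest import make_dataset, week0_dataset


def naive_search(dataset, candidates, k):
    """Per-subset loop oracle: fit, project, score AUROC."""
    week0 = dataset.select(week=0)
    labels = week0.labels
    out = []
    for subset in combinations(sorted(candidates), k):
        X = week0.values[list(subset)]
        model = fit_fda(X, labels)
        out.append((subset, auroc(project(model, X), labels)))
    return out


def test_counts_c32():
    rng = np.random.default_rng(0)
    ds = week0_dataset(5, 5, 3, rng)
    records = exhaustive_search(ds, ds.metabolite_ids, k=2, top_n=100)
    assert len(records) == 3  # C(3,2)


def test_truncation_noop():
    rng = np.random.default_rng(1)
    ds = week0_dataset(5, 5, 4, rng)
    records = exhaustive_search(ds, ds.metabolite_ids, k=2, top_n=10_000)
    assert len(records) == 6  # C(4,2), all returned sorted
    aurocs = [r.auroc for r in records]
    assert aurocs == sorted(aurocs, reverse=True)


def test_planted_pair_ranks_first():
    rng = np.random.default_rng(2)
    values = np.exp(rng.standard_normal((20, 12)))
    values[:10, 0] *= np.exp(4.0)   # pair that separates perfectly together
    values[:10, 1] *= np.exp(4.0)
    ds = make_dataset(values, ["ASD"] * 10 + ["TD"] * 10)
    records = exhaustive_search(ds, ds.metabolite_ids, k=2, top_n=5)
    assert set(records[0].metabolites) == {"M0", "M1"}
    assert records[0].auroc == 1.0


def test_matches_naive_loop_oracle():
    rng = np.random.default_rng(3)
    ds = week0_dataset(8, 9, 9, rng, asd_shift=0.5)
    for k in (2, 3):
        records = exhaustive_search(ds, ds.metabolite_ids, k=k, top_n=10_000)
        oracle = dict((s, a) for s, a in naive_search(ds, ds.metabolite_ids, k))
        assert len(records) == len(oracle)
        for rec in records:
            assert rec.auroc == pytest.approx(oracle[rec.metabolites], abs=1e-12)
        # ranking is AUROC-descending with deterministic tie-breaks
        keys = [(-r.auroc, -r.J, r.metabolites) for r in records]
        assert keys == sorted(keys)


def test_order_independence_and_rerun_equality():
    rng = np.random.default_rng(4)
    ds = week0_dataset(8, 8, 8, rng, asd_shift=0.4)
    a = exhaustive_search(ds, ds.metabolite_ids, k=3, top_n=20)
    b = exhaustive_search(ds, list(reversed(ds.metabolite_ids)), k=3, top_n=20)
    assert a == b


def test_auroc_monotone_in_k():
    rng = np.random.default_rng(5)
    ds = week0_dataset(10, 10, 8, rng, asd_shift=0.5)
    best = [exhaustive_search(ds, ds.metabolite_ids, k=k, top_n=1)[0].auroc
            for k in (2, 3, 4)]
    assert best[0] <= best[1] + 1e-12 and best[1] <= best[2] + 1e-12


def test_not_enough_candidates():
    rng = np.random.default_rng(6)
    ds = week0_dataset(4, 4, 3, rng)
    with pytest.raises(SearchError, match="not enough candidates"):
        exhaustive_search(ds, ds.metabolite_ids, k=5)


def test_augmentation_arithmetic_and_dedup():
    rng = np.random.default_rng(7)
    ds = week0_dataset(6, 6, 10, rng)
    cands = ds.metabolite_ids
    top4 = exhaustive_search(ds, cands, k=4, top_n=2)
    recs = augment_to_five(ds, top4[:1], cands)
    assert len(recs) == 6      # 10 - 4 remaining candidates
    for rec in recs:
        assert len(set(rec.metabolites)) == 5
    # two parents can generate the same 5-set; dedup keeps each once
    recs2 = augment_to_five(ds, top4, cands)
    assert len({r.metabolites for r in recs2}) == len(recs2)


def test_augment_empty_parents():
    rng = np.random.default_rng(8)
    ds = week0_dataset(6, 6, 8, rng)
    with pytest.raises(SearchError, match="nothing to augment"):
        augment_to_five(ds, [], ds.metabolite_ids)


def test_loo_cv_fold_count_and_overwhelming_separation():
    """Under a 10-sigma panel the held-out specificity is perfect, while
    sensitivity tracks 1 - beta: the threshold deliberately concedes a beta
    fraction of the positive density, so its extreme low tail is the one
    part LOO can misclassify."""
    tprs = {0.01: [], 0.05: []}
    for seed in range(10):
        rng = np.random.default_rng(seed)
        values = rng.normal(50.0, 1.0, (38, 6))
        values[:18, 0] += 10.0
        ds = make_dataset(values, ["ASD"] * 18 + ["TD"] * 20)
        report = loo_cv(ds, ["M0", "M1"], betas=(0.01, 0.05))
        assert len(report.folds) == 38
        for beta in (0.01, 0.05):
            assert report.rates[beta]["tnr"] == 1.0
            assert report.rates[beta]["tpr"] >= 1.0 - beta - 2 / 18
            tprs[beta].append(report.rates[beta]["tpr"])
    for beta in (0.01, 0.05):
        assert abs(np.mean(tprs[beta]) - (1.0 - beta)) < 0.06


def test_loo_cv_permuted_labels_near_chance():
    """With labels shuffled, held-out sensitivity tracks 1 - beta while
    specificity collapses toward the beta-quantile chance level."""
    rng = np.random.default_rng(10)
    tprs, tnrs = [], []
    for _ in range(20):
        values = np.exp(rng.standard_normal((30, 3)))
        labels = np.array(["ASD"] * 15 + ["TD"] * 15)
        rng.shuffle(labels)
        ds = make_dataset(values, labels)
        rep = loo_cv(ds, ["M0", "M1"], betas=(0.2,))
        tprs.append(rep.rates[0.2]["tpr"])
        tnrs.append(rep.rates[0.2]["tnr"])
    assert abs(np.mean(tprs) - 0.8) < 0.15
    assert np.mean(tnrs) < 0.5


def test_select_best_preserves_ties():
    rng = np.random.default_rng(11)
    values = np.exp(rng.standard_normal((38, 4)))
    values[:18, 0] *= np.exp(2.0)
    values[:, 3] = values[:, 2]  # M3 duplicates M2 -> identical panels
    ds = make_dataset(values, ["ASD"] * 18 + ["TD"] * 20)
    r1 = loo_cv(ds, ["M0", "M2"])
    r2 = loo_cv(ds, ["M0", "M3"])
    best = select_best([r1, r2])
    assert len(best) == 2  # identical accuracy -> tie preserved
    single = select_best([r1])
    assert single == [r1]


def test_search_pipeline_recovers_planted_panel(small_study):
    scaled = small_study["scaled"]
    truth = small_study["truth"]
    from metapanel import screen_candidates
    cands = [r.metabolite for r in screen_candidates(scaled)][:25]
    out = search_pipeline(scaled, cands, ks=(2, 3), top_n=50, cv_top_n=50)
    best = out["best"][0]
    planted = set(truth.discriminating)
    assert len(set(best.metabolites) & planted) >= 2
    assert best.balanced_accuracy(0.05) > 0.8
    freq = appearance_frequency(out["five"])
    assert 0 < freq.iloc[0] <= 1
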