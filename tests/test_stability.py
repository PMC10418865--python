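"""Resampling engine: splits, AUC, tuning, Shapley oracle, aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from metabosig import (
    StabilitySelection,
    aggregate,
    auc_roc,
    boruta_select,
    generate_matrix,
    impute_censored,
    make_splits,
    run_iteration,
    shapley_importance,
    tune_and_pick,
)
from metabosig.stability import IterationRecord
from metabosig.simulate import recovery_config

from conftest import small_quant_matrix


# -- splits -----------------------------------------------------------------

def _labelled_matrix(n_a, n_b, seed=0):
    rng = np.random.default_rng(seed)
    return small_quant_matrix(
        rng.lognormal(size=(n_a + n_b, 5)), ["sham"] * n_a + ["stroke"] * n_b
    )


def test_split_sizes_40_samples():
    plans = make_splits(_labelled_matrix(28, 12), R=5, seed=1)
    for p in plans:
        assert len(p.train_ids) == 28 and len(p.test_ids) == 12
        assert not set(p.train_ids) & set(p.test_ids)
        assert len(set(p.train_ids) | set(p.test_ids)) == 40


def test_split_sizes_39_samples():
    plans = make_splits(_labelled_matrix(27, 12), R=3, seed=1)
    for p in plans:
        assert len(p.train_ids) == 28 and len(p.test_ids) == 11


def test_split_stratification_preserves_proportions():
    m = _labelled_matrix(28, 12)
    for p in make_splits(m, R=5, seed=2):
        groups = m.groups.loc[p.train_ids]
        assert (groups == "stroke").sum() in (8, 9)


def test_full_train_fraction_errors():
    with pytest.raises(ValueError):
        make_splits(_labelled_matrix(28, 12), R=2, train_fraction=1.0)


def test_splits_deterministic_under_seed():
    m = _labelled_matrix(28, 12)
    p1 = make_splits(m, R=4, seed=9)
    p2 = make_splits(m, R=4, seed=9)
    assert [p.train_ids for p in p1] == [p.train_ids for p in p2]
    assert [p.seed for p in p1] == [p.seed for p in p2]


# -- AUC --------------------------------------------------------------------

def test_auc_examples():
    assert auc_roc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)
    assert auc_roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert auc_roc([0.5, 0.5, 0.5], [1, 0, 1]) == 0.5


def test_auc_equals_concordance_count():
    rng = np.random.default_rng(3)
    for _ in range(10):
        scores = rng.normal(size=20)
        scores[rng.integers(0, 20, 4)] = scores[0]  # inject ties
        labels = rng.integers(0, 2, size=20)
        if labels.sum() in (0, 20):
            continue
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = sum(
            1.0 if p > q else 0.5 if p == q else 0.0
            for p, q in itertools.product(pos, neg)
        ) / (len(pos) * len(neg))
        assert auc_roc(scores, labels) == pytest.approx(conc)


def test_auc_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(4)
    scores = rng.normal(size=50)
    labels = rng.integers(0, 2, size=50)
    assert auc_roc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        auc_roc([0.1, 0.2], [1, 1])


# -- boruta -----------------------------------------------------------------

def test_boruta_confirms_label_copy():
    """A feature identical to the label among noise is confirmed in nearly
    every seeded run."""
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        y = np.array([0] * 28 + [1] * 12)
        X = pd.DataFrame(rng.standard_normal((40, 11)),
                         columns=[f"f{j}" for j in range(11)])
        X["f0"] = y + 0.01 * rng.standard_normal(40)
        dec = boruta_select(X, y, seed=seed)
        if "f0" in dec.confirmed:
            hits += 1
    assert hits >= 0.95 * n_seeds


def test_boruta_bonferroni_rule_confirms_label_copy():
    rng = np.random.default_rng(1)
    y = np.array([0] * 28 + [1] * 12)
    X = pd.DataFrame(rng.standard_normal((40, 11)),
                     columns=[f"f{j}" for j in range(11)])
    X["f0"] = y + 0.01 * rng.standard_normal(40)
    dec = boruta_select(X, y, seed=1, two_step=False)
    assert "f0" in dec.confirmed


def test_boruta_errors():
    with pytest.raises(ValueError):
        boruta_select(pd.DataFrame(index=[0, 1]), np.array([0, 1]))
    X = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 3)))
    with pytest.raises(ValueError):
        boruta_select(X, np.zeros(6))


def test_boruta_deterministic():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.standard_normal((30, 8)), columns=[f"f{j}" for j in range(8)])
    y = np.array([0] * 20 + [1] * 10)
    d1 = boruta_select(X, y, seed=3)
    d2 = boruta_select(X, y, seed=3)
    pd.testing.assert_series_equal(d1.status, d2.status)


# -- tuning -----------------------------------------------------------------

def test_tune_single_grid_point_returned():
    rng = np.random.default_rng(6)
    X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
    y = np.array([0] * 20 + [1] * 10)
    fam, params, model, score = tune_and_pick(
        X, y, grids=[("logistic", [{"C": 1.0}])], seed=0
    )
    assert fam == "logistic" and params == {"C": 1.0}
    assert 0 <= score <= 1


def test_tune_separable_feature_reaches_high_auc():
    rng = np.random.default_rng(7)
    y = np.array([0] * 20 + [1] * 10)
    X = pd.DataFrame({"sig": y + 0.05 * rng.normal(size=30),
                      "noise": rng.normal(size=30)})
    _, _, _, score = tune_and_pick(X, y, seed=1)
    assert score > 0.95


def test_tune_empty_feature_set_errors():
    with pytest.raises(ValueError):
        tune_and_pick(pd.DataFrame(index=range(10)), np.zeros(10))


# -- Shapley ----------------------------------------------------------------

def exact_shapley(predict, x, background):
    """Exact Shapley values by full subset enumeration, with absent features
    drawn jointly from each background row (independent oracle)."""
    m = x.shape[0]
    phi = np.zeros(m)
    from math import comb

    idx = list(range(m))
    for i in idx:
        others = [j for j in idx if j != i]
        for size in range(m):
            for subset in itertools.combinations(others, size):
                w = 1.0 / (m * comb(m - 1, size))
                vals_with = []
                vals_without = []
                for b in background:
                    z = b.copy()
                    z[list(subset)] = x[list(subset)]
                    vals_without.append(predict(z[None, :])[0])
                    z[i] = x[i]
                    vals_with.append(predict(z[None, :])[0])
                phi[i] += w * (np.mean(vals_with) - np.mean(vals_without))
    return phi


def test_shapley_additive_model_analytic():
    rng = np.random.default_rng(8)
    background = rng.normal(size=(200, 2))
    x = np.array([[1.5, -0.5]])
    predict = lambda a: a[:, 0] + a[:, 1]
    phi = shapley_importance(predict, x, background, n_permutations=2000, rng=1)
    assert phi[0, 0] == pytest.approx(1.5 - background[:, 0].mean(), abs=0.08)
    assert phi[0, 1] == pytest.approx(-0.5 - background[:, 1].mean(), abs=0.08)


def test_shapley_constant_model_zero():
    background = np.random.default_rng(9).normal(size=(50, 3))
    phi = shapley_importance(lambda a: np.ones(len(a)), background[:4], background,
                             n_permutations=20, rng=0)
    np.testing.assert_allclose(phi, 0.0, atol=1e-12)


def test_shapley_local_accuracy():
    rng = np.random.default_rng(10)
    background = rng.normal(size=(100, 4))
    x = rng.normal(size=(3, 4))
    predict = lambda a: np.tanh(a).sum(axis=1)
    phi = shapley_importance(predict, x, background, n_permutations=600, rng=2)
    expected = predict(x) - predict(background).mean()
    np.testing.assert_allclose(phi.sum(axis=1), expected, atol=0.1)


def test_shapley_matches_exact_enumeration():
    """Monte-Carlo estimate lies within 3 standard errors of the exact
    subset-enumeration Shapley value for a nonlinear score."""
    rng = np.random.default_rng(11)
    m = 4
    background = rng.normal(size=(12, m))
    x = rng.normal(size=(1, m))
    predict = lambda a: a[:, 0] * a[:, 1] + np.abs(a[:, 2]) - 0.5 * a[:, 3]
    exact = exact_shapley(predict, x[0], background)
    reps = [
        shapley_importance(predict, x, background, n_permutations=150, rng=k)[0]
        for k in range(12)
    ]
    reps = np.array(reps)
    est = reps.mean(axis=0)
    se = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
    assert np.all(np.abs(est - exact) <= 3 * np.maximum(se, 1e-6))


def test_shapley_invalid_permutations():
    with pytest.raises(ValueError):
        shapley_importance(lambda a: a[:, 0], np.ones((1, 1)), np.ones((2, 1)), 0)


# -- aggregation ------------------------------------------------------------

def _rec(i, sel, auc):
    return IterationRecord(index=i, selected=list(sel), test_auc=auc,
                           shap_mean_abs={f: 1.0 for f in sel},
                           shap_mean={f: 0.5 for f in sel})


def test_aggregate_majority_boundary():
    # 30 records; AUC spread so ~22 retained; feature in 12/22 is consensus,
    # 11/22 exactly half is not
    aucs = [0.5] * 8 + [0.9] * 22
    recs = []
    for i, a in enumerate(aucs):
        sel = []
        if a > 0.5:
            j = i - 8
            if j < 12:
                sel.append("maj")
            if j < 11:
                sel.append("half")
        recs.append(_rec(i, sel, a))
    summary = aggregate(recs)
    assert len(summary.retained_indices) == 22
    assert "maj" in summary.consensus
    assert "half" not in summary.consensus
    assert summary.selection_count["maj"] == 12


def test_aggregate_equal_aucs_keeps_all():
    recs = [_rec(i, ["a"], 0.8) for i in range(10)]
    summary = aggregate(recs)
    assert len(summary.retained_indices) == 10
    assert summary.consensus == ["a"]


def test_aggregate_order_invariant():
    rng = np.random.default_rng(12)
    recs = [_rec(i, ["a"] if i % 2 else ["b"], 0.5 + 0.01 * i) for i in range(20)]
    s1 = aggregate(recs)
    shuffled = [recs[i] for i in rng.permutation(20)]
    s2 = aggregate(shuffled)
    assert s1.consensus == s2.consensus
    pd.testing.assert_series_equal(
        s1.selection_frequency.sort_index(), s2.selection_frequency.sort_index()
    )


def test_aggregate_requires_a_successful_record():
    failed = IterationRecord(index=0, selected=[], failed=True)
    with pytest.raises(ValueError):
        aggregate([failed])


# -- one full iteration -----------------------------------------------------

def test_run_iteration_deterministic():
    cfg = recovery_config(n_metabolites=40, n_informative=4, effect_size=1.8, seed=21)
    matrix, _ = generate_matrix(cfg)
    matrix = impute_censored(matrix)
    plan = make_splits(matrix, R=1, seed=5)[0]
    r1 = run_iteration(plan, matrix, shap_permutations=10)
    r2 = run_iteration(plan, matrix, shap_permutations=10)
    assert r1.selected == r2.selected
    assert r1.test_auc == r2.test_auc
    assert r1.shap_mean == r2.shap_mean


def test_model_results_surface():
    cfg = recovery_config(n_metabolites=40, n_informative=4, effect_size=1.8, seed=22)
    matrix, _ = generate_matrix(cfg)
    model = StabilitySelection(impute_censored(matrix), n_iterations=4,
                               shap_permutations=10)
    res = model.fit(seed=3)
    assert len(res.records) == 4
    assert 0 <= res.median_test_auc <= 1
    text = res.summary()
    assert "median test AUC" in text
    counts = res.selection_counts_all()
    assert (counts >= 1).all()
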