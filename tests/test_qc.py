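"""Weight normalization, LOQ filtering with chi-squared rescue, imputation,
standardization."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from metabosig import filter_by_loq, generate_matrix, impute_censored, normalize_by_weight
from metabosig.qc import RETAINED, RETAINED_BY_RESCUE, REMOVED, Standardizer, standardize
from metabosig.simulate import CensorRule, SimulationConfig

from conftest import small_quant_matrix


# -- weight normalization ---------------------------------------------------

def test_weight_normalization_divides_tissue_values():
    qm = small_quant_matrix(
        [[10.0], [9.0]], ["sham", "stroke"], tissue="heart", weights=[2.0, 3.0]
    )
    out = normalize_by_weight(qm)
    assert out.values.iloc[0, 0] == pytest.approx(5.0)
    assert out.values.iloc[1, 0] == pytest.approx(3.0)
    pd.testing.assert_frame_equal(out.status, qm.status)


def test_plasma_unchanged_by_weight_normalization():
    qm = small_quant_matrix([[10.0], [9.0]], ["sham", "stroke"], weights=[2.0, 3.0])
    out = normalize_by_weight(qm)
    pd.testing.assert_frame_equal(out.values, qm.values)


def test_equal_weights_scale_matrix():
    qm = small_quant_matrix(
        [[10.0, 4.0], [8.0, 2.0]], ["sham", "stroke"], tissue="heart", weights=[4.0, 4.0]
    )
    out = normalize_by_weight(qm)
    np.testing.assert_allclose(out.values.to_numpy(), qm.values.to_numpy() / 4.0)


def test_nonpositive_weight_names_sample():
    qm = small_quant_matrix(
        [[1.0], [1.0]], ["sham", "stroke"], tissue="heart", weights=[2.0, 0.0]
    )
    with pytest.raises(ValueError, match="S2"):
        normalize_by_weight(qm)


# -- LOQ filter -------------------------------------------------------------

def _censored_matrix(out_a: int, out_b: int, n_a=28, n_b=12):
    """One metabolite with out_a/out_b below-LLOQ values per group, plus a
    clean companion column."""
    n = n_a + n_b
    vals = np.full((n, 2), 5.0)
    vals[:out_a, 0] = 0.1
    vals[n_a : n_a + out_b, 0] = 0.1
    groups = ["sham"] * n_a + ["stroke"] * n_b
    return small_quant_matrix(vals, groups, lloq=[1.0, 1.0], uloq=[100.0, 100.0])


def test_balanced_censoring_removed():
    # 16/40 out of LOQ split 11/5 over a 28/12 design: proportions are close,
    # chi-squared p >= 0.05, metabolite removed
    qm = _censored_matrix(out_a=11, out_b=5)
    filtered, report = filter_by_loq(qm)
    assert report.table.loc["m1", "decision"] == REMOVED
    assert report.table.loc["m1", "p"] >= 0.05
    assert "m1" not in filtered.metabolites
    assert report.table.loc["m2", "decision"] == RETAINED


def test_group_exclusive_censoring_rescued():
    # 20/20 design, censored in every group-A sample and none of group B:
    # Pearson chi-squared without continuity correction equals n = 40
    qm = _censored_matrix(out_a=20, out_b=0, n_a=20, n_b=20)
    filtered, report = filter_by_loq(qm)
    row = report.table.loc["m1"]
    assert row["decision"] == RETAINED_BY_RESCUE
    assert row["chi2"] == pytest.approx(40.0)
    assert row["p"] < 1e-9
    assert "m1" in filtered.metabolites


def test_no_censoring_retained_without_test(tiny_matrix):
    qm = _censored_matrix(out_a=0, out_b=0)
    _, report = filter_by_loq(qm)
    assert (report.table["decision"] == RETAINED).all()
    assert report.table["p"].isna().all()


def test_threshold_one_is_identity(tiny_matrix):
    matrix, _ = tiny_matrix
    filtered, _ = filter_by_loq(matrix, threshold=1.0)
    assert filtered.metabolites == matrix.metabolites


def test_filter_invariant_to_sample_and_metabolite_order(tiny_matrix):
    matrix, _ = tiny_matrix
    _, report = filter_by_loq(matrix)
    rng = np.random.default_rng(0)
    perm_s = rng.permutation(matrix.sample_ids).tolist()
    perm_m = rng.permutation(matrix.metabolites).tolist()
    shuffled = matrix.subset_samples(perm_s).subset_metabolites(perm_m)
    _, report2 = filter_by_loq(shuffled)
    d1 = report.table["decision"].sort_index()
    d2 = report2.table["decision"].sort_index()
    pd.testing.assert_series_equal(d1, d2)


def test_rescue_fires_for_exactly_the_planted_metabolites():
    """Class-associated censoring (a metabolite quantifiable in one group
    only) is rescued; all other decisions stay clean, across seeds."""
    ok = 0
    n_seeds = 20
    for seed in range(n_seeds):
        cfg = SimulationConfig(
            n_metabolites=80,
            n_informative=0,
            base_censor_fraction=0.05,
            censor_rules=(CensorRule(0.4, 2, class_associated=True),),
            seed=seed,
        )
        matrix, truth = generate_matrix(cfg)
        _, report = filter_by_loq(matrix)
        rescued = set(report.rescued)
        if rescued == set(truth.class_censored_ids):
            ok += 1
    assert ok >= 0.95 * n_seeds


# -- imputation -------------------------------------------------------------

def test_imputation_rule():
    qm = small_quant_matrix(
        [[0.1, 5.0], [2.0, 60.0]], ["sham", "stroke"], lloq=[0.2, 1.0], uloq=[10.0, 50.0]
    )
    out = impute_censored(qm)
    assert out.values.iloc[0, 0] == pytest.approx(0.1)  # LLOQ/2 = 0.2/2
    assert out.values.iloc[1, 1] == pytest.approx(50.0)  # ULOQ
    assert out.values.iloc[1, 0] == pytest.approx(2.0)  # untouched


def test_imputation_identity_when_nothing_flagged():
    qm = small_quant_matrix([[1.0], [2.0]], ["sham", "stroke"], lloq=[0.5], uloq=[10.0])
    out = impute_censored(qm)
    pd.testing.assert_frame_equal(out.values, qm.values)


def test_imputation_respects_weight_normalization():
    qm = small_quant_matrix(
        [[0.1], [5.0]], ["sham", "stroke"], lloq=[1.0], uloq=[100.0],
        tissue="heart", weights=[2.0, 4.0],
    )
    out = impute_censored(normalize_by_weight(qm))
    # below-LLOQ cell: LLOQ/2 in assay units, then divided by that sample's weight
    assert out.values.iloc[0, 0] == pytest.approx(0.5 / 2.0)
    assert out.values.iloc[1, 0] == pytest.approx(5.0 / 4.0)


# -- standardization --------------------------------------------------------

def test_standardize_zero_mean_unit_sd(tiny_matrix):
    matrix, _ = tiny_matrix
    z, _ = standardize(matrix)
    np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, rtol=1e-12)


def test_standardizer_reuse_reproduces_fit():
    rng = np.random.default_rng(1)
    train = pd.DataFrame(rng.normal(5, 2, size=(10, 3)), columns=list("abc"))
    scaler = Standardizer()
    z1 = scaler.fit_transform(train)
    z2 = scaler.transform(train)
    pd.testing.assert_frame_equal(z1, z2)


def test_constant_column_dropped_with_warning():
    frame = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 4.0]})
    scaler = Standardizer()
    with pytest.warns(UserWarning, match="zero-variance"):
        z = scaler.fit_transform(frame)
    assert list(z.columns) == ["a"]
    assert scaler.dropped == ["b"]
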