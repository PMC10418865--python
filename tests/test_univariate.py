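"""Two-group statistics: Mann-Whitney with enumeration oracle, BH, Cohen's d,
t-intervals, fold changes, and the combined comparison table."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metabosig import (
    bh_adjust,
    cohens_d,
    generate_matrix,
    impute_censored,
    log2_fold_change,
    mann_whitney,
    t_confidence_interval,
    volcano_table,
)
from metabosig.simulate import recovery_config


# -- Mann-Whitney -----------------------------------------------------------

def permutation_p(x, y):
    """Brute-force two-sided permutation p-value of the Mann-Whitney U
    statistic over all C(n, nx) group assignments (independent oracle)."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()  # midranks

    def u_stat(idx):
        r = ranks[list(idx)].sum()
        return r - nx * (nx + 1) / 2

    observed = u_stat(range(nx))
    n_half = len(pooled) * (len(pooled) + 1) / 4  # not used; U center below
    center = nx * (len(pooled) - nx) / 2
    obs_dev = abs(observed - center)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        total += 1
        if abs(u_stat(idx) - center) >= obs_dev - 1e-9:
            count += 1
    return count / total


def test_mann_whitney_exact_small_sample():
    u, p = mann_whitney([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)  # 2 / C(6,3)


def test_mann_whitney_all_tied_p_one():
    _, p = mann_whitney([5, 5, 5], [5, 5, 5])
    assert p == pytest.approx(1.0)


def test_mann_whitney_group_swap_invariant():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=7), rng.normal(1, 1, size=5)
    ux, px = mann_whitney(x, y)
    uy, py = mann_whitney(y, x)
    assert px == pytest.approx(py)
    assert ux + uy == pytest.approx(len(x) * len(y))


@pytest.mark.parametrize("seed", range(5))
def test_mann_whitney_matches_enumeration_oracle_6v6(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=6)
    y = rng.normal(0.8, 1, size=6)
    _, p = mann_whitney(x, y)
    assert p == pytest.approx(permutation_p(x, y), abs=1e-12)


def test_mann_whitney_empty_group_errors():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


# -- BH ---------------------------------------------------------------------

def test_bh_hand_computed_values():
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(bh_adjust([0.005, 0.1]), [0.01, 0.1])
    np.testing.assert_allclose(bh_adjust([0.7]), [0.7])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
def test_bh_properties(pvals):
    q = bh_adjust(pvals)
    assert np.all(q >= np.asarray(pvals) - 1e-12)
    assert np.all((q >= 0) & (q <= 1))
    order = np.argsort(pvals)
    assert np.all(np.diff(q[order]) >= -1e-12)  # monotone over sorted input


# -- effect sizes and intervals --------------------------------------------

def test_cohens_d_examples():
    assert cohens_d(27.12, 6.43, 28, 35.48, 6.34, 12) == pytest.approx(1.31, abs=5e-3)
    assert cohens_d(5, 1, 10, 5, 2, 10) == 0.0
    assert cohens_d(0, 1, 2, 1, 1, 2) == pytest.approx(1.0)


def test_cohens_d_scale_invariant():
    d1 = cohens_d(10, 2, 12, 14, 3, 8)
    d2 = cohens_d(10 * 7.5, 2 * 7.5, 12, 14 * 7.5, 3 * 7.5, 8)
    assert d1 == pytest.approx(d2)


def test_cohens_d_errors():
    with pytest.raises(ValueError):
        cohens_d(1, 0, 5, 2, 0, 5)
    with pytest.raises(ValueError):
        cohens_d(1, 1, 1, 2, 1, 5)


def test_t_interval_examples():
    lo, hi = t_confidence_interval(27.12, 6.43, 28)
    assert (round(lo, 2), round(hi, 2)) == (24.63, 29.61)
    assert t_confidence_interval(3.0, 0.0, 5) == (3.0, 3.0)
    lo, _ = t_confidence_interval(352.79, 73.72, 28)
    assert round(lo, 2) == 324.20


def test_log2_fold_change():
    assert log2_fold_change(4.0, 4.0) == 0.0
    assert log2_fold_change(8.0, 4.0) == pytest.approx(1.0)
    assert log2_fold_change(3.0, 6.0) == pytest.approx(-log2_fold_change(6.0, 3.0))
    with pytest.raises(ValueError):
        log2_fold_change(0.0, 1.0)


# -- volcano table ----------------------------------------------------------

def test_volcano_single_metabolite_q_equals_p():
    from conftest import small_quant_matrix

    rng = np.random.default_rng(2)
    vals = rng.lognormal(size=(10, 1))
    qm = small_quant_matrix(vals, ["sham"] * 5 + ["stroke"] * 5)
    table = volcano_table(qm)
    assert len(table) == 1
    assert table["q"].iloc[0] == pytest.approx(table["p"].iloc[0])


def test_volcano_detects_strong_planted_effect():
    """A single d=1.8 metabolite at 28/12 survives BH across a 50-metabolite
    panel in most seeds (the rank-test power ceiling at these group sizes is
    ~86%, so the check asserts 80%)."""
    hits = 0
    n_seeds = 50
    for seed in range(n_seeds):
        cfg = recovery_config(
            n_metabolites=50, n_informative=1, effect_size=1.8, seed=seed
        )
        matrix, truth = generate_matrix(cfg)
        table = volcano_table(impute_censored(matrix))
        if table.loc[truth.informative_metabolite_ids[0], "q"] < 0.05:
            hits += 1
    assert hits >= 0.8 * n_seeds


def test_volcano_coordinates_finite(tiny_matrix):
    matrix, _ = tiny_matrix
    table = volcano_table(impute_censored(matrix))
    assert np.isfinite(table["neg_log10_q"]).all()
    assert np.isfinite(table["log2_fc"]).all()
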