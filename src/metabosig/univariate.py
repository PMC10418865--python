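"""Per-metabolite two-group statistics.

For every metabolite (and, optionally, every indicator ratio/sum) the module
reports the descriptive columns of a targeted-metabolomics comparison table —
group means, sample standard deviations, t-based 95% confidence intervals,
ranges — together with a tie-corrected Mann-Whitney U test, Benjamini-Hochberg
adjusted q-values, the log2 fold change of group means (positive group over
reference group) and Cohen's d with the degrees-of-freedom-weighted pooled
standard deviation:

    d = |m_b - m_a| / sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2))

Volcano coordinates (log2FC, -log10 q) are emitted for plotting; q is floored
at 1e-300 so the coordinates stay finite.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant import QuantMatrix

Q_FLOOR = 1e-300


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for x, p).

    U uses midranks (tie-corrected).  The p-value is the exact enumeration
    value when the smaller group has <= 8 observations and there are no ties,
    and the normal approximation with tie correction otherwise.  Invariant
    under group swap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty groups")
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    p = float(res.pvalue)
    if math.isnan(p):  # all values tied: no evidence against exchangeability
        p = 1.0
    return float(res.statistic), min(p, 1.0)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_d(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> float:
    """Cohen's d magnitude with the df-weighted pooled SD."""
    if n_a < 2 or n_b < 2:
        raise ValueError("cohens_d requires n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd_a == 0 and sd_b == 0:
        raise ValueError("cohens_d undefined when both SDs are zero")
    pooled = math.sqrt(
        ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    )
    return abs(mean_b - mean_a) / pooled


def t_confidence_interval(mean, sd, n, level: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval for a group mean: mean +/- t * sd/sqrt(n)."""
    if n < 2:
        raise ValueError("confidence interval requires n >= 2")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    half = stats.t.ppf((1 + level) / 2, df=n - 1) * sd / math.sqrt(n)
    return mean - half, mean + half


def log2_fold_change(mean_stroke, mean_sham) -> float:
    """log2(mean_stroke / mean_sham); antisymmetric under group swap."""
    if mean_stroke <= 0 or mean_sham <= 0:
        raise ValueError("fold change requires strictly positive means")
    return math.log2(mean_stroke / mean_sham)


def _feature_row(a: np.ndarray, b: np.ndarray, n_a: int, n_b: int) -> dict:
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    sd_a = float(np.std(a, ddof=1))
    sd_b = float(np.std(b, ddof=1))
    ci_a = t_confidence_interval(mean_a, sd_a, n_a)
    ci_b = t_confidence_interval(mean_b, sd_b, n_b)
    u, p = mann_whitney(a, b)
    row = {
        "mean_a": mean_a,
        "ci_low_a": ci_a[0],
        "ci_high_a": ci_a[1],
        "sd_a": sd_a,
        "range_a": float(np.ptp(a)),
        "mean_b": mean_b,
        "ci_low_b": ci_b[0],
        "ci_high_b": ci_b[1],
        "sd_b": sd_b,
        "range_b": float(np.ptp(b)),
        "U": u,
        "p": p,
    }
    row["cohens_d"] = (
        cohens_d(mean_a, sd_a, n_a, mean_b, sd_b, n_b)
        if not (sd_a == 0 and sd_b == 0)
        else 0.0
    )
    row["log2_fc"] = (
        log2_fold_change(mean_b, mean_a) if mean_a > 0 and mean_b > 0 else float("nan")
    )
    return row


def volcano_table(
    matrix: QuantMatrix, indicator_values: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Univariate comparison table with volcano coordinates.

    One row per metabolite, plus one per column of ``indicator_values`` (a
    per-sample table of indicator ratios/sums aligned to the matrix's
    samples).  Group a is the reference (sham), group b the positive class
    (stroke); BH adjustment runs across all rows of the returned table.
    """
    y, positive = matrix.binary_labels()
    n_a, n_b = int((y == 0).sum()), int((y == 1).sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("volcano_table requires >= 2 samples per group")

    frames = [matrix.values]
    if indicator_values is not None and not indicator_values.empty:
        frames.append(indicator_values.reindex(matrix.values.index))
    rows = {}
    for frame, kind in zip(frames, ("metabolite", "indicator")):
        arr = frame.to_numpy(dtype=float)
        for j, name in enumerate(frame.columns):
            col = arr[:, j]
            finite = np.isfinite(col)
            a, b = col[finite & (y == 0)], col[finite & (y == 1)]
            if a.size < 2 or b.size < 2:
                continue
            row = _feature_row(a, b, a.size, b.size)
            row["kind"] = kind
            rows[name] = row

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "feature"
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["neg_log10_q"] = -np.log10(np.maximum(table["q"].to_numpy(), Q_FLOOR))
    table.attrs["positive_group"] = positive
    return table
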