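"""Quantification-matrix quality control: weight normalization, the
limit-of-quantification filter with its chi-squared rescue, censored-value
imputation, and column standardization."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .quant import ABOVE_ULOQ, BELOW_LLOQ, VALID, QuantMatrix

RETAINED = "retained"
RETAINED_BY_RESCUE = "retained_by_rescue"
REMOVED = "removed"


def normalize_by_weight(matrix: QuantMatrix) -> QuantMatrix:
    """Divide tissue-sample concentrations by tissue weight (mg).

    Plasma samples pass through unchanged.  Status flags are preserved: they
    refer to the raw assay units in which the LOQ bounds are expressed.
    """
    weights = matrix.samples["weight_mg"].copy()
    is_tissue = matrix.samples["tissue"] != "plasma"
    bad = is_tissue & (weights.isna() | (weights <= 0))
    if bad.any():
        raise ValueError(
            f"non-positive or missing tissue weight for sample(s) "
            f"{list(matrix.samples.index[bad])}"
        )
    factor = np.where(is_tissue, weights.to_numpy(dtype=float), 1.0)
    values = matrix.values.div(factor, axis=0)
    return QuantMatrix(
        values=values,
        loq=matrix.loq,
        samples=matrix.samples,
        status=matrix.status.copy(),
        weight_normalized=bool(is_tissue.any()) or matrix.weight_normalized,
    )


@dataclasses.dataclass
class FilterReport:
    """Per-metabolite record of the LOQ filter decisions."""

    table: pd.DataFrame  # fraction, out_a, in_a, out_b, in_b, chi2, p, decision

    @property
    def removed(self) -> list[str]:
        return list(self.table.index[self.table["decision"] == REMOVED])

    @property
    def rescued(self) -> list[str]:
        return list(self.table.index[self.table["decision"] == RETAINED_BY_RESCUE])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="metabolite_id")

    def summary(self) -> dict:
        counts = self.table["decision"].value_counts().to_dict()
        return {
            "n_metabolites": int(len(self.table)),
            "n_retained": int(counts.get(RETAINED, 0)),
            "n_retained_by_rescue": int(counts.get(RETAINED_BY_RESCUE, 0)),
            "n_removed": int(counts.get(REMOVED, 0)),
        }


def _chi2_out_of_range(out_a: int, in_a: int, out_b: int, in_b: int):
    """Pearson chi-squared (no continuity correction) on the 2x2
    out-of-range-status x group table.  Degenerate margins give (nan, 1)."""
    table = np.array([[out_a, in_a], [out_b, in_b]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def filter_by_loq(
    matrix: QuantMatrix, threshold: float = 0.30, alpha: float = 0.05
) -> tuple[QuantMatrix, FilterReport]:
    """Remove metabolites with too many out-of-LOQ values.

    A metabolite whose out-of-LOQ fraction exceeds ``threshold`` (strictly) is
    removed unless the out-of-range status is significantly associated with
    the group label (Pearson chi-squared on the 2x2 table, p < ``alpha``) —
    the case of a metabolite quantifiable in one group only, which is kept as
    ``retained_by_rescue``.
    """
    y, _ = matrix.binary_labels()
    counts = matrix.groups.value_counts()
    if (counts < 2).any():
        raise ValueError("filter_by_loq requires >= 2 samples per group")

    out = (matrix.status != VALID).to_numpy()
    n_a = int((y == 0).sum())
    n_b = int((y == 1).sum())
    rows = []
    for j, met in enumerate(matrix.metabolites):
        out_a = int(out[y == 0, j].sum())
        out_b = int(out[y == 1, j].sum())
        frac = (out_a + out_b) / matrix.n_samples
        chi2 = p = float("nan")
        if frac > threshold:
            chi2, p = _chi2_out_of_range(out_a, n_a - out_a, out_b, n_b - out_b)
            decision = RETAINED_BY_RESCUE if p < alpha else REMOVED
        else:
            decision = RETAINED
        rows.append(
            {
                "fraction": frac,
                "out_a": out_a,
                "in_a": n_a - out_a,
                "out_b": out_b,
                "in_b": n_b - out_b,
                "chi2": chi2,
                "p": p,
                "decision": decision,
            }
        )
    report = FilterReport(
        pd.DataFrame(rows, index=pd.Index(matrix.metabolites, name="metabolite_id"))
    )
    keep = [m for m, d in zip(matrix.metabolites, report.table["decision"]) if d != REMOVED]
    return matrix.subset_metabolites(keep), report


def impute_censored(matrix: QuantMatrix) -> QuantMatrix:
    """Replace censored values: below_LLOQ -> LLOQ/2, above_ULOQ -> ULOQ.

    For weight-normalized tissue matrices the replacement is divided by the
    sample's weight so it lands on the same scale as the stored values.
    """
    values = matrix.values.to_numpy().copy()
    status = matrix.status.to_numpy()
    lloq = matrix.loq["lloq"].reindex(matrix.values.columns).to_numpy()
    uloq = matrix.loq["uloq"].reindex(matrix.values.columns).to_numpy()
    needs = (status != VALID).any(axis=0)
    bad = [
        m
        for m, need, lo, hi in zip(matrix.metabolites, needs, lloq, uloq)
        if need and not (np.isfinite(lo) and np.isfinite(hi))
    ]
    if bad:
        raise ValueError(f"missing LOQ bounds for metabolites needing imputation: {bad}")

    if matrix.weight_normalized:
        is_tissue = (matrix.samples["tissue"] != "plasma").to_numpy()
        w = np.where(is_tissue, matrix.samples["weight_mg"].to_numpy(dtype=float), 1.0)
    else:
        w = np.ones(matrix.n_samples)

    below = status == BELOW_LLOQ
    above = status == ABOVE_ULOQ
    values[below] = (lloq[None, :] / 2.0 / w[:, None])[below]
    values[above] = (uloq[None, :] / w[:, None])[above]
    return QuantMatrix(
        values=pd.DataFrame(values, index=matrix.values.index, columns=matrix.values.columns),
        loq=matrix.loq,
        samples=matrix.samples,
        status=matrix.status.copy(),
        weight_normalized=matrix.weight_normalized,
    )


@dataclasses.dataclass
class Standardizer:
    """Column z-scoring (mean centring, unit sample SD, ddof=1).

    Fitted on one matrix (typically the training split) and reusable on
    held-out data.  Zero-variance columns are dropped with a warning and
    recorded in ``dropped``.
    """

    means: pd.Series | None = None
    sds: pd.Series | None = None
    dropped: list[str] = dataclasses.field(default_factory=list)

    def fit(self, values: pd.DataFrame) -> "Standardizer":
        means = values.mean(axis=0)
        sds = values.std(axis=0, ddof=1)
        self.dropped = list(values.columns[(sds == 0) | sds.isna()])
        if self.dropped:
            warnings.warn(
                f"dropping {len(self.dropped)} zero-variance column(s): "
                f"{self.dropped[:5]}",
                stacklevel=2,
            )
        keep = [c for c in values.columns if c not in set(self.dropped)]
        self.means = means[keep]
        self.sds = sds[keep]
        return self

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        if self.means is None:
            raise RuntimeError("Standardizer not fitted")
        return (values[self.means.index] - self.means) / self.sds

    def fit_transform(self, values: pd.DataFrame) -> pd.DataFrame:
        return self.fit(values).transform(values)


def standardize(matrix: QuantMatrix) -> tuple[pd.DataFrame, Standardizer]:
    """Z-score every metabolite column of ``matrix`` (full-matrix convention,
    used for descriptive PCA); returns the transform for reuse."""
    scaler = Standardizer()
    z = scaler.fit_transform(matrix.values)
    return z, scaler
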