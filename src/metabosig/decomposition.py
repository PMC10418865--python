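"""Unsupervised sample screening: PCA and robust score-distance outlier flags."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


@dataclasses.dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a centered SVD."""

    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # metabolites x components
    explained_variance: np.ndarray        # per-component variance
    explained_variance_ratio: np.ndarray  # fractions of total variance

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(z: pd.DataFrame, k: int | None = None) -> PCAResult:
    """Principal-component decomposition of an (already standardized) matrix.

    The matrix is re-centered column-wise, decomposed by SVD, and each
    component's sign fixed so its largest-magnitude loading is positive.
    ``k`` defaults to min(n_samples - 1, n_metabolites).
    """
    n, p = z.shape
    kmax = min(n - 1, p)
    if k is None:
        k = kmax
    if not 1 <= k <= kmax:
        raise ValueError(f"k must lie in [1, {kmax}], got {k}")
    arr = z.to_numpy(dtype=float)
    centered = arr - arr.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(min(len(s), k)):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    var = s**2 / (n - 1)
    ratio = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    comp = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame((u[:, :k] * s[:k]), index=z.index, columns=comp),
        loadings=pd.DataFrame(vt[:k].T, index=z.columns, columns=comp),
        explained_variance=var[:k],
        explained_variance_ratio=ratio[:k],
    )


def score_distances(result: PCAResult, k: int = 2) -> pd.Series:
    """Per-sample distance in the first ``k`` components, each component
    scaled by its standard deviation (zero-variance components ignored)."""
    if result.n_components < k:
        raise ValueError(f"result has {result.n_components} components, need {k}")
    sd = np.sqrt(result.explained_variance[:k])
    scores = result.scores.iloc[:, :k].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sd > 0, scores / sd, 0.0)
    return pd.Series(np.sqrt((ratio**2).sum(axis=1)), index=result.scores.index)


def flag_outliers(
    result: PCAResult, k: int = 2, z_threshold: float = 4.0
) -> pd.DataFrame:
    """Flag samples whose robust z-score of PCA score distance exceeds
    ``z_threshold``.

    The z-score uses median and MAD (scaled to the normal) of the distances;
    when the MAD is zero the SD is used instead, and when both are zero no
    sample is flagged.  Returns a per-sample table with columns ``distance``,
    ``robust_z`` and ``outlier``.
    """
    d = score_distances(result, k=k)
    med = d.median()
    mad = float((d - med).abs().median()) * 1.4826
    scale = mad if mad > 0 else float(d.std(ddof=1))
    if not np.isfinite(scale) or scale == 0:
        z = pd.Series(0.0, index=d.index)
    else:
        z = (d - med) / scale
    return pd.DataFrame(
        {"distance": d, "robust_z": z, "outlier": z > z_threshold}
    )
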