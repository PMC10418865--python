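"""All-relevant feature selection with shadow features.

Each round permutes every remaining feature column into a "shadow" copy, fits
a random-forest importance model on the concatenated [real | shadow] matrix,
and credits a *hit* to every real feature whose importance exceeds the
``perc``-th percentile of the shadow importances (``perc=100``: the shadow
maximum).  Features are confirmed or rejected by binomial tests of their hit
count against chance (p = 0.5), with multiplicity correction; rejected
features are dropped from subsequent rounds.  The procedure stops when every
feature is decided or after ``max_iter`` rounds, leaving the rest *tentative*
(treated as not selected downstream).

Two decision rules are available:

* ``two_step=True`` (default, the reference algorithm's default): one-sided
  binomial tests in each direction, corrected per round across features by
  Benjamini-Hochberg and across rounds by alpha/round;
* ``two_step=False``: two-sided binomial tests with a plain Bonferroni
  correction over the number of features — more conservative, slower to
  decide.

The default shadow pool is tiled to 60 columns, keeping the hit bar the
maximum of more noise draws than a small panel has features; this controls
the familywise chance of confirming anything on pure-noise data at the cost
of sensitivity to moderate effects.  ``min_shadows=5`` reproduces the
reference algorithm's pool (one shadow per surviving feature), which is more
sensitive but confirms a small panel's strongest chance-correlate far more
often than ``alpha`` once rejection has narrowed the arena.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import config_context
from sklearn.ensemble import RandomForestClassifier

CONFIRMED = "confirmed"
REJECTED = "rejected"
TENTATIVE = "tentative"

#: default shadow-pool floor: shadows are tiled up to at least this many
#: columns (or the full panel width if smaller), so the hit bar remains a
#: high-order statistic even after rejection has narrowed the arena.  See
#: the ``min_shadows`` parameter of :func:`boruta_select` for the trade-off
#: this floor controls.
MIN_SHADOWS = 60

DEFAULT_FOREST = dict(max_depth=5, n_jobs=1)


def _n_trees(width: int) -> int:
    """Forest size per round, scaled to the current matrix width so each
    feature keeps a comparable number of split opportunities."""
    return int(np.clip(30 + width // 6, 30, 120))


@dataclasses.dataclass
class BorutaDecision:
    """Outcome of one selection run."""

    status: pd.Series       # per feature: confirmed / rejected / tentative
    hits: pd.Series         # rounds in which the feature beat the shadows
    n_iterations: int
    perc: float

    @property
    def confirmed(self) -> list[str]:
        return list(self.status.index[self.status == CONFIRMED])

    @property
    def rejected(self) -> list[str]:
        return list(self.status.index[self.status == REJECTED])

    @property
    def tentative(self) -> list[str]:
        return list(self.status.index[self.status == TENTATIVE])


def _shadow_matrix(
    x: np.ndarray, rng: np.random.Generator, min_shadows: int
) -> np.ndarray:
    """Independently permute each column; tile permutations up to
    ``min_shadows`` columns."""
    n, m = x.shape
    reps = max(1, int(np.ceil(min_shadows / m)))
    tiled = np.tile(x, reps)
    idx = np.argsort(rng.random((n, m * reps)), axis=0, kind="stable")
    return np.take_along_axis(tiled, idx, axis=0)


def _decide(h: np.ndarray, rounds: int, m_total: int, alpha: float, two_step: bool):
    """Per-feature confirm/reject/undecided decisions from cumulative hits."""
    accept_p = stats.binom.sf(h - 1, rounds, 0.5)
    reject_p = stats.binom.cdf(h, rounds, 0.5)
    if two_step:
        # BH across the features still under test, and alpha/rounds across
        # the repeated looks at the growing hit counts
        accept = _bh_reject(accept_p, alpha) & (accept_p <= alpha / rounds)
        reject = _bh_reject(reject_p, alpha) & (reject_p <= alpha / rounds)
    else:
        pvals = np.minimum(1.0, 2 * np.minimum(accept_p, reject_p))
        signif = pvals * m_total < alpha
        accept = signif & (h > rounds / 2)
        reject = signif & (h < rounds / 2)
    return accept, reject


def _bh_reject(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask."""
    m = len(pvals)
    order = np.argsort(pvals)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = pvals[order] <= thresh
    out = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = np.max(np.nonzero(passed)[0])
        out[order[: kmax + 1]] = True
    return out


def boruta_select(
    x: pd.DataFrame,
    y: np.ndarray,
    max_iter: int = 100,
    perc: float = 100.0,
    alpha: float = 0.05,
    seed: int | None = 0,
    forest_params: dict | None = None,
    two_step: bool = True,
    resolve_tentative: bool = False,
    min_shadows: int = MIN_SHADOWS,
) -> BorutaDecision:
    """Run the shadow-feature selection on a training matrix.

    Parameters
    ----------
    x : DataFrame
        Training features (standardized), samples in rows.
    y : array
        Binary class labels; both classes must be present.
    max_iter : int
        Maximum number of shadow rounds.
    perc : float
        Percentile of shadow importances a real feature must beat to score a
        hit (100 = shadow maximum, the strictest setting).
    alpha : float
        Significance level of the binomial decisions.
    seed : int
        Seeds both the shadow permutations and the forests.
    forest_params : dict
        Overrides for the random-forest importance model; when
        ``n_estimators`` is absent the forest size scales with the current
        matrix width.
    resolve_tentative : bool
        At termination, promote tentative features whose median importance
        across rounds exceeded the median shadow threshold (the reference
        algorithm's closing heuristic); otherwise leave them tentative.
    min_shadows : int
        Tile the shadow pool to at least this many columns (default 60,
        the familywise-controlled setting; see the module docstring).
    """
    if x.shape[1] < 1:
        raise ValueError("boruta_select requires at least one feature")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("boruta_select requires both classes in y")

    rng = np.random.default_rng(seed)
    params = dict(DEFAULT_FOREST)
    if forest_params:
        params.update(forest_params)

    features = list(x.columns)
    m_total = len(features)
    hits = pd.Series(0, index=features, dtype=int)
    status = pd.Series(TENTATIVE, index=features, dtype=object)
    active = list(features)
    arr_full = x.to_numpy(dtype=float)
    col_index = {f: j for j, f in enumerate(features)}

    imp_history: dict[str, list[float]] = {f: [] for f in features}
    thresh_history: list[float] = []
    rounds = 0
    while active and rounds < max_iter:
        rounds += 1
        arr = arr_full[:, [col_index[f] for f in active]]
        shadows = _shadow_matrix(arr, rng, min_shadows)
        if "n_estimators" in params:
            forest_size = params["n_estimators"]
            extra = {k: v for k, v in params.items() if k != "n_estimators"}
        else:
            forest_size = _n_trees(arr.shape[1] + shadows.shape[1])
            extra = params
        forest = RandomForestClassifier(
            n_estimators=forest_size,
            random_state=int(rng.integers(2**31)),
            **extra,
        )
        with config_context(assume_finite=True):
            forest.fit(np.hstack([arr, shadows]), y)
        imp = forest.feature_importances_
        thresh = np.percentile(imp[arr.shape[1] :], perc)
        thresh_history.append(float(thresh))
        beat = imp[: arr.shape[1]] > thresh
        for f, v, b in zip(active, imp[: arr.shape[1]], beat):
            imp_history[f].append(float(v))
            if b:
                hits[f] += 1

        h = hits[active].to_numpy()
        accept, reject = _decide(h, rounds, m_total, alpha, two_step)
        for f, a, r in zip(active, accept, reject):
            if a:
                status[f] = CONFIRMED
            elif r:
                status[f] = REJECTED
        active = [f for f, a, r in zip(active, accept, reject) if not (a or r)]

    if resolve_tentative and active:
        # closing heuristic: a still-undecided feature whose typical
        # importance beat the typical shadow threshold is kept
        med_thresh = float(np.median(thresh_history))
        for f in active:
            if np.median(imp_history[f]) > med_thresh:
                status[f] = CONFIRMED

    return BorutaDecision(status=status, hits=hits, n_iterations=rounds, perc=perc)
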