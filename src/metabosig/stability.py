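"""Repeated-resampling consensus feature selection ("stability selection").

The engine repeats, on R stratified train/test partitions of a two-group
concentration matrix:

1. column standardization fitted on the training split only;
2. shadow-feature (Boruta-style) selection of all relevant metabolites;
3. hyperparameter tuning of four classical model families (regularized
   logistic regression, linear SVM, RBF SVM, random forest) by mean
   validation AUC over stratified 70/30 subsampling resamples of the
   training split ("bootstrap without replacement");
4. evaluation of the winning model's AUC-ROC on the held-out test split;
5. Monte-Carlo Shapley attribution of the test predictions.

Rounds whose test AUC falls strictly below the lower 25th percentile of all
rounds are excluded, and metabolites selected in more than half of the
remaining rounds form the consensus signature, ranked by mean |phi|.

The model/results surface follows the statsmodels convention:
``StabilitySelection(values, y).fit(seed)`` returns a
:class:`StabilityResults` with the per-round records, the consensus summary
and a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn import config_context
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .boruta import boruta_select
from .qc import Standardizer
from .quant import QuantMatrix
from .shapley import shapley_importance

# ---------------------------------------------------------------------------
# splits


@dataclasses.dataclass
class SplitPlan:
    """One stratified train/test partition with its child seed."""

    index: int
    train_ids: list[str]
    test_ids: list[str]
    seed: int


def _stratified_split(
    ids: np.ndarray, y: np.ndarray, n_train: int, rng: np.random.Generator
) -> tuple[list, list]:
    """Allocate per-class training counts by largest remainder, then sample."""
    classes, counts = np.unique(y, return_counts=True)
    ideal = n_train * counts / counts.sum()
    base = np.floor(ideal).astype(int)
    remainder = n_train - base.sum()
    order = np.argsort(-(ideal - base))
    for i in order[:remainder]:
        base[i] += 1
    train, test = [], []
    for cls, k in zip(classes, base):
        members = ids[y == cls]
        perm = rng.permutation(len(members))
        train.extend(members[perm[:k]].tolist())
        test.extend(members[perm[k:]].tolist())
    return sorted(train), sorted(test)


def make_splits(
    matrix: QuantMatrix,
    R: int = 30,
    train_fraction: float = 0.70,
    seed: int = 0,
) -> list[SplitPlan]:
    """R stratified train/test plans.

    The training size is ceil(train_fraction * n); with n >= 40 it is reduced
    if needed so at least 12 samples remain in the test set.  For the 28/12
    design this gives 28 train / 12 test, and for 39 samples 28 train / 11
    test.  Class proportions are preserved to within rounding.
    """
    y = matrix.groups.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("make_splits requires >= 2 samples in each class")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = matrix.n_samples
    n_train = math.ceil(train_fraction * n)
    if n >= 40 and n - n_train < 12:
        n_train = n - 12
    if not 0 < n_train < n:
        raise ValueError(
            f"train_fraction={train_fraction} leaves an empty train or test set"
        )
    ids = np.asarray(matrix.sample_ids)
    master = np.random.SeedSequence(seed)
    plans = []
    for i, child in enumerate(master.spawn(R)):
        child_seed = int(child.generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(child_seed)
        train, test = _stratified_split(ids, y, n_train, rng)
        plans.append(SplitPlan(index=i, train_ids=train, test_ids=test, seed=child_seed))
    return plans


# ---------------------------------------------------------------------------
# AUC


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve in rank-statistic form with midranks.

    AUC = (R+ - n+(n+ + 1)/2) / (n+ n-), where R+ is the rank sum of the
    positive-class scores; equals the probability that a random positive
    outranks a random negative (ties counted half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auc_roc requires both classes")
    ranks = rankdata(scores)
    r_pos = ranks[pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# model families and tuning


def default_model_grids() -> list[tuple[str, list[dict]]]:
    """Family order fixes tie-breaking; within a family, grids are listed
    from least to most complex."""
    return [
        ("logistic", [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)]),
        ("linear_svm", [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)]),
        (
            "rbf_svm",
            [
                {"C": c, "gamma": g}
                for c in (0.1, 1.0, 10.0)
                for g in ("scale", 0.1)
            ],
        ),
        (
            "random_forest",
            [{"n_estimators": 100, "max_depth": d} for d in (3, None)],
        ),
    ]


def _build_model(family: str, params: dict, seed: int):
    if family == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if family == "linear_svm":
        return SVC(kernel="linear", random_state=seed, **params)
    if family == "rbf_svm":
        return SVC(kernel="rbf", random_state=seed, **params)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    raise ValueError(f"unknown model family {family!r}")


def _score(model, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(x), dtype=float)
    return np.asarray(model.predict_proba(x)[:, 1], dtype=float)


def tune_and_pick(
    x: pd.DataFrame,
    y: np.ndarray,
    grids: list[tuple[str, list[dict]]] | None = None,
    n_resamples: int = 10,
    val_fraction: float = 0.30,
    seed: int = 0,
):
    """Pick the best (family, hyperparameters) by mean validation AUC.

    The training split is subsampled ``n_resamples`` times into stratified
    train/validation parts (subsampling without replacement).  Ties go to the
    earlier family, then the earlier (less complex) grid point.  Returns
    ``(family, params, fitted_model, validation_auc)`` with the winner refit
    on the full input.
    """
    if x.shape[1] == 0:
        raise ValueError("tune_and_pick requires a non-empty feature set")
    if grids is None:
        grids = default_model_grids()
    y = np.asarray(y)
    ids = np.arange(len(y))
    rng = np.random.default_rng(seed)
    n_sub = max(1, math.ceil((1 - val_fraction) * len(y)))

    splits = []
    for _ in range(n_resamples):
        train, val = _stratified_split(ids, y, n_sub, rng)
        if len(np.unique(y[val])) < 2 or len(np.unique(y[train])) < 2:
            continue  # degenerate resample at tiny n; skip
        splits.append((np.asarray(train), np.asarray(val)))
    if not splits:
        raise ValueError("no valid tuning resamples (groups too small)")

    arr = x.to_numpy(dtype=float)
    best = None
    for family, grid in grids:
        for params in grid:
            aucs = []
            with config_context(assume_finite=True):
                for k, (tr, va) in enumerate(splits):
                    model = _build_model(family, params, seed=int((seed + k) % 2**31))
                    model.fit(arr[tr], y[tr])
                    aucs.append(auc_roc(_score(model, arr[va]), y[va]))
            mean_auc = float(np.mean(aucs))
            if best is None or mean_auc > best[3]:
                best = (family, params, None, mean_auc)
    family, params, _, val_auc = best
    final = _build_model(family, params, seed=int(seed % 2**31))
    final.fit(arr, y)
    return family, params, final, val_auc


# ---------------------------------------------------------------------------
# per-round record and execution


@dataclasses.dataclass
class IterationRecord:
    """Everything one resampling round produced."""

    index: int
    selected: list[str]
    model_family: str | None = None
    model_params: dict | None = None
    validation_auc: float | None = None
    test_auc: float | None = None
    shap_mean_abs: dict[str, float] | None = None   # per-feature mean |phi|
    shap_mean: dict[str, float] | None = None       # per-feature signed mean phi
    failed: bool = False
    failure_reason: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_iteration(
    plan: SplitPlan,
    matrix: QuantMatrix,
    boruta_params: dict | None = None,
    grids: list[tuple[str, list[dict]]] | None = None,
    shap_permutations: int = 50,
) -> IterationRecord:
    """Execute one full round on the given split plan.

    Standardization is fitted on the training split only; the shadow-feature
    selection, tuning, test evaluation and Shapley attribution all derive
    their randomness from the plan's child seed.  A round on which no feature
    is confirmed is marked failed (and later excluded from aggregation).
    """
    rng = np.random.default_rng(plan.seed)
    y_all, _ = matrix.binary_labels()
    y = pd.Series(y_all, index=matrix.values.index)
    train_x = matrix.values.loc[plan.train_ids]
    test_x = matrix.values.loc[plan.test_ids]
    y_train = y.loc[plan.train_ids].to_numpy()
    y_test = y.loc[plan.test_ids].to_numpy()

    scaler = Standardizer()
    z_train = scaler.fit_transform(train_x)
    z_test = scaler.transform(test_x)

    decision = boruta_select(
        z_train,
        y_train,
        seed=int(rng.integers(2**31)),
        **(boruta_params or {}),
    )
    selected = decision.confirmed
    if not selected:
        return IterationRecord(
            index=plan.index,
            selected=[],
            failed=True,
            failure_reason="no features confirmed",
        )

    family, params, model, val_auc = tune_and_pick(
        z_train[selected],
        y_train,
        grids=grids,
        seed=int(rng.integers(2**31)),
    )
    test_scores = _score(model, z_test[selected].to_numpy(dtype=float))
    test_auc = auc_roc(test_scores, y_test)

    phi = shapley_importance(
        lambda a: _score(model, a),
        z_test[selected].to_numpy(dtype=float),
        z_train[selected].to_numpy(dtype=float),
        n_permutations=shap_permutations,
        rng=np.random.default_rng(int(rng.integers(2**31))),
    )
    return IterationRecord(
        index=plan.index,
        selected=selected,
        model_family=family,
        model_params=params,
        validation_auc=val_auc,
        test_auc=test_auc,
        shap_mean_abs={f: float(v) for f, v in zip(selected, np.abs(phi).mean(axis=0))},
        shap_mean={f: float(v) for f, v in zip(selected, phi.mean(axis=0))},
    )


# ---------------------------------------------------------------------------
# aggregation


@dataclasses.dataclass
class StabilitySummary:
    """Consensus of the resampling rounds."""

    retained_indices: list[int]
    selection_count: pd.Series       # over retained rounds
    selection_frequency: pd.Series
    mean_abs_shap: pd.Series
    mean_shap: pd.Series
    consensus: list[str]             # ordered by mean |phi|, descending
    median_test_auc: float
    test_auc_sd: float
    n_successful: int
    n_failed: int

    def consensus_table(self) -> pd.DataFrame:
        t = pd.DataFrame(
            {
                "frequency": self.selection_frequency,
                "mean_abs_shap": self.mean_abs_shap,
                "mean_shap": self.mean_shap,
            }
        ).loc[self.consensus]
        t.index.name = "feature"
        return t


def aggregate(
    records: list[IterationRecord],
    exclude_quantile: float = 0.25,
    majority: float = 0.5,
) -> StabilitySummary:
    """Screen rounds by test AUC and take the majority-vote consensus.

    Rounds with test AUC *strictly below* the empirical ``exclude_quantile``
    of all successful rounds are dropped (so when all AUCs are equal nothing
    is excluded).  A feature reaches consensus when selected in strictly more
    than ``majority`` of the retained rounds; consensus features are ranked
    by their mean |phi| over the retained rounds in which they were selected.
    The reported median/SD of test AUC covers all successful rounds.
    """
    ok = [r for r in records if not r.failed]
    if not ok:
        raise ValueError("aggregate requires at least one successful record")
    aucs = np.array([r.test_auc for r in ok])
    cut = np.quantile(aucs, exclude_quantile)
    retained = [r for r in ok if r.test_auc >= cut]

    counts: dict[str, int] = {}
    abs_sums: dict[str, float] = {}
    signed_sums: dict[str, float] = {}
    for r in retained:
        for f in r.selected:
            counts[f] = counts.get(f, 0) + 1
            abs_sums[f] = abs_sums.get(f, 0.0) + r.shap_mean_abs[f]
            signed_sums[f] = signed_sums.get(f, 0.0) + r.shap_mean[f]

    features = sorted(counts)
    count = pd.Series({f: counts[f] for f in features}, dtype=int)
    freq = count / len(retained)
    mean_abs = pd.Series({f: abs_sums[f] / counts[f] for f in features})
    mean_signed = pd.Series({f: signed_sums[f] / counts[f] for f in features})
    consensus = sorted(
        [f for f in features if freq[f] > majority],
        key=lambda f: (-mean_abs[f], f),
    )
    return StabilitySummary(
        retained_indices=[r.index for r in retained],
        selection_count=count,
        selection_frequency=freq,
        mean_abs_shap=mean_abs,
        mean_shap=mean_signed,
        consensus=consensus,
        median_test_auc=float(np.median(aucs)),
        test_auc_sd=float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        n_successful=len(ok),
        n_failed=len(records) - len(ok),
    )


# ---------------------------------------------------------------------------
# model / results surface


class StabilitySelection:
    """Consensus feature-selection model over repeated stratified partitions.

    Parameters
    ----------
    matrix : QuantMatrix
        Filtered, imputed concentration matrix with binary group labels.
    n_iterations : int
        Number of train/test partitions R (30 in the reference design).
    train_fraction : float
        Training share of each partition (0.70).
    exclude_quantile, majority : float
        Aggregation rule: drop rounds below the AUC quantile, keep features
        selected in strictly more than ``majority`` of the rest.
    boruta_params, model_grids, shap_permutations
        Passed through to the per-round stages.

    Examples
    --------
    >>> res = StabilitySelection(matrix, n_iterations=30).fit(seed=7)
    >>> res.consensus
    ['Lys', 'Ser', ...]
    """

    def __init__(
        self,
        matrix: QuantMatrix,
        n_iterations: int = 30,
        train_fraction: float = 0.70,
        exclude_quantile: float = 0.25,
        majority: float = 0.5,
        boruta_params: dict | None = None,
        model_grids: list | None = None,
        shap_permutations: int = 50,
    ) -> None:
        self.matrix = matrix
        self.n_iterations = n_iterations
        self.train_fraction = train_fraction
        self.exclude_quantile = exclude_quantile
        self.majority = majority
        self.boruta_params = boruta_params
        self.model_grids = model_grids
        self.shap_permutations = shap_permutations

    @classmethod
    def from_dataframe(
        cls, values: pd.DataFrame, groups: pd.Series, **kwargs
    ) -> "StabilitySelection":
        """Build from a plain concentration table and a group label series."""
        loq = pd.DataFrame(
            {"lloq": 0.0, "uloq": np.inf},
            index=pd.Index(values.columns, name="metabolite_id"),
        )
        samples = pd.DataFrame(
            {
                "group": groups.reindex(values.index),
                "tissue": "plasma",
                "weight_mg": np.nan,
            },
            index=values.index,
        )
        return cls(QuantMatrix(values=values, loq=loq, samples=samples), **kwargs)

    def fit(self, seed: int = 0, verbose: bool = False) -> "StabilityResults":
        plans = make_splits(
            self.matrix, R=self.n_iterations,
            train_fraction=self.train_fraction, seed=seed,
        )
        records = []
        for plan in plans:
            rec = run_iteration(
                plan,
                self.matrix,
                boruta_params=self.boruta_params,
                grids=self.model_grids,
                shap_permutations=self.shap_permutations,
            )
            if verbose:
                print(
                    f"round {rec.index:2d}: "
                    + ("failed" if rec.failed else
                       f"{len(rec.selected)} features, test AUC {rec.test_auc:.3f}")
                )
            records.append(rec)
        return StabilityResults(self, plans, records, seed)


class StabilityResults:
    """Fitted results: per-round records plus the aggregated consensus."""

    def __init__(self, model, plans, records, seed) -> None:
        self.model = model
        self.plans = plans
        self.records = records
        self.seed = seed
        if any(not r.failed for r in records):
            self.summary_ = aggregate(
                records,
                exclude_quantile=model.exclude_quantile,
                majority=model.majority,
            )
        else:
            # every round failed to confirm a feature (typical of null data
            # under the strict selector): empty consensus, no AUC
            empty = pd.Series(dtype=float)
            self.summary_ = StabilitySummary(
                retained_indices=[],
                selection_count=pd.Series(dtype=int),
                selection_frequency=empty,
                mean_abs_shap=empty,
                mean_shap=empty,
                consensus=[],
                median_test_auc=float("nan"),
                test_auc_sd=float("nan"),
                n_successful=0,
                n_failed=len(records),
            )

    # convenience accessors -------------------------------------------------

    @property
    def consensus(self) -> list[str]:
        return self.summary_.consensus

    @property
    def selection_frequency(self) -> pd.Series:
        return self.summary_.selection_frequency

    @property
    def median_test_auc(self) -> float:
        return self.summary_.median_test_auc

    def selection_counts_all(self) -> pd.Series:
        """Selection counts over *all* rounds (pre-exclusion), the input the
        over-representation step uses."""
        counts: dict[str, int] = {}
        for r in self.records:
            for f in r.selected:
                counts[f] = counts.get(f, 0) + 1
        return pd.Series(counts, dtype=int).sort_values(ascending=False)

    def summary(self) -> str:
        s = self.summary_
        lines = [
            "Stability selection results",
            "===========================",
            f"rounds: {len(self.records)}  successful: {s.n_successful}  "
            f"failed: {s.n_failed}  retained after AUC screen: "
            f"{len(s.retained_indices)}",
            f"median test AUC: {s.median_test_auc:.3f} (+/- {s.test_auc_sd:.3f})",
            f"consensus signature ({len(s.consensus)} features):",
            "",
            f"{'feature':<24}{'freq':>8}{'mean|phi|':>12}{'mean phi':>12}",
        ]
        for f in s.consensus:
            lines.append(
                f"{f:<24}{s.selection_frequency[f]:>8.2f}"
                f"{s.mean_abs_shap[f]:>12.4f}{s.mean_shap[f]:>12.4f}"
            )
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "records": [r.to_dict() for r in self.records],
            "retained_indices": self.summary_.retained_indices,
            "consensus": self.summary_.consensus,
            "median_test_auc": self.summary_.median_test_auc,
            "test_auc_sd": self.summary_.test_auc_sd,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def consensus_table(self) -> pd.DataFrame:
        return self.summary_.consensus_table()
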