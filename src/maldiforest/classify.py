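"""Random Forest classification, repeated cross-validation and median-MDA RFE.

Tree induction is delegated to scikit-learn's ``RandomForestClassifier``
(bootstrap sampling, ``mtry = floor(sqrt(p))`` candidate features per
split).  Everything the method contract actually relies on is computed
here on top of the fitted trees:

* out-of-bag (OOB) vote fractions — for each training sample, the share
  of trees in whose bootstrap it did not appear that vote "case";
* the OOB error under the strict >50% major-vote rule;
* Breiman-style mean decrease in accuracy (MDA): per tree, the drop in
  OOB accuracy when one feature's OOB values are permuted, averaged over
  trees; the z-score divides the mean by its standard error over trees.

Model assessment is repeated stratified k-fold cross-validation: each
repetition partitions the samples into stratified folds, so with 10
repetitions every sample is scored exactly 10 times and a 58-sample
cohort yields 580 pooled predictions (350 on 35 cases, 230 on 23
controls).  Any feature selection is applied inside the training fold
only.  The ROC/AUC operates on vote fractions: the AUC is the
tie-corrected probability that a random case receives a higher vote
fraction than a random control.

Recursive feature elimination refits the forest and removes all features
whose MDA lies strictly below the median MDA of the current set, records
every set, scores each recorded set by repeated CV, and selects the set
with the highest pooled AUC (ties go to the smaller set).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .peaks import FeatureMatrix
from .preprocess import CASE, CONTROL

DEFAULT_N_TREES = 500
DEFAULT_N_FOLDS = 10
DEFAULT_N_REPETITIONS = 10

_SEED_MOD = 2**31 - 1


def derive_seeds(seed: int, n: int, stream: str = "") -> np.ndarray:
    """Derive n reproducible child seeds (< 2^31) from one pipeline seed."""
    entropy = [seed] + [ord(c) for c in stream]
    return np.random.SeedSequence(entropy).generate_state(n) % _SEED_MOD


def major_vote(vote_fraction: float) -> str:
    """Class assignment by strict major vote: case iff the fraction > 50%."""
    if not 0.0 <= vote_fraction <= 1.0:
        raise ValueError(f"vote fraction must lie in [0, 1], got {vote_fraction}")
    return CASE if vote_fraction > 0.5 else CONTROL


def vote_auc(vote_fractions: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC of the case vote fractions.

    Equals (concordant pairs + 0.5 * ties) / (n_case * n_control); ties in
    the fractions receive half credit via midranks.
    """
    fractions = np.asarray(vote_fractions, dtype=float)
    is_case = np.asarray(labels) == CASE
    n1, n0 = int(is_case.sum()), int((~is_case).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(fractions)
    return float((ranks[is_case].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class ConfusionMetrics:
    accuracy: float  # percent, 1 decimal
    sensitivity: float
    specificity: float
    n_correct: int
    n_total: int
    n_correct_cases: int
    n_cases: int
    n_correct_controls: int
    n_controls: int


def confusion_metrics(predictions: np.ndarray, labels: np.ndarray) -> ConfusionMetrics:
    """Pooled accuracy/sensitivity/specificity, as percentages to 1 decimal."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    is_case = labels == CASE
    n_cases, n_controls = int(is_case.sum()), int((~is_case).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("both classes must be present in the labels")
    correct = predictions == labels
    tp = int(correct[is_case].sum())
    tn = int(correct[~is_case].sum())
    total = predictions.size
    return ConfusionMetrics(
        accuracy=round(100.0 * (tp + tn) / total, 1),
        sensitivity=round(100.0 * tp / n_cases, 1),
        specificity=round(100.0 * tn / n_controls, 1),
        n_correct=tp + tn,
        n_total=total,
        n_correct_cases=tp,
        n_cases=n_cases,
        n_correct_controls=tn,
        n_controls=n_controls,
    )


@dataclass
class ForestModel:
    """A fitted ensemble with its OOB diagnostics and MDA importances."""

    forest: RandomForestClassifier
    feature_ids: list[str]
    n_trees: int
    oob_error: float
    oob_votes: np.ndarray  # per training sample, case vote fraction
    mda_raw: np.ndarray | None = None
    mda_z: np.ndarray | None = None

    def vote_fractions(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting case for each row of X."""
        proba = self.forest.predict_proba(np.asarray(X, dtype=float))
        case_col = list(self.forest.classes_).index(1)
        return proba[:, case_col]

    def ranked_panel(self) -> pd.DataFrame:
        """Features ranked by MDA z-score, descending (panel-table shape)."""
        if self.mda_z is None:
            raise ValueError("model was fitted without importance computation")
        order = np.argsort(-self.mda_z, kind="stable")
        return pd.DataFrame(
            {
                "peak_id": [self.feature_ids[i] for i in order],
                "mda_z_score": self.mda_z[order],
                "mda_raw": self.mda_raw[order],
            }
        )


def _oob_masks(forest: RandomForestClassifier, n_samples: int) -> list[np.ndarray]:
    masks = []
    for sample_indices in forest.estimators_samples_:
        mask = np.ones(n_samples, dtype=bool)
        mask[sample_indices] = False
        masks.append(mask)
    return masks


def fit_forest(
    features: FeatureMatrix,
    n_trees: int = DEFAULT_N_TREES,
    mtry: int | None = None,
    seed: int = 0,
    compute_importance: bool = True,
) -> ForestModel:
    """Fit a Random Forest and compute OOB votes, OOB error and MDA.

    Requires at least two samples per class and one feature.  Fully
    deterministic for a given seed.
    """
    X, y = features.values, features.y
    if features.n_features < 1:
        raise ValueError("empty feature set")
    if np.unique(y).size < 2 or min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least two samples of each class")
    mtry = mtry if mtry is not None else max(1, int(np.sqrt(features.n_features)))
    forest_seed, perm_seed = derive_seeds(seed, 2, "forest")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        bootstrap=True,
        random_state=int(forest_seed),
        n_jobs=1,
    ).fit(X, y)

    n = X.shape[0]
    masks = _oob_masks(forest, n)
    vote_case = np.zeros(n)
    vote_total = np.zeros(n)
    tree_preds: list[np.ndarray] = []
    for tree, mask in zip(forest.estimators_, masks):
        if not mask.any():
            tree_preds.append(np.empty(0, dtype=int))
            continue
        pred = tree.predict(X[mask]).astype(int)
        tree_preds.append(pred)
        vote_case[mask] += pred
        vote_total[mask] += 1
    with np.errstate(invalid="ignore"):
        oob_votes = np.where(vote_total > 0, vote_case / np.maximum(vote_total, 1), 0.5)
    oob_pred = oob_votes > 0.5
    oob_error = float(np.mean(oob_pred != (y == 1)))

    mda_raw = mda_z = None
    if compute_importance:
        p = features.n_features
        rng = np.random.default_rng(int(perm_seed))
        decreases = np.zeros((n_trees, p))
        for t, (tree, mask) in enumerate(zip(forest.estimators_, masks)):
            n_oob = int(mask.sum())
            if n_oob == 0:
                continue
            X_oob = X[mask]
            y_oob = y[mask]
            base_acc = float(np.mean(tree_preds[t] == y_oob))
            # permuting a feature the tree never splits on cannot change its
            # predictions, so the accuracy decrease is exactly 0 for those;
            # only the used features need the (batched) permuted predict
            used = np.unique(tree.tree_.feature)
            used = used[used >= 0]
            k = used.size
            if k == 0:
                continue
            tiled = np.tile(X_oob, (k, 1))
            perm = rng.permuted(np.tile(np.arange(n_oob), (k, 1)), axis=1)
            rows = (np.arange(k)[:, None] * n_oob + np.arange(n_oob)[None, :]).ravel()
            cols = np.repeat(used, n_oob)
            tiled[rows, cols] = X_oob[perm.ravel(), cols]
            pred = tree.predict(tiled).astype(int).reshape(k, n_oob)
            decreases[t, used] = base_acc - (pred == y_oob[None, :]).mean(axis=1)
        mda_raw = decreases.mean(axis=0)
        sd = decreases.std(axis=0, ddof=1)
        se = sd / np.sqrt(n_trees)
        with np.errstate(divide="ignore", invalid="ignore"):
            mda_z = np.where(se > 0, mda_raw / np.where(se > 0, se, 1.0), 0.0)

    return ForestModel(
        forest=forest,
        feature_ids=list(features.peak_ids),
        n_trees=n_trees,
        oob_error=oob_error,
        oob_votes=oob_votes,
        mda_raw=mda_raw,
        mda_z=mda_z,
    )


@dataclass
class CVResult:
    """Pooled predictions and metrics of repeated stratified k-fold CV."""

    predictions: pd.DataFrame  # repetition, sample_id, label, vote_fraction, prediction
    auc: float
    metrics: ConfusionMetrics
    n_folds: int
    n_repetitions: int

    @property
    def n_predictions(self) -> int:
        return len(self.predictions)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_folds": self.n_folds,
            "n_repetitions": self.n_repetitions,
            "auc": self.auc,
            "metrics": self.metrics.__dict__,
            "predictions": self.predictions.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CVResult":
        payload = json.loads(Path(path).read_text())
        return cls(
            predictions=pd.DataFrame(payload["predictions"]),
            auc=payload["auc"],
            metrics=ConfusionMetrics(**payload["metrics"]),
            n_folds=payload["n_folds"],
            n_repetitions=payload["n_repetitions"],
        )


def repeated_cv(
    features: FeatureMatrix,
    n_folds: int = DEFAULT_N_FOLDS,
    n_repetitions: int = DEFAULT_N_REPETITIONS,
    n_trees: int = DEFAULT_N_TREES,
    mtry: int | None = None,
    selector=None,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold CV with optional in-fold feature selection.

    Each repetition draws an independent stratified partition, so every
    sample lands in the test set exactly once per repetition.  ``selector``
    is called as ``selector(train_features, fold_seed) -> list of feature
    ids`` using training data only; the forest is then fit on the selected
    columns and the held-out fold is scored.  Predictions are pooled over
    all repetitions: the AUC uses the pooled vote fractions, the confusion
    metrics the pooled major-vote class assignments.
    """
    y = features.y
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least two samples of each class")
    rep_seeds = derive_seeds(seed, n_repetitions, "cv-rep")
    records: list[tuple] = []
    for rep, rep_seed in enumerate(rep_seeds):
        splitter = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=int(rep_seed % _SEED_MOD)
        )
        fold_seeds = derive_seeds(int(rep_seed), n_folds, "cv-fold")
        for fold, (train_idx, test_idx) in enumerate(splitter.split(features.values, y)):
            if np.unique(y[train_idx]).size < 2:
                raise ValueError("a training fold lost one class; reduce n_folds")
            train = FeatureMatrix(
                values=features.values[train_idx],
                sample_ids=[features.sample_ids[i] for i in train_idx],
                labels=features.labels[train_idx],
                peak_ids=list(features.peak_ids),
            )
            fold_seed = int(fold_seeds[fold])
            if selector is not None:
                selected = list(selector(train, fold_seed))
                if not selected:
                    raise ValueError("selector returned an empty feature set")
                train = train.select(selected)
                test_values = features.select(selected).values[test_idx]
            else:
                test_values = features.values[test_idx]
            model = fit_forest(
                train,
                n_trees=n_trees,
                mtry=mtry,
                seed=fold_seed,
                compute_importance=False,
            )
            fractions = model.vote_fractions(test_values)
            for i, frac in zip(test_idx, fractions):
                records.append(
                    (
                        rep,
                        features.sample_ids[i],
                        str(features.labels[i]),
                        float(frac),
                        major_vote(float(frac)),
                    )
                )
    predictions = pd.DataFrame(
        records, columns=["repetition", "sample_id", "label", "vote_fraction", "prediction"]
    )
    auc = vote_auc(
        predictions["vote_fraction"].to_numpy(), predictions["label"].to_numpy()
    )
    metrics = confusion_metrics(
        predictions["prediction"].to_numpy(), predictions["label"].to_numpy()
    )
    return CVResult(
        predictions=predictions,
        auc=auc,
        metrics=metrics,
        n_folds=n_folds,
        n_repetitions=n_repetitions,
    )


def below_median_mask(mda: np.ndarray) -> np.ndarray:
    """Keep-mask of the median-MDA elimination rule.

    Features with MDA *strictly below* the median are removed; features
    exactly at the median survive.  For n pairwise-distinct values this
    removes floor((n-1)/2) features for odd n and n/2 for even n, e.g.
    153 -> 77 -> 39 -> 20 -> 10 -> 5 -> 3 -> 2.
    """
    mda = np.asarray(mda, dtype=float)
    return mda >= np.median(mda)


def elimination_schedule(
    features: FeatureMatrix,
    seed: int,
    n_trees: int = DEFAULT_N_TREES,
    min_size: int = 2,
) -> list[list[str]]:
    """Run median-MDA elimination, returning every recorded feature set.

    The first entry is the full set; elimination stops when fewer than
    ``min_size`` features would remain (or when no feature falls strictly
    below the median, which can happen with heavily tied importances).
    """
    if features.n_features < 2:
        raise ValueError("recursive elimination needs at least 2 features")
    step_seeds = derive_seeds(seed, 64, "rfe-step")
    current = features
    sets: list[list[str]] = [list(current.peak_ids)]
    step = 0
    while current.n_features >= 2:
        model = fit_forest(
            current, n_trees=n_trees, seed=int(step_seeds[step % 64]), compute_importance=True
        )
        keep = below_median_mask(model.mda_raw)
        n_keep = int(keep.sum())
        if n_keep < min_size or n_keep == current.n_features:
            break
        kept_ids = [pid for pid, k in zip(current.peak_ids, keep) if k]
        current = current.select(kept_ids)
        sets.append(kept_ids)
        step += 1
    return sets


@dataclass
class RFETrace:
    """The sequence of candidate feature sets with their CV performance."""

    feature_sets: list[list[str]]
    cv_results: list[CVResult]
    selected_index: int = field(init=False)

    def __post_init__(self) -> None:
        sizes = [len(s) for s in self.feature_sets]
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("recorded set sizes must be strictly decreasing")
        aucs = np.array([r.auc for r in self.cv_results])
        best = aucs.max()
        # ties on AUC break toward the smaller set (later entries are smaller)
        self.selected_index = int(np.flatnonzero(aucs >= best - 1e-12)[-1])

    @property
    def sizes(self) -> list[int]:
        return [len(s) for s in self.feature_sets]

    @property
    def selected_set(self) -> list[str]:
        return self.feature_sets[self.selected_index]

    @property
    def selected_cv(self) -> CVResult:
        return self.cv_results[self.selected_index]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sizes": self.sizes,
            "selected_index": self.selected_index,
            "entries": [
                {"features": fs, "auc": cv.auc, "metrics": cv.metrics.__dict__}
                for fs, cv in zip(self.feature_sets, self.cv_results)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def rfe(
    features: FeatureMatrix,
    seed: int = 0,
    n_trees_importance: int = DEFAULT_N_TREES,
    n_trees_cv: int = DEFAULT_N_TREES,
    n_folds: int = DEFAULT_N_FOLDS,
    n_repetitions: int = DEFAULT_N_REPETITIONS,
) -> RFETrace:
    """Median-MDA recursive feature elimination with CV-AUC model selection.

    Records the full elimination schedule, scores every recorded set by
    repeated stratified CV (selection already fixed, so no selector inside),
    and selects the set with the highest pooled AUC, breaking ties toward
    the smaller set.
    """
    sets = elimination_schedule(features, seed=seed, n_trees=n_trees_importance)
    score_seeds = derive_seeds(seed, len(sets), "rfe-score")
    cv_results = [
        repeated_cv(
            features.select(fs),
            n_folds=n_folds,
            n_repetitions=n_repetitions,
            n_trees=n_trees_cv,
            seed=int(s),
        )
        for fs, s in zip(sets, score_seeds)
    ]
    return RFETrace(feature_sets=sets, cv_results=cv_results)


def make_median_mda_selector(
    selected_fraction: float, n_trees: int = DEFAULT_N_TREES
):
    """In-fold selector: run the elimination schedule on the training fold
    and keep the recorded set whose size fraction is closest to the
    globally selected fraction (ties toward the smaller set)."""

    def selector(train: FeatureMatrix, fold_seed: int) -> list[str]:
        sets = elimination_schedule(train, seed=fold_seed, n_trees=n_trees)
        target = selected_fraction * train.n_features
        best = min(sets, key=lambda fs: (abs(len(fs) - target), len(fs)))
        return best

    return selector


def nested_performance(
    features: FeatureMatrix,
    seed: int = 0,
    selected_fraction: float | None = None,
    n_trees_importance: int = DEFAULT_N_TREES,
    n_trees_cv: int = DEFAULT_N_TREES,
    n_folds: int = DEFAULT_N_FOLDS,
    n_repetitions: int = DEFAULT_N_REPETITIONS,
) -> CVResult:
    """Generalization estimate with feature selection inside the CV loop.

    Every training fold reruns the median-MDA elimination from scratch and
    keeps the set whose size fraction matches the globally selected one
    (determined by a fresh :func:`rfe` run when ``selected_fraction`` is
    not supplied), so no class information leaks from the test folds.
    """
    if selected_fraction is None:
        trace = rfe(
            features,
            seed=seed,
            n_trees_importance=n_trees_importance,
            n_trees_cv=n_trees_cv,
            n_folds=n_folds,
            n_repetitions=n_repetitions,
        )
        selected_fraction = len(trace.selected_set) / features.n_features
    selector = make_median_mda_selector(selected_fraction, n_trees=n_trees_importance)
    return repeated_cv(
        features,
        n_folds=n_folds,
        n_repetitions=n_repetitions,
        n_trees=n_trees_cv,
        selector=selector,
        seed=seed,
    )


def roc_points(vote_fractions: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC curve from vote fractions, one row per distinct cutoff.

    A sample is called a case when its vote fraction exceeds the cutoff.
    Cutoffs descend from above the maximum score (point (0,0)) to below
    the minimum (point (1,1)); the trapezoidal area under the returned
    points equals :func:`vote_auc` exactly.
    """
    fractions = np.asarray(vote_fractions, dtype=float)
    is_case = np.asarray(labels) == CASE
    n1, n0 = int(is_case.sum()), int((~is_case).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs both classes present")
    distinct = np.unique(fractions)[::-1]
    cutoffs = np.concatenate(([distinct[0] + 1.0], distinct, [distinct[-1] - 1.0]))
    rows = []
    for cut in cutoffs:
        called = fractions > cut
        tpr = float(called[is_case].sum() / n1)
        fpr = float(called[~is_case].sum() / n0)
        rows.append((fpr, tpr, float(cut)))
    return pd.DataFrame(rows, columns=["fpr", "tpr", "cutoff"])
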