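"""Random-forest marker selection by repeated cross-validation error curves.

The procedure mirrors standard metagenome-wide association practice for
building a taxonomic disease classifier:

1.  Candidate features (the significantly different taxa) are ranked by
    impurity-based importance from a forest trained on all candidates.
2.  For each trial, a stratified k-fold cross-validation misclassification
    error is estimated for forests built on the top 1, 2, ..., K candidates,
    yielding one error curve per trial.
3.  The curves are averaged; with ``k_min`` the argmin of the average curve,
    the cutoff is ``average(k_min) + SD_across_trials(k_min)`` and the
    selected marker count ``k*`` is the smallest k whose average error lies
    at or below the cutoff. ``k* <= k_min`` by construction.
4.  A final forest on the ``k*`` selected markers yields per-sample disease
    probabilities — out-of-bag vote fractions on training samples (avoiding
    resubstitution optimism) and ordinary vote fractions on held-out
    samples — evaluated by ROC/AUC.

Defaults follow the classical randomForest configuration: 500 trees,
sqrt(p) features per split, unlimited depth; five folds and five trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .exceptions import DataError
from .profile_io import AbundanceTable

DEFAULT_RF_PARAMS: dict = {"n_estimators": 500, "max_features": "sqrt", "n_jobs": 1}

CASE, CONTROL = "case", "control"


def _as_binary(labels: pd.Series) -> np.ndarray:
    y = np.asarray([1 if v == CASE else 0 for v in labels])
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return y


def _forest(rf_params: dict | None, seed: int, **extra) -> RandomForestClassifier:
    params = dict(DEFAULT_RF_PARAMS)
    if rf_params:
        params.update(rf_params)
    params.update(extra)
    return RandomForestClassifier(random_state=seed, **params)


def _matrix(table: AbundanceTable, features, samples) -> np.ndarray:
    missing = [f for f in features if f not in table.data.index]
    if missing:
        raise DataError(f"missing marker feature(s): {missing[:5]}")
    return table.data.loc[list(features), list(samples)].to_numpy().T


def rank_candidates(
    table: AbundanceTable,
    labels: pd.Series,
    rf_params: dict | None = None,
    seed: int = 0,
) -> list[str]:
    """Order candidate features by decreasing mean impurity importance.

    A single forest is trained on all candidates; ties in importance are
    broken lexicographically so the ordering is invariant to the input
    feature order.
    """
    if len(table.features) < 2:
        raise ValueError("need at least two candidate features to rank")
    samples = [s for s in table.samples if s in labels.index]
    y = _as_binary(labels.loc[samples])
    # canonical (sorted) feature order so the ranking cannot depend on the
    # order features happen to appear in the input table
    features = sorted(table.features)
    x = _matrix(table, features, samples)
    forest = _forest(rf_params, seed).fit(x, y)
    imp = pd.Series(forest.feature_importances_, index=features)
    order = sorted(imp.index, key=lambda f: (-imp[f], f))
    return order


@dataclass
class ErrorCurveSet:
    """Per-trial CV error curves over nested top-k candidate sets."""

    candidates: list[str]  # in rank order; k indexes into this list
    errors: np.ndarray  # trials x K misclassification errors
    average: np.ndarray  # K
    sd: np.ndarray  # K, SD of trial errors at each k
    k_min: int  # 1-based argmin of the average curve
    cutoff: float  # average[k_min] + sd[k_min]
    k_star: int  # 1-based selected marker count

    @property
    def selected(self) -> list[str]:
        return self.candidates[: self.k_star]

    def to_frame(self) -> pd.DataFrame:
        k = np.arange(1, len(self.candidates) + 1)
        df = pd.DataFrame({"k": k, "average": self.average, "sd": self.sd})
        for t in range(self.errors.shape[0]):
            df[f"trial_{t + 1}"] = self.errors[t]
        return df


def cv_error_curves(
    table: AbundanceTable,
    labels: pd.Series,
    ordered_features: list[str],
    n_folds: int = 5,
    n_trials: int = 5,
    rf_params: dict | None = None,
    seed: int = 0,
) -> ErrorCurveSet:
    """Estimate misclassification-error curves over top-k feature sets.

    For each trial a fresh stratified fold assignment is drawn; for each k
    the pooled cross-validated error of a forest on the top-k candidates is
    recorded. Folds are stratified so every fold contains both classes.
    """
    samples = [s for s in table.samples if s in labels.index]
    y = _as_binary(labels.loc[samples])
    if min((y == 1).sum(), (y == 0).sum()) < n_folds:
        raise DataError(
            f"stratification impossible: a class has fewer than {n_folds} samples"
        )
    x_full = _matrix(table, ordered_features, samples)
    n_k = len(ordered_features)
    rng = np.random.SeedSequence(seed)
    trial_seeds = rng.generate_state(2 * n_trials).reshape(n_trials, 2) % (2**31)
    errors = np.empty((n_trials, n_k))
    for t in range(n_trials):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(trial_seeds[t, 0]))
        splits = list(skf.split(x_full, y))
        for k in range(1, n_k + 1):
            wrong = 0
            for f, (train, test) in enumerate(splits):
                forest = _forest(
                    rf_params, int((trial_seeds[t, 1] + 7919 * k + f) % (2**31))
                )
                forest.fit(x_full[train, :k], y[train])
                wrong += int((forest.predict(x_full[test, :k]) != y[test]).sum())
            errors[t, k - 1] = wrong / len(y)
    average = errors.mean(axis=0)
    sd = errors.std(axis=0, ddof=1) if n_trials > 1 else np.zeros(n_k)
    k_min = int(np.argmin(average)) + 1
    cutoff = float(average[k_min - 1] + sd[k_min - 1])
    k_star = int(np.nonzero(average <= cutoff + 1e-15)[0][0]) + 1
    return ErrorCurveSet(list(ordered_features), errors, average, sd, k_min, cutoff, k_star)


@dataclass
class MarkerModel:
    """A trained marker-set forest and its training context."""

    forest: RandomForestClassifier
    markers: list[str]
    train_samples: list[str]
    seed: int

    def predict_probability(self, table: AbundanceTable) -> pd.Series:
        """Vote-fraction disease probability for each sample in ``table``."""
        x = _matrix(table, self.markers, table.samples)
        proba = self.forest.predict_proba(x)[:, list(self.forest.classes_).index(1)]
        return pd.Series(proba, index=table.samples, name="p_case")


@dataclass
class MarkerSelectionResult:
    """Selected markers with probabilities, ROC points and AUC."""

    markers: list[str]
    probabilities: pd.Series  # per-sample predicted disease probability
    labels: pd.Series  # case/control per sample
    roc_points: pd.DataFrame  # fpr / tpr / threshold
    auc: float
    curve_set: ErrorCurveSet | None = None
    model: MarkerModel | None = None
    split: "TrainTestSplit | None" = None


def fit_final_classifier(
    table: AbundanceTable,
    labels: pd.Series,
    selected_markers: list[str],
    rf_params: dict | None = None,
    seed: int = 0,
) -> tuple[MarkerModel, MarkerSelectionResult]:
    """Train the final forest on the selected markers only.

    Training-sample probabilities are out-of-bag vote fractions; samples
    without any out-of-bag tree (possible at very small tree counts) fall
    back to 0.5.
    """
    if not selected_markers:
        raise ValueError("selected marker set is empty")
    samples = [s for s in table.samples if s in labels.index]
    y = _as_binary(labels.loc[samples])
    x = _matrix(table, selected_markers, samples)
    forest = _forest(rf_params, seed, oob_score=True, bootstrap=True)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        forest.fit(x, y)
        oob = forest.oob_decision_function_[:, list(forest.classes_).index(1)]
    oob = np.where(np.isnan(oob), 0.5, oob)
    probs = pd.Series(oob, index=samples, name="p_case")
    model = MarkerModel(forest, list(selected_markers), samples, seed)
    roc_points, auc = roc_auc(probs, labels.loc[samples])
    result = MarkerSelectionResult(
        list(selected_markers), probs, labels.loc[samples], roc_points, auc, model=model
    )
    return model, result


def roc_auc(probabilities: pd.Series, labels: pd.Series) -> tuple[pd.DataFrame, float]:
    """ROC points at every distinct threshold and the Mann-Whitney AUC.

    Ties between case and control scores count one half, so the AUC equals
    the concordance probability U / (n_case * n_control).
    """
    common = probabilities.index.intersection(labels.index)
    y = _as_binary(labels.loc[common])
    scores = probabilities.loc[common].to_numpy(dtype=float)
    fpr, tpr, thresholds = roc_curve(y, scores, drop_intermediate=False)
    auc = float(roc_auc_score(y, scores))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return points, auc


@dataclass(frozen=True)
class TrainTestSplit:
    """Reproducible discovery/validation split descriptor."""

    train_case: tuple[str, ...]
    train_control: tuple[str, ...]
    test_case: tuple[str, ...]
    test_control: tuple[str, ...]
    seed: int

    @property
    def train(self) -> list[str]:
        return list(self.train_case) + list(self.train_control)

    @property
    def test(self) -> list[str]:
        return list(self.test_case) + list(self.test_control)


def make_train_test_split(
    case_ids,
    control_ids,
    validation_case_ids,
    n_control_holdout: int,
    seed: int = 0,
) -> TrainTestSplit:
    """Form a train/test split in the validation design of the study:
    the test set is the validation-cohort cases plus ``n_control_holdout``
    controls sampled from the discovery cohort; the training set is all
    discovery cases plus the remaining controls.
    """
    case_ids = list(case_ids)
    control_ids = list(control_ids)
    validation_case_ids = list(validation_case_ids)
    overlap = set(case_ids) & set(validation_case_ids)
    if overlap:
        raise DataError(f"discovery/validation case overlap: {sorted(overlap)[:3]}")
    if n_control_holdout > len(control_ids):
        raise ValueError("n_control_holdout exceeds the number of controls")
    rng = np.random.default_rng(seed)
    holdout = sorted(rng.choice(control_ids, size=n_control_holdout, replace=False))
    remaining = [c for c in control_ids if c not in set(holdout)]
    return TrainTestSplit(
        tuple(case_ids), tuple(remaining), tuple(validation_case_ids), tuple(holdout), seed
    )


def select_markers(
    table: AbundanceTable,
    labels: pd.Series,
    candidates: list[str],
    n_folds: int = 5,
    n_trials: int = 5,
    rf_params: dict | None = None,
    seed: int = 0,
) -> MarkerSelectionResult:
    """Run the full marker-selection procedure on a training cohort."""
    sub = table.subset_features(candidates)
    order = rank_candidates(sub, labels, rf_params=rf_params, seed=seed)
    curves = cv_error_curves(
        sub, labels, order, n_folds=n_folds, n_trials=n_trials, rf_params=rf_params, seed=seed
    )
    model, result = fit_final_classifier(
        table, labels, curves.selected, rf_params=rf_params, seed=seed
    )
    result.curve_set = curves
    return result
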