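"""Classification pipelines: splitting, cross-validation, a-priori
feature-set selection, randomized hyperparameter search, final training
and multiclass/binary evaluation.

The workflow mirrors a standard supervised protocol: records are split
80/20 into training and test partitions; a development set of 12.5% of
the training rows is used — and only it — for feature-set selection
(5-fold CV with regularized logistic regression against benchmark
feature sets) and hyperparameter optimization (randomized search scored
by 5-fold CV repeated three times on F1). Final models are trained on
the full training set (the dev rows included) and evaluated once on the
untouched test set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from . import evaluate
from .encode import NAME_GROUPS, PRESETS, CensusFeaturizer, FeatureSetSpec, resolve_spec
from .ingest import (
    BINARY_TARGETS,
    EthnicityLabel,
    PersonRecord,
    binarize,
    drop_incomplete_and_duplicates,
    records_from_frame,
)

logger = logging.getLogger(__name__)

ALGORITHMS = ("LR", "SVC", "NB", "DT", "RF")
#: DT and RF are available for research but excluded from default reports.
DEFAULT_ALGORITHMS = ("LR", "SVC", "NB")

#: Default randomized-search spaces (("loguniform", lo, hi) or ("choice", [...])).
DEFAULT_SEARCH_SPACES: dict[str, dict[str, tuple]] = {
    "LR": {"C": ("loguniform", 1e-3, 1e3), "penalty": ("choice", ["l1", "l2"])},
    "SVC": {"C": ("loguniform", 1e-3, 1e3)},
    "NB": {"alpha": ("loguniform", 1e-3, 10.0)},
    "DT": {"max_depth": ("choice", [5, 10, 20, 40, None])},
    "RF": {
        "n_estimators": ("choice", [50, 100, 200]),
        "max_depth": ("choice", [10, 20, None]),
    },
}


@dataclass
class SplitConfig:
    test_fraction: float = 0.20
    dev_fraction_of_train: float = 0.125
    seed: int = 0

    def validate(self) -> None:
        for name in ("test_fraction", "dev_fraction_of_train"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class CVConfig:
    k: int = 5
    repeats: int = 3  # used by hyperparameter search only
    n_candidates: int = 20

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_sizes(
    n: int, test_fraction: float = 0.20, dev_fraction_of_train: float = 0.125
) -> tuple[int, int, int]:
    """Planned (train, test, dev) partition sizes with half-up rounding."""
    n_test = _round_half_up(test_fraction * n)
    n_train = n - n_test
    n_dev = _round_half_up(dev_fraction_of_train * n_train)
    return n_train, n_test, n_dev


def split_data(
    records: pd.DataFrame, config: SplitConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Uniform random train/test split plus a dev subsample of the train set.

    The dev set is a subset of the training set; the test set is disjoint
    from both. Reproducible from ``config.seed``.
    """
    config.validate()
    n = len(records)
    if n < 10:
        raise ValueError("need at least 10 records to split")
    n_train, n_test, n_dev = split_sizes(
        n, config.test_fraction, config.dev_fraction_of_train
    )
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    test_idx = perm[:n_test]
    train_idx = perm[n_test:]
    dev_idx = train_idx[rng.permutation(n_train)[:n_dev]]
    return (
        records.iloc[np.sort(train_idx)],
        records.iloc[np.sort(dev_idx)],
        records.iloc[np.sort(test_idx)],
    )


class EthnicityClassifier(ClassifierMixin, BaseEstimator):
    """Featurizer + classifier over raw census-style records.

    ``X`` is a DataFrame with ``name``, ``location`` and ``sex`` columns;
    ``y`` is a sequence of class labels (the ten ethnicity categories for
    the multiclass pipeline, or 0/1 for a binary target). The featurizer
    is refitted on every call to :meth:`fit`, so cross-validation never
    leaks encoder state across folds.

    Parameters mirror the underlying scikit-learn models: ``C``/``penalty``
    for regularized logistic regression (LR) and the linear C-support
    vector classifier (SVC), ``alpha`` for Bernoulli naive Bayes (NB),
    ``max_depth``/``n_estimators`` for the optional tree models (DT, RF).
    """

    def __init__(
        self,
        feature_set="All name and location features",
        algorithm: str = "LR",
        C: float = 1.0,
        penalty: str = "l2",
        alpha: float = 1.0,
        max_depth=None,
        n_estimators: int = 100,
        class_weight=None,
        dedup_tokens: bool = True,
        strip_apostrophes: bool = True,
        max_iter: int = 100,
        random_state=None,
    ):
        self.feature_set = feature_set
        self.algorithm = algorithm
        self.C = C
        self.penalty = penalty
        self.alpha = alpha
        self.max_depth = max_depth
        self.n_estimators = n_estimators
        self.class_weight = class_weight
        self.dedup_tokens = dedup_tokens
        self.strip_apostrophes = strip_apostrophes
        self.max_iter = max_iter
        self.random_state = random_state

    def _make_model(self):
        if self.algorithm == "LR":
            if self.penalty not in ("l1", "l2"):
                raise ValueError("penalty must be 'l1' or 'l2'")
            # liblinear: coordinate descent handles both penalties on
            # sparse input efficiently at any regularization strength;
            # multiclass problems are wrapped one-vs-rest in fit().
            return LogisticRegression(
                C=self.C,
                l1_ratio=1.0 if self.penalty == "l1" else 0.0,
                solver="liblinear",
                max_iter=self.max_iter,
                class_weight=self.class_weight,
                random_state=self.random_state,
            )
        if self.algorithm == "SVC":
            return LinearSVC(
                C=self.C,
                class_weight=self.class_weight,
                max_iter=max(self.max_iter, 2000),
                random_state=self.random_state,
            )
        if self.algorithm == "NB":
            return BernoulliNB(alpha=self.alpha)
        if self.algorithm == "DT":
            return DecisionTreeClassifier(
                max_depth=self.max_depth,
                class_weight=self.class_weight,
                random_state=self.random_state,
            )
        if self.algorithm == "RF":
            return RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                class_weight=self.class_weight,
                random_state=self.random_state,
            )
        raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training data contains a single class")
        self.featurizer_ = CensusFeaturizer(
            feature_set=self.feature_set,
            dedup_tokens=self.dedup_tokens,
            strip_apostrophes=self.strip_apostrophes,
            random_state=self.random_state,
        )
        M = self.featurizer_.fit_transform(X)
        model = self._make_model()
        if self.algorithm == "LR" and len(np.unique(y)) > 2:
            from sklearn.multiclass import OneVsRestClassifier

            model = OneVsRestClassifier(model)
        self.model_ = model.fit(M, y)
        self.classes_ = self.model_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        # classes_ is lexicographically sorted and argmax takes the first
        # maximum, so score ties resolve to the smallest label.
        check_is_fitted(self, "model_")
        return self.model_.predict(self.featurizer_.transform(X))

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Continuous class scores (records x classes; 1-D for binary).

        Probabilities where the model provides them, signed decision-
        function values otherwise (LinearSVC).
        """
        check_is_fitted(self, "model_")
        M = self.featurizer_.transform(X)
        if hasattr(self.model_, "predict_proba"):
            scores = self.model_.predict_proba(M)
        else:
            scores = self.model_.decision_function(M)
            if scores.ndim == 1:  # binary decision function
                return scores
            return scores
        if scores.shape[1] == 2:
            return scores[:, 1]
        return scores

    def multiclass_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Scores as a (records x classes) matrix even for binary targets."""
        check_is_fitted(self, "model_")
        M = self.featurizer_.transform(X)
        if hasattr(self.model_, "predict_proba"):
            return self.model_.predict_proba(M)
        scores = self.model_.decision_function(M)
        if scores.ndim == 1:
            return np.column_stack([-scores, scores])
        return scores


def cross_validate(
    X: pd.DataFrame,
    y,
    feature_set,
    algorithm: str = "LR",
    cv: Optional[CVConfig] = None,
    seed: int = 0,
    repeats: int = 1,
    stratified: bool = True,
    **alg_params,
) -> dict[str, float]:
    """K-fold cross-validation returning fold-mean overall metrics.

    Encoders are refitted inside every fold (the featurizer lives inside
    the estimator). Folds are stratified by class by default so rare
    classes appear in every fold; a fold whose training part still misses
    a class logs a warning, and classes absent from a fold's truth enter
    that fold's overall row with zero support.
    """
    cv = cv or CVConfig()
    cv.validate()
    y = np.asarray(y)
    if cv.k > len(y):
        raise ValueError("k exceeds the number of records")
    labels = sorted(np.unique(y).astype(str))
    if stratified and repeats > 1:
        splitter = RepeatedStratifiedKFold(n_splits=cv.k, n_repeats=repeats, random_state=seed)
    elif stratified:
        splitter = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=seed)
    else:
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=cv.k, shuffle=True, random_state=seed)
    fold_metrics: list[dict[str, float]] = []
    base = EthnicityClassifier(
        feature_set=feature_set, algorithm=algorithm, random_state=seed, **alg_params
    )
    for fold, (tr, te) in enumerate(splitter.split(np.zeros(len(y)), y)):
        y_tr, y_te = y[tr], y[te]
        missing = set(labels) - set(np.unique(y_tr).astype(str))
        if missing:
            logger.warning("fold %d training part misses classes %s", fold, sorted(missing))
        clf = clone(base).fit(X.iloc[tr], y_tr)
        pred = clf.predict(X.iloc[te])
        report = evaluate.multiclass_report(
            y_te.astype(str), pred.astype(str), labels
        )
        fold_metrics.append(report.overall)
    return {
        name: float(np.nanmean([m.get(name, np.nan) for m in fold_metrics]))
        for name in fold_metrics[0]
    }


def relative_gain(metric_new: float, metric_ref: float) -> float:
    """Percent improvement of *metric_new* over *metric_ref*
    (reference as denominator): ``100 * (new/ref - 1)``."""
    if metric_ref <= 0:
        raise ValueError("reference metric must be positive")
    return 100.0 * (metric_new / metric_ref - 1.0)


_GROUP_PRESET = {
    "basic": "Basic name features",
    "substrings": "Name substring features",
    "numeric": "Numeric name features",
    "phonetic": "Phonetic name features",
}


def select_feature_sets(
    X_dev: pd.DataFrame,
    y_dev,
    cv: Optional[CVConfig] = None,
    seed: int = 0,
    threshold_pct: float = 10.0,
) -> tuple[list[FeatureSetSpec], dict]:
    """A-priori feature-set selection on the dev set.

    Every candidate feature set is scored by 5-fold CV with regularized
    logistic regression. Each individual name group enters the final
    "All name features" set only if its F1 exceeds the dummy benchmark's
    F1 by at least ``threshold_pct`` percent (dummy as denominator).
    "All location features" are then added to form "All name and location
    features". Whether the combined set beats "All name features" by the
    same margin is reported as a confirmation, but both final sets proceed
    regardless.
    """
    cv = cv or CVConfig()
    scores: dict[str, dict[str, float]] = {}
    for preset_name in PRESETS:
        scores[preset_name] = cross_validate(
            X_dev, y_dev, preset_name, "LR", cv=cv, seed=seed
        )
        logger.info("selection CV %-35s F1=%.3f", preset_name, scores[preset_name]["f1"])
    dummy_f1 = scores["Dummy features only"]["f1"]

    def gain_over_dummy(f1: float) -> float:
        if dummy_f1 <= 0:
            return float("inf") if f1 > 0 else 0.0
        return relative_gain(f1, dummy_f1)

    admitted = [
        group
        for group in NAME_GROUPS
        if gain_over_dummy(scores[_GROUP_PRESET[group]]["f1"]) >= threshold_pct
    ]
    all_name = FeatureSetSpec("All name features", frozenset(admitted))
    name_loc = FeatureSetSpec(
        "All name and location features", frozenset(admitted) | {"location"}
    )
    # Confirmation uses the composed sets (identical to the presets when
    # every name group was admitted, so reuse those CV scores).
    if set(admitted) == set(NAME_GROUPS):
        f1_name = scores["All name features"]["f1"]
        f1_name_loc = scores["All name and location features"]["f1"]
    else:
        f1_name = cross_validate(X_dev, y_dev, all_name, "LR", cv=cv, seed=seed)["f1"]
        f1_name_loc = cross_validate(X_dev, y_dev, name_loc, "LR", cv=cv, seed=seed)["f1"]
    confirmation_gain = (
        relative_gain(f1_name_loc, f1_name) if f1_name > 0 else float("inf")
    )
    report = {
        "cv_scores": {k: v["f1"] for k, v in scores.items()},
        "dummy_f1": dummy_f1,
        "gains_over_dummy_pct": {
            _GROUP_PRESET[g]: gain_over_dummy(scores[_GROUP_PRESET[g]]["f1"])
            for g in NAME_GROUPS
        },
        "admitted_groups": admitted,
        "confirmation_gain_pct": confirmation_gain,
        "confirmation_holds": confirmation_gain >= threshold_pct,
    }
    return [all_name, name_loc], report


def _draw_params(space: dict[str, tuple], rng: np.random.Generator) -> dict:
    params = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "loguniform":
            lo, hi = spec[1], spec[2]
            params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        elif kind == "choice":
            options = spec[1]
            params[name] = options[int(rng.integers(0, len(options)))]
        else:
            raise ValueError(f"unknown search-space kind {kind!r}")
    return params


def tune_hyperparameters(
    X_dev: pd.DataFrame,
    y_dev,
    feature_set,
    algorithm: str,
    cv: Optional[CVConfig] = None,
    search_space: Optional[dict] = None,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Randomized hyperparameter search on the dev set.

    Draws ``cv.n_candidates`` parameter settings and scores each by
    k-fold CV repeated ``cv.repeats`` times (fresh shuffles), returning
    the setting with the highest mean F1 (ties broken by earliest draw)
    and a per-candidate trace.
    """
    cv = cv or CVConfig()
    space = search_space if search_space is not None else DEFAULT_SEARCH_SPACES[algorithm]
    if not space:
        raise ValueError("hyperparameter search space is empty")
    rng = np.random.default_rng(seed)
    candidates = [_draw_params(space, rng) for _ in range(cv.n_candidates)]
    best_params, best_f1 = None, -np.inf
    trace = []
    for i, params in enumerate(candidates):
        f1 = cross_validate(
            X_dev, y_dev, feature_set, algorithm,
            cv=cv, seed=seed + 1, repeats=cv.repeats, **params,
        )["f1"]
        trace.append({"candidate": i, "params": params, "mean_f1": f1})
        if f1 > best_f1:  # strict: ties keep the earliest draw
            best_params, best_f1 = params, f1
    return best_params, {"trace": trace, "best_f1": best_f1}


def train_final(
    X_train: pd.DataFrame,
    y_train,
    feature_set,
    algorithm: str,
    params: Optional[dict] = None,
    seed: int = 0,
) -> EthnicityClassifier:
    """Fit the final model on the full training set (dev rows included)."""
    clf = EthnicityClassifier(
        feature_set=feature_set, algorithm=algorithm, random_state=seed, **(params or {})
    )
    clf.fit(X_train, y_train)
    clf.fitted_partition_ = "train"
    return clf


# ---------------------------------------------------------------------------
# End-to-end runs
# ---------------------------------------------------------------------------


def prepare_records(raw_df: pd.DataFrame, training_mode: bool = True):
    """Ingest a raw table: clean, standardize labels, drop incomplete and
    duplicate rows. Returns (clean DataFrame, audit dict).

    The cleaned frame carries re-assembled name/location strings (cleaning
    is idempotent, so featurizers re-derive identical features), the sex
    column, the primary category in ``y`` and the full label object in
    ``label``.
    """
    records = records_from_frame(raw_df)
    kept, audit = drop_incomplete_and_duplicates(records, training_mode=training_mode)
    frame = pd.DataFrame(
        {
            "name": [" ".join(r.name.entities) for r in kept],
            "location": [r.location.full_string for r in kept],
            "sex": [r.sex for r in kept],
            "y": [r.ethnicity.primary if r.ethnicity else "" for r in kept],
            "label": [r.ethnicity for r in kept],
        }
    )
    return frame, audit


@dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run."""

    raw_data: Optional[pd.DataFrame] = None  # or a synthetic config below
    synthetic: Optional[dict] = None
    algorithms: Sequence[str] = ("LR",)
    feature_sets: Optional[Sequence] = None  # None => a-priori selection
    tune: bool = True
    split: SplitConfig = field(default_factory=SplitConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    seed: int = 0


def _resolve_data(config: RunConfig) -> pd.DataFrame:
    if (config.raw_data is None) == (config.synthetic is None):
        raise ValueError("config must set exactly one of raw_data / synthetic")
    if config.raw_data is not None:
        return config.raw_data
    from .synthetic import SyntheticConfig, generate

    syn = SyntheticConfig(**{**config.synthetic, "seed": config.synthetic.get("seed", config.seed)})
    return generate(syn)


def _prepare_run(config: RunConfig):
    raw = _resolve_data(config)
    clean, audit = prepare_records(raw, training_mode=True)
    config.split.seed = config.seed
    train, dev, test = split_data(clean, config.split)
    if config.feature_sets is None:
        specs, selection = select_feature_sets(dev, dev["y"], cv=config.cv, seed=config.seed)
    else:
        specs = [resolve_spec(s) for s in config.feature_sets]
        selection = {"note": "feature sets supplied, selection skipped"}
    return clean, audit, train, dev, test, specs, selection


def run_multiclass(config: RunConfig) -> dict:
    """Full multiclass pipeline; returns reports keyed by
    (feature-set name, algorithm)."""
    clean, audit, train, dev, test, specs, selection = _prepare_run(config)
    labels = sorted(clean["y"].unique())  # cover rare classes absent from a partition
    results: dict = {
        "audit": audit,
        "selection": selection,
        "split_sizes": {"train": len(train), "dev": len(dev), "test": len(test)},
        "models": {},
    }
    for spec in specs:
        for algorithm in config.algorithms:
            params = None
            if config.tune:
                params, _ = tune_hyperparameters(
                    dev, dev["y"], spec, algorithm, cv=config.cv, seed=config.seed
                )
            clf = train_final(train, train["y"], spec, algorithm, params, seed=config.seed)
            pred = clf.predict(test)
            scores = clf.multiclass_scores(test)
            report = evaluate.multiclass_report(test["y"], pred, labels, scores=scores)
            results["models"][(spec.name, algorithm)] = {
                "best_params": params,
                "report": report,
            }
    return results


def run_binary(config: RunConfig, target: str) -> dict:
    """Binary pipeline for one of the 13 targets (the ten primary
    categories plus the named Aboriginal subgroups)."""
    if target not in BINARY_TARGETS:
        raise ValueError(f"unknown binary target {target!r}")
    clean, audit, train, dev, test, specs, selection = _prepare_run(config)
    results: dict = {
        "audit": audit,
        "selection": selection,
        "split_sizes": {"train": len(train), "dev": len(dev), "test": len(test)},
        "target": target,
        "models": {},
    }
    y_train = binarize(train["label"], target)
    y_test = binarize(test["label"], target)
    y_dev = binarize(dev["label"], target)
    for spec in specs:
        for algorithm in config.algorithms:
            params = None
            if config.tune:
                params, _ = tune_hyperparameters(
                    dev, y_dev, spec, algorithm, cv=config.cv, seed=config.seed
                )
            clf = train_final(train, y_train, spec, algorithm, params, seed=config.seed)
            pred = clf.predict(test)
            scores = clf.decision_scores(test)
            report = evaluate.binary_report(y_test, pred, scores, positive_name=target)
            results["models"][(spec.name, algorithm)] = {
                "best_params": params,
                "report": report,
            }
    return results
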