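"""Benchmark machine-learning classifiers under class-imbalance handling.

The comparison suite trains a logistic regression (GLM), a random forest
(RF) and a gradient-boosted tree classifier (XGB) to predict the
self-reported physician diagnosis from recall items, the IADL count and
sociodemographic/interviewer covariates.  Because diagnosed dementia is
rare (~2% of respondents), three training sets are constructed from the
random 50:50 split:

* ``SPLIT`` — the raw training half;
* ``DOWN``  — majority class downsampled to the minority count;
* ``SMOTE`` — synthetic minority oversampling: new minority rows are
  interpolated between a minority row and one of its k nearest minority
  neighbours (Euclidean distance on standardised continuous features),
  with the majority optionally subsampled.

Additionally the GLM supports prevalence-derived case weights
(1/p for cases, 1/(1-p) for controls, with p the country prevalence).
RF/XGB hyperparameters are tuned by grid search under stratified 5-fold
cross-validation with mean AUC as the selection criterion (ties resolved
in declared grid order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from xgboost import XGBClassifier

from probdem.simulate import (
    EDUCATION_LEVELS,
    PROXY_LEVELS,
    SEX_LEVELS,
    WILLINGNESS_LEVELS,
)

__all__ = [
    "CONTINUOUS_FEATURES",
    "CATEGORICAL_FEATURES",
    "FittedModel",
    "build_feature_matrix",
    "default_grid",
    "downsample",
    "glm_case_weights",
    "predict_labels",
    "smote",
    "tune_and_fit",
]

LABEL_COLUMN = "self_report_dx"

#: Features treated as continuous (interpolated by SMOTE, standardised for
#: neighbour distances).
CONTINUOUS_FEATURES = (
    "recall_immediate",
    "recall_delayed",
    "iadl_count",
    "age",
    "clarification",
)

#: Categorical features with their declared levels (first level = reference
#: for one-hot encoding).
CATEGORICAL_FEATURES: dict[str, tuple[str, ...]] = {
    "sex": SEX_LEVELS,
    "education": EDUCATION_LEVELS,
    "willingness": WILLINGNESS_LEVELS,
    "proxy_present": PROXY_LEVELS,
}

BINARY_FEATURES = ("reading_assistance",)

MODEL_FEATURES = CONTINUOUS_FEATURES + tuple(CATEGORICAL_FEATURES) + BINARY_FEATURES


@dataclass
class FittedModel:
    """A tuned classifier plus the protocol metadata that produced it.

    ``cv_results`` records mean CV AUC per grid point in declared order;
    ``params`` is the argmax (first on ties).
    """

    family: str
    strategy: str
    params: dict[str, Any]
    estimator: Any
    threshold: float = 0.5
    cv_results: list[dict[str, Any]] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)


def build_feature_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """One-hot encoded model matrix with a fixed, order-stable column set.

    Categorical features are expanded against their declared level lists
    (reference level dropped) so train and test matrices always align,
    regardless of which levels happen to be present.
    """
    missing = [c for c in MODEL_FEATURES if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort lacks model feature columns: {missing}")
    cols: dict[str, np.ndarray] = {}
    for f in CONTINUOUS_FEATURES:
        cols[f] = cohort[f].to_numpy(dtype=float)
    for f in BINARY_FEATURES:
        cols[f] = cohort[f].to_numpy(dtype=float)
    for f, levels in CATEGORICAL_FEATURES.items():
        vals = cohort[f].astype(str)
        bad = sorted(set(vals) - set(levels))
        if bad:
            raise ValueError(f"unknown level(s) {bad} in feature {f!r}")
        for level in levels[1:]:
            safe = level.replace(" ", "_").replace("/", "_")
            cols[f"{f}__{safe}"] = (vals == level).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=cohort.index)


def downsample(train: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Balance classes by sampling the majority down to the minority count.

    All minority rows are retained; majority rows are drawn without
    replacement.  The output has exactly twice the minority count.
    """
    y = train[LABEL_COLUMN]
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("downsampling requires both classes in the training set")
    minority_label = counts.idxmin()
    minority = train[y == minority_label]
    majority = train[y != minority_label]
    if len(majority) == len(minority):
        return train
    rng = np.random.default_rng(seed)
    take = rng.choice(len(majority), size=len(minority), replace=False)
    out = pd.concat([minority, majority.iloc[np.sort(take)]])
    return out.sort_index()


def smote(
    train: pd.DataFrame,
    k: int = 5,
    over_pct: float = 100.0,
    majority_ratio: float | None = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic minority oversampling on the cohort table.

    For each synthetic case a minority row is drawn, one of its ``k``
    nearest minority neighbours selected (Euclidean distance on
    standardised continuous features), and the continuous features
    interpolated at a uniform random fraction along the connecting
    segment.  Categorical and binary features are copied from the base
    row (the majority vote over the base/neighbour pair, ties resolved
    toward the base).  ``over_pct/100 * minority_count`` synthetic rows
    are added; the majority class is subsampled without replacement to
    ``majority_ratio * minority_count`` rows when the ratio is given.

    Synthetic rows carry ``synthetic = 1``; latent ground-truth columns,
    if present, are set to missing for them.
    """
    y = train[LABEL_COLUMN]
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("SMOTE requires both classes in the training set")
    minority_label = counts.idxmin()
    minority = train[y == minority_label]
    majority = train[y != minority_label]
    n_min = len(minority)
    if n_min <= k:
        raise ValueError(
            f"minority count {n_min} must exceed k={k}; use a smaller k"
        )

    rng = np.random.default_rng(seed)
    x = minority.loc[:, list(CONTINUOUS_FEATURES)].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    xs = (x - x.mean(axis=0)) / sd
    # k+1 neighbours because each point is its own nearest neighbour.
    nn = NearestNeighbors(n_neighbors=min(k + 1, n_min)).fit(xs)
    _, idx = nn.kneighbors(xs)
    neighbours = idx[:, 1:]

    n_syn = int(round(over_pct / 100.0 * n_min))
    base = rng.integers(0, n_min, size=n_syn)
    pick = neighbours[base, rng.integers(0, neighbours.shape[1], size=n_syn)]
    frac = rng.random(n_syn)[:, None]
    interp = x[base] + frac * (x[pick] - x[base])

    synthetic = minority.iloc[base].copy().reset_index(drop=True)
    synthetic[list(CONTINUOUS_FEATURES)] = interp
    synthetic["synthetic"] = 1
    for col in ("true_dementia", "dep_symptoms", "verbal_fluency",
                "numeracy", "grip_strength", "orientation"):
        if col in synthetic.columns:
            synthetic[col] = np.nan

    if majority_ratio is not None:
        n_maj = min(len(majority), int(round(majority_ratio * n_min)))
        take = rng.choice(len(majority), size=n_maj, replace=False)
        majority = majority.iloc[np.sort(take)]

    out = pd.concat(
        [
            minority.assign(synthetic=0),
            majority.assign(synthetic=0),
            synthetic,
        ],
        ignore_index=True,
    )
    return out


def glm_case_weights(labels, country_codes, prevalence: dict[str, float]) -> np.ndarray:
    """Prevalence-derived GLM case weights.

    Cases (minority) receive ``1/p_c`` and controls (majority)
    ``1/(1 - p_c)``, where ``p_c`` is the country-specific dementia
    prevalence; rare cases are thus upweighted in proportion to their
    rarity.
    """
    y = np.asarray(labels)
    codes = np.asarray(country_codes)
    if y.shape != codes.shape:
        raise ValueError("labels and country_codes must match in length")
    p = np.empty(y.shape, dtype=float)
    for code in np.unique(codes):
        try:
            pc = prevalence[code]
        except KeyError:
            raise KeyError(f"no prevalence for country {code!r}") from None
        if not (0.0 < pc < 1.0):
            raise ValueError(f"prevalence for {code!r} must lie in (0, 1), got {pc!r}")
        p[codes == code] = pc
    return np.where(y == 1, 1.0 / p, 1.0 / (1.0 - p))


def _make_estimator(family: str, params: dict[str, Any], seed: int):
    if family == "GLM":
        return LogisticRegression(max_iter=2000, **params)
    if family == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "XGB":
        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
            verbosity=0,
            **params,
        )
    raise ValueError(f"unknown model family {family!r}; expected GLM, RF or XGB")


def default_grid(family: str) -> list[dict[str, Any]]:
    """Modest documented hyperparameter grids per family.

    The tuning contract is the selection protocol (grid search, stratified
    5-fold CV, mean AUC, first-on-tie), not a particular grid.
    """
    if family == "GLM":
        return [{"C": [1.0]}]
    if family == "RF":
        return [{"n_estimators": [200], "max_depth": [None, 8],
                 "max_features": ["sqrt"]}]
    if family == "XGB":
        return [{"n_estimators": [150], "max_depth": [2, 4],
                 "learning_rate": [0.1, 0.3]}]
    raise ValueError(f"unknown model family {family!r}")


def tune_and_fit(
    family: str,
    X: pd.DataFrame,
    y,
    grid: list[dict[str, Any]] | None = None,
    seed: int = 0,
    sample_weight=None,
    strategy: str = "SPLIT",
    threshold: float = 0.5,
) -> FittedModel:
    """Grid search under stratified 5-fold CV with mean AUC selection.

    Every grid point is fitted on each training fold and scored by AUC on
    the held-out fold; the point with maximal mean AUC is selected (ties
    go to the earlier point in declared grid order) and refitted on the
    full training set.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    candidates = list(ParameterGrid(grid if grid is not None else default_grid(family)))
    if not candidates:
        raise ValueError("empty hyperparameter grid")
    sw = None if sample_weight is None else np.asarray(sample_weight, dtype=float)

    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    cv_results = []
    for params in candidates:
        aucs = []
        for tr, va in folds:
            est = _make_estimator(family, params, seed)
            fit_kw = {} if sw is None else {"sample_weight": sw[tr]}
            est.fit(X.iloc[tr], y[tr], **fit_kw)
            scores = est.predict_proba(X.iloc[va])[:, 1]
            aucs.append(roc_auc_score(y[va], scores))
        cv_results.append({"params": params, "mean_auc": float(np.mean(aucs))})

    best_i = int(np.argmax([r["mean_auc"] for r in cv_results]))
    best = candidates[best_i]
    est = _make_estimator(family, best, seed)
    fit_kw = {} if sw is None else {"sample_weight": sw}
    est.fit(X, y, **fit_kw)
    return FittedModel(
        family=family,
        strategy=strategy,
        params=dict(best),
        estimator=est,
        threshold=threshold,
        cv_results=cv_results,
        feature_names=list(X.columns),
    )


def predict_labels(
    model: FittedModel, cohort: pd.DataFrame, threshold: float | None = None
) -> tuple[pd.Series, pd.Series]:
    """Predicted labels and scores on a cohort.

    Labels are 1 where the predicted probability strictly exceeds the
    threshold (the model's own by default); raising the threshold never
    increases the positive count.  Scores are returned for AUC.
    """
    thr = model.threshold if threshold is None else threshold
    X = build_feature_matrix(cohort)
    missing = [c for c in model.feature_names if c not in X.columns]
    if missing:
        raise KeyError(f"cohort lacks feature columns: {missing}")
    X = X[model.feature_names]
    scores = model.estimator.predict_proba(X)[:, 1]
    labels = (scores > thr).astype(int)
    name = f"{model.family.lower()}_{model.strategy.lower()}"
    return (
        pd.Series(labels, index=cohort.index, name=name),
        pd.Series(scores, index=cohort.index, name=f"{name}_score"),
    )
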