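"""Response-prediction recipes: LASSO selection, gradient boosting, LOOCV.

Four recipes mirror the clinical comparison of interest, all scored by
leave-one-out cross-validation (LOOCV) with the *positive class = durable
non-responder* convention:

* ``ev_only``       — logistic model on log ΔEV PD-L1 alone;
* ``tissue_tps``    — logistic model on the ordered tissue PD-L1 TPS
  group (<1% or unknown, 1-49%, >=50%);
* ``radiomics``     — L1-penalized logistic feature selection over the
  400-feature radiomics vectors, then a gradient-boosted tree classifier
  (shallow trees, small learning rate, logistic loss);
* ``ev_plus_radiomics`` — the selected radiomics features with log Δ
  appended, under the same boosted classifier. When selection returns no
  radiomics feature this recipe degenerates to the ``ev_only`` model.

By default feature selection runs *inside* every LOOCV fold so the
held-out sample never influences its own feature set (no optimistic
leakage); ``selection_outside=True`` reproduces the simpler
select-once-on-all-data workflow for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .config import ModelConfig
from .errors import ValidationError
from .stats import univariate_roc

logger = logging.getLogger(__name__)

RECIPES = ("ev_only", "radiomics", "ev_plus_radiomics", "tissue_tps")

#: ordered TPS groups; 'unknown' merges into the low-or-absent group
TPS_ORDINAL = {"<1%": 0, "unknown": 0, "1-49%": 1, ">=50%": 2}


@dataclass
class CVReport:
    """Out-of-fold LOOCV predictions and aggregate metrics for one recipe."""

    recipe: str
    y_true: np.ndarray
    scores: np.ndarray
    selected_features: list[list[str]]
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    seed: int


class _MajorityModel:
    """Intercept-only fallback: predicts the training prevalence."""

    def __init__(self, prevalence: float) -> None:
        self.prevalence = prevalence

    def predict_proba(self, X) -> np.ndarray:
        n = len(X)
        return np.column_stack([np.full(n, 1 - self.prevalence), np.full(n, self.prevalence)])


def tps_to_ordinal(tps: np.ndarray) -> np.ndarray:
    """Map TPS category strings to the ordered groups 0 < 1 < 2."""
    try:
        return np.array([TPS_ORDINAL[t] for t in tps], dtype=float)
    except KeyError as exc:
        raise ValidationError(f"unknown TPS category {exc}") from exc


def lasso_select(
    features: pd.DataFrame, outcome: np.ndarray, config: ModelConfig | None = None
) -> list[str]:
    """L1-penalized logistic feature selection.

    Features are standardized internally; the penalty is chosen by
    ``config.n_folds``-fold cross-validated deviance over a log grid of
    ``config.n_penalties`` values (or fixed via ``config.fixed_c``).
    Returns the names of features with nonzero coefficients.
    """
    config = config or ModelConfig()
    X = pd.DataFrame(features)
    y = np.asarray(outcome).astype(int)
    if len(X) != y.size:
        raise ValidationError("features and outcome must align")
    if len(X) < 5:
        raise ValidationError("LASSO selection requires n >= 5")
    if np.unique(y).size < 2:
        raise ValidationError("outcome is degenerate (single class)")
    if X.shape[1] == 0:
        return []
    Xs = StandardScaler().fit_transform(X.to_numpy(dtype=float))
    if config.fixed_c is not None:
        model = LogisticRegression(
            l1_ratio=1, C=config.fixed_c, solver="liblinear", max_iter=2000
        )
    else:
        n_folds = min(config.n_folds, int(np.bincount(y).min()))
        if n_folds < 2:
            raise ValidationError("too few samples in the minority class for CV")
        model = LogisticRegressionCV(
            Cs=np.logspace(-3, 2, config.n_penalties),
            cv=StratifiedKFold(n_folds, shuffle=True, random_state=config.seed),
            l1_ratios=[1.0],
            solver="liblinear",
            scoring="neg_log_loss",
            max_iter=2000,
            use_legacy_attributes=False,
        )
    model.fit(Xs, y)
    coefs = np.ravel(model.coef_)
    return [name for name, c in zip(X.columns, coefs) if abs(c) > 1e-10]


def fit_boosted_model(features: pd.DataFrame, outcome: np.ndarray, config: ModelConfig):
    """Gradient-boosted tree classifier with fixed, documented settings.

    Shallow trees (depth ``xgb_max_depth``), ``xgb_n_estimators`` rounds
    at learning rate ``xgb_learning_rate``, logistic loss, seeded. An
    empty feature set falls back to an intercept-only majority model
    with a warning.
    """
    X = pd.DataFrame(features)
    y = np.asarray(outcome).astype(int)
    if X.shape[1] == 0:
        logger.warning("no features selected: falling back to intercept-only model")
        return _MajorityModel(float(y.mean()))
    model = XGBClassifier(
        n_estimators=config.xgb_n_estimators,
        max_depth=config.xgb_max_depth,
        learning_rate=config.xgb_learning_rate,
        objective="binary:logistic",
        random_state=config.seed,
        n_jobs=1,
        tree_method="exact",
        eval_metric="logloss",
    )
    model.fit(X.to_numpy(dtype=float), y)
    return model


@dataclass
class ResponseDataset:
    """Aligned per-patient inputs for the response-prediction recipes."""

    outcome: np.ndarray  # 1 = non-responder (PD at the durable evaluation)
    delta: np.ndarray | None = None
    tps_group: np.ndarray | None = None  # ordinal 0/1/2
    radiomics: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = len(self.outcome)
        for name in ("delta", "tps_group"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValidationError(f"{name} misaligned with outcome")
        if self.radiomics is not None and len(self.radiomics) != n:
            raise ValidationError("radiomics misaligned with outcome")


def _fit_recipe(
    recipe: str,
    train: ResponseDataset,
    config: ModelConfig,
    preselected: list[str] | None,
):
    """Fit one recipe on a training set; returns (scorer, selected names)."""
    y = train.outcome
    if recipe == "ev_only":
        X = np.log(np.asarray(train.delta, dtype=float)).reshape(-1, 1)
        model = LogisticRegression(C=np.inf, max_iter=2000).fit(X, y)
        return (
            lambda ds: model.predict_proba(
                np.log(np.asarray(ds.delta, dtype=float)).reshape(-1, 1)
            )[:, 1],
            [],
        )
    if recipe == "tissue_tps":
        X = np.asarray(train.tps_group, dtype=float).reshape(-1, 1)
        if np.unique(X).size == 1:  # all one TPS group: no usable signal
            model = _MajorityModel(float(y.mean()))
            return (
                lambda ds: model.predict_proba(np.zeros((len(ds.outcome), 1)))[:, 1],
                [],
            )
        model = LogisticRegression(C=np.inf, max_iter=2000).fit(X, y)
        return (
            lambda ds: model.predict_proba(
                np.asarray(ds.tps_group, dtype=float).reshape(-1, 1)
            )[:, 1],
            [],
        )
    if recipe in ("radiomics", "ev_plus_radiomics"):
        if train.radiomics is None:
            raise ValidationError(f"recipe '{recipe}' requires radiomics features")
        selected = (
            preselected
            if preselected is not None
            else lasso_select(train.radiomics, y, config)
        )
        if recipe == "ev_plus_radiomics" and not selected:
            # degenerate reduction: no radiomics signal -> EV-only model
            return _fit_recipe("ev_only", train, config, None)

        def build_matrix(ds: ResponseDataset) -> pd.DataFrame:
            X = ds.radiomics[selected].copy()
            if recipe == "ev_plus_radiomics":
                X["log_delta_ev_pdl1"] = np.log(np.asarray(ds.delta, dtype=float))
            return X

        model = fit_boosted_model(build_matrix(train), y, config)
        return (lambda ds: model.predict_proba(build_matrix(ds).to_numpy(dtype=float))[:, 1], selected)
    raise ValidationError(f"unknown recipe '{recipe}' (choose from {RECIPES})")


def _subset(ds: ResponseDataset, idx: np.ndarray) -> ResponseDataset:
    return ResponseDataset(
        outcome=ds.outcome[idx],
        delta=None if ds.delta is None else np.asarray(ds.delta)[idx],
        tps_group=None if ds.tps_group is None else np.asarray(ds.tps_group)[idx],
        radiomics=None if ds.radiomics is None else ds.radiomics.iloc[idx].reset_index(drop=True),
    )


def loocv_evaluate(
    dataset: ResponseDataset, recipe: str, config: ModelConfig | None = None
) -> CVReport:
    """Leave-one-out cross-validation of one recipe.

    For each sample the entire recipe — including LASSO selection unless
    ``config.selection_outside`` — is refit on the remaining n-1 samples
    and scores the held-out sample. Aggregate AUC comes from the
    out-of-fold scores; accuracy/sensitivity/specificity are evaluated at
    the Youden cut-point of the out-of-fold ROC, the convention used when
    reporting biomarker performance. (A fixed 0.5 threshold is biased
    against the held-out sample under leave-one-out, because its own
    class is always under-represented in the training prevalence.)
    """
    config = config or ModelConfig()
    y = np.asarray(dataset.outcome).astype(int)
    n = y.size
    if n < 3:
        raise ValidationError("LOOCV requires n >= 3")
    if np.unique(y).size < 2:
        raise ValidationError("outcome is degenerate (single class)")

    preselected: list[str] | None = None
    if config.selection_outside and recipe in ("radiomics", "ev_plus_radiomics"):
        preselected = lasso_select(dataset.radiomics, y, config)

    scores = np.empty(n)
    selected_per_fold: list[list[str]] = []
    for i in range(n):
        idx = np.setdiff1d(np.arange(n), [i])
        train = _subset(dataset, idx)
        if np.unique(train.outcome).size < 2:
            raise ValidationError(
                "a LOOCV training fold lost one outcome class entirely"
            )
        scorer, selected = _fit_recipe(recipe, train, config, preselected)
        selected_per_fold.append(list(selected))
        scores[i] = float(scorer(_subset(dataset, np.array([i])))[0])

    roc = univariate_roc(scores, y, direction="greater")
    return CVReport(
        recipe=recipe,
        y_true=y,
        scores=scores,
        selected_features=selected_per_fold,
        auc=roc.auc,
        accuracy=roc.accuracy,
        sensitivity=roc.sensitivity,
        specificity=roc.specificity,
        seed=config.seed,
    )


def combined_model(
    dataset: ResponseDataset,
    config: ModelConfig | None = None,
    recipes: tuple[str, ...] = RECIPES,
) -> dict[str, CVReport]:
    """LOOCV comparison table across the configured recipes."""
    config = config or ModelConfig()
    reports: dict[str, CVReport] = {}
    for recipe in recipes:
        if recipe in ("radiomics", "ev_plus_radiomics") and dataset.radiomics is None:
            continue
        if recipe == "tissue_tps" and dataset.tps_group is None:
            continue
        if recipe in ("ev_only", "ev_plus_radiomics") and dataset.delta is None:
            continue
        reports[recipe] = loocv_evaluate(dataset, recipe, config)
    return reports
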