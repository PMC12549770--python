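"""Repeated cross-validated ridge regression of subject-level targets.

Each repeat performs a stratified 80/20 train/test split (continuous targets
stratified by quantile bins), selects the ridge penalty by 10-fold CV on the
training set, refits, and evaluates on the held-out test set; features are
standardized within training folds only. Metrics and coefficients are
aggregated over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

DEFAULT_ALPHAS = np.logspace(-3, 3, 13)

BEHAVIORAL_FEATURES = "behavioral"
PARAMETER_FEATURES = "parameters"


@dataclass
class PredictionReport:
    feature_names: list
    mse: np.ndarray  # per repeat
    r2: np.ndarray
    coefs: np.ndarray  # (n_repeats, n_features), standardized scale
    best_alphas: np.ndarray

    @property
    def mean_mse(self) -> float:
        return float(self.mse.mean())

    @property
    def mean_r2(self) -> float:
        return float(self.r2.mean())

    def aggregates(self) -> dict:
        return {
            "mse": {
                "mean": float(self.mse.mean()),
                "sd": float(self.mse.std(ddof=1)),
                "range": [float(self.mse.min()), float(self.mse.max())],
            },
            "r2": {
                "mean": float(self.r2.mean()),
                "sd": float(self.r2.std(ddof=1)),
                "range": [float(self.r2.min()), float(self.r2.max())],
            },
        }

    def coefficient_summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "mean_coef": self.coefs.mean(axis=0),
                "ci_lower": np.percentile(self.coefs, 2.5, axis=0),
                "ci_upper": np.percentile(self.coefs, 97.5, axis=0),
            }
        )


def _stratification_bins(y: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bins of a continuous target for stratified splitting."""
    edges = np.unique(np.quantile(y, np.linspace(0, 1, n_bins + 1)[1:-1]))
    bins = np.searchsorted(edges, y, side="left")
    if len(np.unique(bins)) < 2:
        raise ValueError("cannot form stratification bins: target nearly constant")
    return bins


def repeated_ridge_eval(
    features: pd.DataFrame,
    target,
    *,
    n_repeats: int = 100,
    test_frac: float = 0.2,
    k_folds: int = 10,
    seed: int = 0,
    alphas=DEFAULT_ALPHAS,
    n_bins: int = 5,
) -> PredictionReport:
    """Repeatedly train and evaluate the ridge pipeline.

    Standardization statistics and penalty selection are computed on training
    folds only (no leakage); test-set r-squared is 1 - SSE/SST and may go
    negative.
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    names = (
        list(features.columns)
        if isinstance(features, pd.DataFrame)
        else [f"f{j}" for j in range(X.shape[1])]
    )
    y = np.asarray(target, dtype=float)
    if len(y) < 30:
        raise ValueError("need at least 30 subjects")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("features/target contain missing values")
    bins = _stratification_bins(y, n_bins)

    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(2 * n_repeats).reshape(n_repeats, 2)
    mse = np.empty(n_repeats)
    r2 = np.empty(n_repeats)
    coefs = np.empty((n_repeats, X.shape[1]))
    best_alphas = np.empty(n_repeats)
    for rep in range(n_repeats):
        s_split, s_cv = (int(v) % (2**31 - 1) for v in rep_seeds[rep])
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_frac, stratify=bins, random_state=s_split
        )
        pipe = Pipeline(
            [("scale", StandardScaler()), ("ridge", Ridge())]
        )
        search = GridSearchCV(
            pipe,
            {"ridge__alpha": list(alphas)},
            cv=KFold(n_splits=k_folds, shuffle=True, random_state=s_cv),
            scoring="neg_mean_squared_error",
            n_jobs=1,
        )
        search.fit(X_tr, y_tr)
        pred = search.predict(X_te)
        mse[rep] = mean_squared_error(y_te, pred)
        r2[rep] = r2_score(y_te, pred)
        coefs[rep] = search.best_estimator_.named_steps["ridge"].coef_
        best_alphas[rep] = search.best_params_["ridge__alpha"]
    return PredictionReport(
        feature_names=names, mse=mse, r2=r2, coefs=coefs, best_alphas=best_alphas
    )


def behavioral_features(trials: pd.DataFrame) -> pd.DataFrame:
    """Behavioral summary features per subject.

    Accuracy at each set size, overall accuracy, and mean correct-trial RT at
    each set size.
    """
    responded = trials[trials["action"].notna()]
    rows = []
    for sid, sdf in responded.groupby("subject_id", sort=True):
        row = {"subject_id": sid, "accuracy_overall": sdf["reward"].mean()}
        for ss in sorted(trials["set_size"].unique()):
            sub = sdf[sdf["set_size"] == ss]
            row[f"accuracy_ss{ss}"] = sub["reward"].mean()
            correct = sub[sub["reward"] == 1]
            row[f"rt_correct_ss{ss}"] = correct["rt"].mean()
        rows.append(row)
    return pd.DataFrame(rows)
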