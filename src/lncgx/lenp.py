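"""Top-k elastic-net drug-response models (LENP) and their evaluation.

A LENP model refits a tuned elastic net on an agent's top-k (default 20)
features ranked by predictive score, stores the feature normalization so it
can score new panels deterministically, and is evaluated by 10 iterations
of 10-fold cross-validation (Pearson r and Kendall tau of pooled
out-of-fold predictions). Protein-coding-gene models are the same code path
with a different feature universe.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .dataio import FeatureMatrix, ValidationError
from .enselect import (
    ENHyperparams,
    BootstrapCoefficients,
    PredictiveScores,
    fit_elastic_net,
    tune_hyperparams,
)

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1


@dataclass
class LENPModel:
    """Serialized linear scoring model for one agent."""

    agent_id: str
    scope: str  # "pan" or a cancer-type label
    features: list[str]
    coefficients: np.ndarray
    intercept: float
    alpha: float
    lam: float
    response_metric: str
    feature_means: np.ndarray
    feature_sds: np.ndarray
    trainable: bool = True

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "agent_id": self.agent_id,
            "scope": self.scope,
            "features": self.features,
            "coefficients": [float(v) for v in self.coefficients],
            "intercept": float(self.intercept),
            "alpha": float(self.alpha),
            "lam": float(self.lam),
            "response_metric": self.response_metric,
            "feature_means": [float(v) for v in self.feature_means],
            "feature_sds": [float(v) for v in self.feature_sds],
            "trainable": self.trainable,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LENPModel":
        d = json.loads(Path(path).read_text())
        return cls(
            agent_id=d["agent_id"],
            scope=d["scope"],
            features=list(d["features"]),
            coefficients=np.array(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            alpha=float(d["alpha"]),
            lam=float(d["lam"]),
            response_metric=d["response_metric"],
            feature_means=np.array(d["feature_means"], dtype=float),
            feature_sds=np.array(d["feature_sds"], dtype=float),
            trainable=bool(d.get("trainable", True)),
        )


def top_k_features(
    ps: PredictiveScores,
    k: int = 20,
    bootstrap: BootstrapCoefficients | None = None,
) -> list[str]:
    """Top-k features by descending PS.

    Ties at rank k are broken by larger |mean nonzero bootstrap coefficient|
    (when available), then by feature ID.
    """
    mean_abs = (
        bootstrap.mean_nonzero().abs()
        if bootstrap is not None
        else pd.Series(0.0, index=ps.scores.index)
    )
    order = sorted(
        ps.scores.index,
        key=lambda f: (-ps.scores[f], -mean_abs.get(f, 0.0), f),
    )
    return order[:k]


def train_lenp(
    X: FeatureMatrix | pd.DataFrame,
    y: pd.Series,
    ps: PredictiveScores,
    k: int = 20,
    grids: ENHyperparams | None = None,
    seed: int = 0,
    scope: str = "pan",
    response_metric: str = "ic50",
    bootstrap: BootstrapCoefficients | None = None,
) -> LENPModel:
    """Tune and refit an elastic net on the agent's top-k features.

    Selected columns are standardized (mean/sd stored in the model) before
    fitting. A model with fewer than 2 positive-PS features is marked
    untrainable.
    """
    Xd = X.data if isinstance(X, FeatureMatrix) else X
    mask = y.notna()
    Xd, y = Xd.loc[mask.values], y[mask]
    n_positive = int((ps.scores > 0).sum())
    features = top_k_features(ps, k=k, bootstrap=bootstrap)
    if n_positive < 2:
        logger.warning("train_lenp[%s]: <2 features with PS>0; untrainable", ps.agent_id)
        return LENPModel(
            agent_id=ps.agent_id, scope=scope, features=features,
            coefficients=np.zeros(len(features)), intercept=float(np.mean(y)),
            alpha=1.0, lam=1.0, response_metric=response_metric,
            feature_means=np.zeros(len(features)), feature_sds=np.ones(len(features)),
            trainable=False,
        )
    sub = Xd[features].to_numpy(dtype=float)
    means = sub.mean(axis=0)
    sds = sub.std(axis=0, ddof=1)
    sds = np.where(sds == 0, 1.0, sds)
    z = (sub - means) / sds
    a_star, l_star = tune_hyperparams(
        pd.DataFrame(z, columns=features), np.asarray(y), grids, seed=seed
    )
    coef, b0 = fit_elastic_net(z, np.asarray(y, dtype=float), a_star, l_star)
    return LENPModel(
        agent_id=ps.agent_id, scope=scope, features=features,
        coefficients=coef, intercept=b0, alpha=a_star, lam=l_star,
        response_metric=response_metric, feature_means=means, feature_sds=sds,
    )


def predict(model: LENPModel, X_new: FeatureMatrix | pd.DataFrame) -> pd.Series:
    """Deterministic linear scoring of new samples.

    Missing model features are an explicit error, never a silent zero.
    Columns are re-standardized with the model's stored normalization.
    """
    Xd = X_new.data if isinstance(X_new, FeatureMatrix) else X_new
    absent = [f for f in model.features if f not in Xd.columns]
    if absent:
        raise ValidationError(f"input matrix lacks model features: {absent}")
    z = (Xd[model.features].to_numpy(dtype=float) - model.feature_means) / model.feature_sds
    return pd.Series(z @ model.coefficients + model.intercept, index=Xd.index,
                     name=model.agent_id)


@dataclass
class CVReport:
    """Per-iteration pooled out-of-fold performance."""

    per_iteration: pd.DataFrame  # columns: pearson_r, kendall_tau
    mean_r: float
    sd_r: float
    mean_tau: float
    sd_tau: float


def evaluate_cv(
    X: FeatureMatrix | pd.DataFrame,
    y: pd.Series,
    features: list[str],
    alpha: float,
    lam: float,
    iterations: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> CVReport:
    """10 iterations of seeded 10-fold CV at fixed hyperparameters.

    Out-of-fold predictions are pooled per iteration; an iteration with
    constant pooled predictions is recorded as r = tau = 0 with a warning.
    """
    Xd = X.data if isinstance(X, FeatureMatrix) else X
    mask = y.notna()
    Xd, y = Xd.loc[mask.values], y[mask]
    if len(y) < folds:
        raise ValidationError(f"need at least {folds} samples")
    sub = Xd[features].to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float)
    rows = []
    for it in range(iterations):
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed + it)
        pred = np.empty_like(ya)
        for train_idx, test_idx in cv.split(sub):
            xt = sub[train_idx]
            means = xt.mean(axis=0)
            sds = xt.std(axis=0, ddof=1)
            sds = np.where(sds == 0, 1.0, sds)
            coef, b0 = fit_elastic_net((xt - means) / sds, ya[train_idx], alpha, lam)
            pred[test_idx] = ((sub[test_idx] - means) / sds) @ coef + b0
        if np.ptp(pred) == 0:
            logger.warning("evaluate_cv: constant predictions in iteration %d", it)
            rows.append((0.0, 0.0))
            continue
        r = stats.pearsonr(pred, ya).statistic
        tau = stats.kendalltau(pred, ya).statistic
        rows.append((float(r), float(tau)))
    per_it = pd.DataFrame(rows, columns=["pearson_r", "kendall_tau"])
    return CVReport(
        per_iteration=per_it,
        mean_r=float(per_it["pearson_r"].mean()),
        sd_r=float(per_it["pearson_r"].std(ddof=1)),
        mean_tau=float(per_it["kendall_tau"].mean()),
        sd_tau=float(per_it["kendall_tau"].std(ddof=1)),
    )


def validate_external(
    models: dict[str, LENPModel],
    external_X: FeatureMatrix,
    external_y: pd.DataFrame,
    min_cell_lines: int = 10,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Correlate model predictions with observed response on another panel.

    Returns per-agent Pearson r, Spearman rho with p, and a ``validated``
    flag (Spearman p < 0.05). Agents with fewer than ``min_cell_lines``
    shared, non-missing cell lines are skipped with a notice.
    """
    rows = []
    for agent, model in models.items():
        if agent not in external_y.columns:
            continue
        yo = external_y[agent]
        shared = external_X.data.index.intersection(yo.index)
        yo = yo.loc[shared].dropna()
        if len(yo) < min_cell_lines:
            logger.warning("validate_external[%s]: only %d shared lines; skipped",
                           agent, len(yo))
            continue
        pred = predict(model, external_X.data.loc[yo.index])
        r = stats.pearsonr(pred, yo).statistic
        sp = stats.spearmanr(pred, yo)
        rows.append((agent, float(r), float(sp.statistic), float(sp.pvalue),
                     bool(sp.pvalue < p_threshold)))
    return pd.DataFrame(
        rows, columns=["agent", "pearson_r", "spearman_rho", "spearman_p", "validated"]
    ).set_index("agent")
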