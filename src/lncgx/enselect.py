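"""Bootstrapped elastic-net selection of lncRNA-drug predictive pairs.

For each agent the elastic net

    min_{b0, b}  1/(2N) ||y - b0 - X b||^2 + lam * P_alpha(b),
    P_alpha(b) = (1 - alpha)/2 ||b||_2^2 + alpha ||b||_1,

is tuned by 10-fold cross-validation over a 10 x 200 (alpha, lam) grid and
then refit on 200 bootstrap resamples at the frozen optimum. A feature's
predictive score PS is the fraction of resamples in which its coefficient
is nonzero; features with PS >= 0.25 define lncRNA-drug predictive pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .dataio import FeatureMatrix, ValidationError

logger = logging.getLogger(__name__)

NONZERO_TOL = 1e-8


@dataclass
class ENHyperparams:
    """Grid defaults: 10 mixing ratios on [0.2, 1.0], 200 penalties e^tau
    with tau evenly spaced on [-5, 5], 10 CV folds."""

    alpha_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.2, 1.0, 10)
    )
    lam_grid: np.ndarray = field(
        default_factory=lambda: np.exp(np.linspace(-5.0, 5.0, 200))
    )
    cv_folds: int = 10

    def __post_init__(self) -> None:
        self.alpha_grid = np.sort(np.asarray(self.alpha_grid, dtype=float))
        self.lam_grid = np.sort(np.asarray(self.lam_grid, dtype=float))
        if not (0 < self.alpha_grid[0] and self.alpha_grid[-1] <= 1):
            raise ValidationError("alpha grid must lie in (0, 1]")
        if self.lam_grid[0] <= 0:
            raise ValidationError("lam grid must be positive")


@dataclass
class BootstrapCoefficients:
    """B x p coefficient matrix across bootstrap replicates."""

    coefficients: pd.DataFrame  # replicates x features
    intercepts: np.ndarray
    replicate_seeds: list[int]

    @property
    def n_replicates(self) -> int:
        return self.coefficients.shape[0]

    def mean_nonzero(self) -> pd.Series:
        """Mean coefficient over replicates where it was selected (0 if never)."""
        arr = self.coefficients.to_numpy()
        selected = np.abs(arr) > NONZERO_TOL
        counts = selected.sum(axis=0)
        sums = np.where(selected, arr, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        return pd.Series(means, index=self.coefficients.columns)


@dataclass
class PredictiveScores:
    """Per-feature selection frequency for one agent (multiples of 1/B)."""

    agent_id: str
    scores: pd.Series
    n_replicates: int


def _drop_missing(X: pd.DataFrame, y: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    keep = y.notna()
    return X.loc[keep.values], y.loc[keep.values]


def tune_hyperparams(
    X: FeatureMatrix | pd.DataFrame,
    y: pd.Series | np.ndarray,
    grids: ENHyperparams | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Exhaustive (alpha, lam) grid search minimizing mean 10-fold CV MSE.

    Ties are broken toward the larger lam, then the larger alpha (the
    sparser model). Fold assignment is seeded.
    """
    grids = grids or ENHyperparams()
    Xd = X.data if isinstance(X, FeatureMatrix) else X
    y = np.asarray(y, dtype=float)
    if len(y) < grids.cv_folds:
        raise ValidationError(
            f"need at least cv_folds={grids.cv_folds} samples, got {len(y)}"
        )
    cv = KFold(n_splits=grids.cv_folds, shuffle=True, random_state=seed)
    model = ElasticNetCV(
        l1_ratio=list(grids.alpha_grid),
        alphas=list(grids.lam_grid),
        cv=cv,
        max_iter=5000,
        n_jobs=None,
    )
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(np.asarray(Xd, dtype=float), y)
    # mse_path_: (n_l1_ratio, n_alphas, n_folds); alphas_ descending per row.
    mse = model.mse_path_.mean(axis=2)
    alphas_used = np.asarray(model.alphas_)
    if alphas_used.ndim == 1:
        alphas_used = np.tile(alphas_used, (len(grids.alpha_grid), 1))
    best = None
    for i, a in enumerate(grids.alpha_grid):
        for j in range(mse.shape[1]):
            cand = (mse[i, j], a, alphas_used[i, j])
            if (
                best is None
                or cand[0] < best[0] - 1e-15
                or (
                    abs(cand[0] - best[0]) <= 1e-15
                    and (cand[2], cand[1]) > (best[2], best[1])
                )
            ):
                best = cand
    assert best is not None
    return float(best[1]), float(best[2])


def fit_elastic_net(
    X: np.ndarray, y: np.ndarray, alpha: float, lam: float
) -> tuple[np.ndarray, float]:
    """Single elastic-net solve at fixed hyperparameters."""
    model = ElasticNet(alpha=lam, l1_ratio=alpha, max_iter=5000)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model.coef_.copy(), float(model.intercept_)


def bootstrap_ps(
    X: FeatureMatrix | pd.DataFrame,
    y: pd.Series,
    alpha: float,
    lam: float,
    B: int = 200,
    seed: int = 0,
    agent_id: str = "agent",
    retune_per_replicate: bool = False,
    grids: ENHyperparams | None = None,
) -> tuple[BootstrapCoefficients, PredictiveScores]:
    """Refit the elastic net on B row-resamples; PS = selection frequency.

    Hyperparameters stay frozen across replicates by default
    (``retune_per_replicate`` re-runs the grid search inside every resample
    — much slower, off by default). A replicate whose resampled response
    has zero variance is skipped (logged), reducing the effective B.
    """
    Xd = X.data if isinstance(X, FeatureMatrix) else X
    Xa = np.asarray(Xd, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = len(ya)
    rng = np.random.default_rng(seed)
    coefs, intercepts, used_seeds = [], [], []
    skipped = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        yb = ya[idx]
        if np.var(yb) == 0:
            skipped += 1
            continue
        a_b, l_b = (alpha, lam)
        if retune_per_replicate:
            a_b, l_b = tune_hyperparams(
                pd.DataFrame(Xa[idx], columns=Xd.columns), yb, grids, seed=seed + b
            )
        coef, b0 = fit_elastic_net(Xa[idx], yb, a_b, l_b)
        coefs.append(coef)
        intercepts.append(b0)
        used_seeds.append(b)
    if skipped:
        logger.warning(
            "bootstrap_ps[%s]: skipped %d zero-variance replicate(s); effective B=%d",
            agent_id, skipped, len(coefs),
        )
    coef_df = pd.DataFrame(np.array(coefs), columns=list(Xd.columns))
    bs = BootstrapCoefficients(
        coefficients=coef_df,
        intercepts=np.array(intercepts),
        replicate_seeds=used_seeds,
    )
    b_eff = max(len(coefs), 1)
    ps = (np.abs(coef_df.to_numpy()) > NONZERO_TOL).sum(axis=0) / b_eff
    scores = PredictiveScores(
        agent_id=agent_id,
        scores=pd.Series(ps, index=coef_df.columns, name=agent_id),
        n_replicates=len(coefs),
    )
    return bs, scores


@dataclass
class PairTable:
    """lncRNA-drug predictive pairs at a PS cutoff."""

    table: pd.DataFrame  # columns: feature, agent, ps, sign, spearman_rho
    cutoff: float

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.table["feature"], self.table["agent"]))


def define_pairs(
    scores: list[PredictiveScores],
    X: FeatureMatrix | pd.DataFrame,
    responses: pd.DataFrame,
    bootstraps: dict[str, BootstrapCoefficients] | None = None,
    cutoff: float = 0.25,
) -> PairTable:
    """Keep features with PS >= cutoff (inclusive) per agent.

    Each pair is annotated with the sign of the mean nonzero bootstrap
    coefficient (when bootstrap coefficients are supplied) and the
    univariate Spearman rho between feature expression and response.
    """
    if not 0 < cutoff <= 1:
        raise ValidationError("cutoff must be in (0, 1]")
    Xd = X.data if isinstance(X, FeatureMatrix) else X
    rows = []
    for ps in scores:
        kept = ps.scores[ps.scores >= cutoff]
        if kept.empty:
            continue
        y = responses[ps.agent_id]
        mean_coef = (
            bootstraps[ps.agent_id].mean_nonzero() if bootstraps else None
        )
        mask = y.notna()
        for feature, value in kept.items():
            rho = float("nan")
            if mask.sum() >= 3:
                rho = stats.spearmanr(Xd.loc[mask.values, feature], y[mask]).statistic
            sign = 0
            if mean_coef is not None:
                sign = int(np.sign(mean_coef[feature]))
            rows.append((feature, ps.agent_id, float(value), sign, float(rho)))
    table = pd.DataFrame(
        rows, columns=["feature", "agent", "ps", "sign", "spearman_rho"]
    )
    return PairTable(table=table, cutoff=cutoff)


def select_pan_cancer(
    expr: FeatureMatrix,
    responses: pd.DataFrame,
    agents: list[str] | None = None,
    grids: ENHyperparams | None = None,
    B: int = 200,
    cutoff: float = 0.25,
    seed: int = 0,
) -> tuple[dict[str, PredictiveScores], dict[str, BootstrapCoefficients], PairTable]:
    """Full selection pipeline over a panel: tune, bootstrap, tabulate pairs.

    Cell lines missing an agent's response are dropped for that agent.
    """
    agents = agents if agents is not None else list(responses.columns)
    all_scores: dict[str, PredictiveScores] = {}
    all_bs: dict[str, BootstrapCoefficients] = {}
    for i, agent in enumerate(agents):
        y = responses[agent]
        Xa, ya = _drop_missing(expr.data, y)
        a_star, l_star = tune_hyperparams(Xa, ya, grids, seed=seed + i)
        bs, ps = bootstrap_ps(
            Xa, ya, a_star, l_star, B=B, seed=seed + 10_000 + i, agent_id=agent
        )
        all_scores[agent] = ps
        all_bs[agent] = bs
    pair_table = define_pairs(
        list(all_scores.values()), expr, responses, all_bs, cutoff=cutoff
    )
    return all_scores, all_bs, pair_table


def calibrate_cutoff(
    scores: list[PredictiveScores],
    external_X: FeatureMatrix | pd.DataFrame,
    external_y: pd.DataFrame,
    cutoffs: np.ndarray | None = None,
    min_side: int = 10,
) -> pd.DataFrame:
    """Specificity curve: KS distance between |Spearman rho| distributions
    of predictive vs non-predictive pairs on an external panel, per cutoff.

    Returns a DataFrame (cutoff, ks, n_predictive, n_nonpredictive, knee)
    where ``knee`` marks the maximum discrete second difference of the KS
    curve. Calibration is advisory; the pipeline default cutoff stays 0.25.
    """
    cutoffs = cutoffs if cutoffs is not None else np.arange(0.05, 0.951, 0.05)
    Xd = external_X.data if isinstance(external_X, FeatureMatrix) else external_X
    # precompute |rho| for every (feature, agent) once
    abs_rho: dict[str, pd.Series] = {}
    ps_map: dict[str, pd.Series] = {}
    for ps in scores:
        if ps.agent_id not in external_y.columns:
            continue
        y = external_y[ps.agent_id]
        mask = y.notna()
        sub = Xd.loc[mask.values, ps.scores.index]
        r = np.array(
            [stats.spearmanr(sub[f], y[mask]).statistic for f in ps.scores.index]
        )
        abs_rho[ps.agent_id] = pd.Series(np.abs(r), index=ps.scores.index)
        ps_map[ps.agent_id] = ps.scores
    rows = []
    for c in cutoffs:
        pred, nonpred = [], []
        for agent, rho in abs_rho.items():
            sel = ps_map[agent] >= c
            pred.extend(rho[sel.values].tolist())
            nonpred.extend(rho[~sel.values].tolist())
        if len(pred) < min_side or len(nonpred) < min_side:
            continue
        ks = stats.ks_2samp(pred, nonpred).statistic
        rows.append((float(c), float(ks), len(pred), len(nonpred)))
    curve = pd.DataFrame(rows, columns=["cutoff", "ks", "n_predictive", "n_nonpredictive"])
    curve["knee"] = False
    if len(curve) >= 3:
        second_diff = np.diff(curve["ks"].to_numpy(), 2)
        knee_idx = int(np.argmax(second_diff)) + 1
        curve.loc[curve.index[knee_idx], "knee"] = True
    return curve


def replication_overlap(
    pairs_a: PairTable,
    pairs_b: PairTable,
    n_features: int,
    n_agents: int,
) -> tuple[int, float, float]:
    """Agreement of two pair tables over an explicit universe.

    Builds the 2x2 table (in both / A only / B only / neither) over a
    universe of n_features x n_agents pairs; returns (overlap count, odds
    ratio with Haldane 0.5 correction on zero margins, two-sided Fisher p).
    """
    universe = n_features * n_agents
    set_a, set_b = pairs_a.pairs(), pairs_b.pairs()
    both = len(set_a & set_b)
    only_a = len(set_a - set_b)
    only_b = len(set_b - set_a)
    neither = universe - both - only_a - only_b
    if neither < 0:
        raise ValidationError("universe smaller than observed pair counts")
    table = np.array([[both, only_a], [only_b, neither]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        t = table + 0.5
        odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    else:
        odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    return both, float(odds), float(p)
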