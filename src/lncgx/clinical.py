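"""Patient drug-response prediction and survival analyses.

Trained drug-response models are applied to tumor expression (stage-I
patients are excluded except LAML, where stage is uninformative); per agent
the lowest predicted-IC50 quartile is labeled sensitive, summarized per
cancer type, and tested against the rest by a two-sided KS test. A
consensus weighted-average rank over each type's approved first/second-line
drugs feeds univariate and multivariate Cox models, and patients with an
actual treatment record are split at the median predicted response for
Kaplan-Meier / log-rank analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .dataio import ClinicalTable, FeatureMatrix, ValidationError
from .lenp import LENPModel, predict

logger = logging.getLogger(__name__)

CATEGORIES = ["sensitive", "partial_response", "partial_resistance", "resistance"]
AGE_CUTOFF = 65  # age >= 65 is "old"
STAGE_EXEMPT_TYPES = ("LAML",)


def predict_patients(
    models: dict[str, LENPModel],
    tumor_expr: FeatureMatrix,
    clinical: ClinicalTable,
    stage_exempt_types: tuple[str, ...] = STAGE_EXEMPT_TYPES,
) -> pd.DataFrame:
    """Patient x agent predicted-response matrix after the stage filter.

    Stage-I patients are removed unless their cancer type is stage-exempt
    (leukemias); patients with an unknown stage are retained with a warning.
    """
    clin = clinical.data.loc[clinical.data.index.intersection(tumor_expr.data.index)]
    stage = clin["stage"].astype(str)
    unknown = ~stage.isin(["I", "II", "III", "IV"])
    if unknown.any():
        logger.warning("predict_patients: %d patients with unknown stage retained",
                       int(unknown.sum()))
    drop = (stage == "I") & ~clin["cancer_type"].isin(stage_exempt_types)
    kept = clin.index[~drop]
    if len(kept) == 0:
        logger.warning("predict_patients: no patients pass the stage filter")
        return pd.DataFrame(columns=list(models))
    X = tumor_expr.data.loc[kept]
    return pd.DataFrame({agent: predict(m, X) for agent, m in models.items()})


def label_sensitive(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per agent, label the lowest predicted-response quartile sensitive.

    The threshold is the nearest-rank 25th percentile (the ceil(n/4)-th
    smallest prediction); every patient tied with it is included. Labels are
    therefore invariant to monotone transforms of the predictions.
    """
    labels = pd.DataFrame(False, index=predictions.index, columns=predictions.columns)
    for agent in predictions.columns:
        p = predictions[agent].dropna()
        if len(p) < 4:
            raise ValidationError(f"agent {agent!r}: need >= 4 patients")
        h = math.ceil(0.25 * len(p))
        threshold = np.sort(p.to_numpy())[h - 1]
        sel = p <= threshold
        if sel.all():
            logger.warning("label_sensitive[%s]: degenerate (all predictions tied)", agent)
        labels.loc[p.index, agent] = sel
    return labels


def sensitivity_summary(
    labels: pd.DataFrame,
    predictions: pd.DataFrame,
    cancer_types: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sensitive percentage per (cancer type, agent) plus type-vs-rest KS.

    Returns (percentage matrix in [0, 100], KS table with statistic, p, and
    the direction of the type's predicted-response shift). Singleton types
    are skipped for KS.
    """
    types = cancer_types.reindex(labels.index)
    pct = labels.groupby(types.values).mean() * 100.0
    pct.index.name = "cancer_type"
    rows = []
    for t in pct.index:
        mask = (types == t).to_numpy()
        if mask.sum() < 2 or (~mask).sum() < 2:
            logger.info("sensitivity_summary: KS skipped for singleton type %s", t)
            continue
        for agent in predictions.columns:
            a = predictions.loc[mask, agent].dropna()
            b = predictions.loc[~mask, agent].dropna()
            ks = stats.ks_2samp(a, b)
            direction = "more_sensitive" if a.median() < b.median() else "more_resistant"
            rows.append((t, agent, float(ks.statistic), float(ks.pvalue), direction))
    ks_table = pd.DataFrame(
        rows, columns=["cancer_type", "agent", "ks", "p", "direction"]
    )
    return pct, ks_table


def _cox_fit(df: pd.DataFrame, duration: str, event: str) -> CoxPHFitter:
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration, event_col=event)
    return cph


def univariate_cox(
    score: pd.Series,
    clinical: ClinicalTable,
    endpoint: str = "os",
    min_events: int = 10,
) -> dict[str, float]:
    """Proportional-hazards fit on one standardized continuous predictor.

    Returns HR per sd with 95% CI and p. Requires >= ``min_events`` events.
    """
    time_col, event_col = f"{endpoint}_time", f"{endpoint}_event"
    clin = clinical.data
    shared = score.index.intersection(clin.index)
    df = pd.DataFrame(
        {
            "score": score.loc[shared].astype(float),
            "time": clin.loc[shared, time_col].astype(float),
            "event": clin.loc[shared, event_col].astype(int),
        }
    ).dropna()
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValidationError("no events observed")
    if n_events < min_events:
        raise ValidationError(f"only {n_events} events (< {min_events})")
    sd = df["score"].std(ddof=1)
    df["score"] = (df["score"] - df["score"].mean()) / (sd if sd > 0 else 1.0)
    cph = _cox_fit(df, "time", "event")
    s = cph.summary.loc["score"]
    return {
        "hr": float(s["exp(coef)"]),
        "ci_low": float(s["exp(coef) lower 95%"]),
        "ci_high": float(s["exp(coef) upper 95%"]),
        "p": float(s["p"]),
        "n_events": n_events,
    }


@dataclass
class ConsensusScore:
    """Weighted-average sensitivity ranks and response categories, per type."""

    scores: pd.DataFrame  # index patient; columns consensus_rank, category, cancer_type
    drug_weights: dict[str, dict[str, float]]


def consensus_rank(
    predictions: pd.DataFrame,
    cancer_types: pd.Series,
    approved_map: dict[str, dict[str, list[str]]],
) -> ConsensusScore:
    """Per-patient weighted average of per-drug sensitivity ranks.

    Within each cancer type, patients are ranked ascending by predicted
    response per approved drug (rank 1 = most sensitive, average ranks on
    ties); weights are 1.0 for first-line and 0.5 for second-line agents.
    R' percentiles within the type set the four response categories
    (nearest-rank: first 30% sensitive, 30-50% partial response, 50-70%
    partial resistance, remainder resistance). Types with no approved drug
    in the prediction matrix are skipped with a notice.
    """
    types = cancer_types.reindex(predictions.index)
    frames = []
    weights_used: dict[str, dict[str, float]] = {}
    for t, idx in predictions.groupby(types.values).groups.items():
        approved = approved_map.get(str(t))
        if not approved:
            logger.info("consensus_rank: no approved drugs configured for %s; skipped", t)
            continue
        w = {}
        for d in approved.get("first_line", []):
            if d in predictions.columns:
                w[d] = 1.0
        for d in approved.get("second_line", []):
            if d in predictions.columns:
                w[d] = 0.5
        if not w:
            logger.info("consensus_rank: approved drugs for %s absent from predictions", t)
            continue
        weights_used[str(t)] = w
        sub = predictions.loc[idx, list(w)]
        ranks = sub.rank(axis=0, method="average", ascending=True)
        wvec = np.array([w[d] for d in ranks.columns])
        rprime = (ranks.to_numpy() * wvec).sum(axis=1) / wvec.sum()
        rprime = pd.Series(rprime, index=sub.index, name="consensus_rank")
        n = len(rprime)
        order = rprime.rank(method="first").astype(int)  # 1..n by ascending R'
        n_sens = math.ceil(0.30 * n)
        n_pr = math.ceil(0.50 * n) - n_sens
        n_pres = math.ceil(0.70 * n) - n_sens - n_pr
        cats = pd.Series("resistance", index=rprime.index, name="category")
        cats[order <= n_sens] = "sensitive"
        cats[(order > n_sens) & (order <= n_sens + n_pr)] = "partial_response"
        cats[(order > n_sens + n_pr) & (order <= n_sens + n_pr + n_pres)] = "partial_resistance"
        frames.append(pd.DataFrame({
            "consensus_rank": rprime, "category": cats, "cancer_type": str(t)
        }))
    scores = pd.concat(frames) if frames else pd.DataFrame(
        columns=["consensus_rank", "category", "cancer_type"]
    )
    return ConsensusScore(scores=scores, drug_weights=weights_used)


def weighted_rank(ranks: list[float], weights: list[float]) -> float:
    """R' = sum(w_i R_i) / sum(w_i) for one patient."""
    w = np.asarray(weights, dtype=float)
    r = np.asarray(ranks, dtype=float)
    return float((w * r).sum() / w.sum())


def multivariate_cox(
    consensus: ConsensusScore,
    clinical: ClinicalTable,
    endpoint: str = "os",
    covariate: str = "category",
) -> pd.DataFrame:
    """Cox fit with resistance, stage, and age covariates.

    Resistance is the ordinal response category 0-3 (resistance high) by
    default, or the continuous consensus rank with ``covariate='rank'``.
    Stage is ordinal I-IV; age is dichotomized at 65 (>= 65 is old).
    Degenerate covariates are dropped with a notice.
    """
    time_col, event_col = f"{endpoint}_time", f"{endpoint}_event"
    clin = clinical.data
    shared = consensus.scores.index.intersection(clin.index)
    cs = consensus.scores.loc[shared]
    if covariate == "category":
        resistance = cs["category"].map({c: i for i, c in enumerate(CATEGORIES)})
    elif covariate == "rank":
        resistance = cs["consensus_rank"].astype(float)
    else:
        raise ValidationError("covariate must be 'category' or 'rank'")
    stage_map = {"I": 1, "II": 2, "III": 3, "IV": 4}
    df = pd.DataFrame(
        {
            "resistance": resistance.astype(float),
            "stage": clin.loc[shared, "stage"].map(stage_map).astype(float),
            "old_age": (clin.loc[shared, "age"] >= AGE_CUTOFF).astype(float),
            "time": clin.loc[shared, time_col].astype(float),
            "event": clin.loc[shared, event_col].astype(int),
        }
    ).dropna()
    for col in ["resistance", "stage", "old_age"]:
        if df[col].nunique() < 2:
            logger.warning("multivariate_cox: degenerate covariate %r dropped", col)
            df = df.drop(columns=col)
    cph = _cox_fit(df, "time", "event")
    out = cph.summary[["exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]]
    return out.rename(
        columns={
            "exp(coef)": "hr",
            "exp(coef) lower 95%": "ci_low",
            "exp(coef) upper 95%": "ci_high",
        }
    )


def treated_km(
    predictions: pd.Series,
    clinical: ClinicalTable,
    drug: str,
    endpoint: str = "os",
    min_patients: int = 10,
    min_events: int = 5,
) -> dict:
    """Median-split KM analysis restricted to patients treated with ``drug``.

    Patients are sorted by predicted response; the upper half (including the
    median patient when n is odd) is the predicted-resistant group, so group
    sizes differ by at most one. Returns the log-rank p, the Cox HR of the
    split, and per-group KM survival tables.
    """
    time_col, event_col = f"{endpoint}_time", f"{endpoint}_event"
    clin = clinical.data
    treated = clin.index[
        clin["treatments"].map(lambda t: drug in t if isinstance(t, (list, tuple)) else False)
    ]
    treated = treated.intersection(predictions.index)
    if len(treated) < min_patients:
        raise ValidationError(
            f"only {len(treated)} treated patients (< {min_patients})"
        )
    p = predictions.loc[treated]
    n_events = int(clin.loc[treated, event_col].sum())
    if n_events < min_events:
        raise ValidationError(f"only {n_events} events (< {min_events})")
    order = p.sort_values(kind="mergesort").index
    n_sens = len(order) // 2  # odd n: median patient goes to the resistant group
    sens_idx, res_idx = order[:n_sens], order[n_sens:]
    t_s = clin.loc[sens_idx, time_col].astype(float)
    e_s = clin.loc[sens_idx, event_col].astype(int)
    t_r = clin.loc[res_idx, time_col].astype(float)
    e_r = clin.loc[res_idx, event_col].astype(int)
    lr = logrank_test(t_s, t_r, event_observed_A=e_s, event_observed_B=e_r)
    df = pd.DataFrame(
        {
            "resistant": [0] * len(sens_idx) + [1] * len(res_idx),
            "time": pd.concat([t_s, t_r]).to_numpy(),
            "event": pd.concat([e_s, e_r]).to_numpy(),
        }
    )
    cph = _cox_fit(df, "time", "event")
    hr = float(cph.summary.loc["resistant", "exp(coef)"])
    km_tables = {}
    for name, (tt, ee) in {"sensitive": (t_s, e_s), "resistant": (t_r, e_r)}.items():
        kmf = KaplanMeierFitter()
        kmf.fit(tt, ee, label=name)
        km_tables[name] = kmf.survival_function_
    return {
        "logrank_p": float(lr.p_value),
        "hr": hr,
        "n_sensitive": len(sens_idx),
        "n_resistant": len(res_idx),
        "km": km_tables,
    }
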