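"""Drug-drug similarity from shared predictive features, plus lineage ANOVA.

Agents' predictive scores are dichotomized into binary selection vectors;
pairwise one-sided Fisher exact tests on the shared-selection 2x2 tables
give a -log10(p) similarity matrix that is clustered with average linkage
on Euclidean distances. One-way ANOVA per agent quantifies how much of a
drug's response variance is between cancer lineages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .dataio import ValidationError

logger = logging.getLogger(__name__)

NEGLOG10_CAP = 300.0


def selection_vectors(
    ps_by_agent: pd.DataFrame | dict, cutoff: float = 0.25
) -> pd.DataFrame:
    """Dichotomize predictive scores: 1 where PS >= cutoff (agents x features)."""
    df = pd.DataFrame(ps_by_agent).T if isinstance(ps_by_agent, dict) else ps_by_agent
    return (df >= cutoff).astype(int)


def fisher_one_sided(table: np.ndarray) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test with Haldane-corrected OR."""
    table = np.asarray(table)
    _, p = stats.fisher_exact(table, alternative="greater")
    if (table == 0).any():
        t = table + 0.5
        odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    else:
        odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    return float(odds), float(p)


@dataclass
class SimilarityMatrix:
    """Symmetric agent x agent -log10 Fisher p (capped) and odds ratios."""

    neg_log10_p: pd.DataFrame
    odds_ratio: pd.DataFrame


def pairwise_fisher(selections: pd.DataFrame) -> SimilarityMatrix:
    """Pairwise 2x2 Fisher tests on binary selection vectors.

    Table per agent pair: [both selected, only A, only B, neither]. Agents
    with all-zero vectors get p = 1 against every partner. -log10 p is
    capped at 300 and the diagonal is set to the maximum finite off-diagonal
    value so distances stay finite.
    """
    agents = list(selections.index)
    arr = selections.to_numpy().astype(bool)
    n = len(agents)
    neglogp = np.zeros((n, n))
    ors = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arr[i], arr[j]
            both = int((a & b).sum())
            only_a = int((a & ~b).sum())
            only_b = int((~a & b).sum())
            neither = int((~a & ~b).sum())
            odds, p = fisher_one_sided([[both, only_a], [only_b, neither]])
            nlp = min(-np.log10(max(p, 10.0 ** (-NEGLOG10_CAP))), NEGLOG10_CAP)
            neglogp[i, j] = neglogp[j, i] = nlp
            ors[i, j] = ors[j, i] = odds
    off = neglogp[~np.eye(n, dtype=bool)]
    diag = float(off.max()) if off.size else 0.0
    np.fill_diagonal(neglogp, diag)
    np.fill_diagonal(ors, np.nan)
    return SimilarityMatrix(
        neg_log10_p=pd.DataFrame(neglogp, index=agents, columns=agents),
        odds_ratio=pd.DataFrame(ors, index=agents, columns=agents),
    )


@dataclass
class ClusteringResult:
    linkage: np.ndarray
    labels: list[str]
    flat_clusters: pd.Series

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            return f"({left}:{node.dist/2:.6g},{right}:{node.dist/2:.6g})"

        return walk(tree) + ";"


def cluster_agents(
    similarity: SimilarityMatrix,
    n_clusters: int | None = None,
    use_odds_ratio: bool = False,
) -> ClusteringResult:
    """Average-linkage agglomeration on Euclidean distances between rows.

    Agents are pre-sorted by name so the leaf order (and any linkage
    tie-break) is deterministic and independent of input order. Infinite
    entries are capped at the matrix cap and logged.
    """
    df = similarity.odds_ratio if use_odds_ratio else similarity.neg_log10_p
    if df.shape[0] < 2:
        raise ValidationError("need at least 2 agents to cluster")
    order = sorted(df.index)
    df = df.loc[order, order]
    vals = df.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        logger.warning("cluster_agents: non-finite similarity entries capped")
        vals = np.nan_to_num(vals, nan=0.0, posinf=NEGLOG10_CAP, neginf=-NEGLOG10_CAP)
    link = hierarchy.linkage(pdist(vals, metric="euclidean"), method="average")
    k = n_clusters if n_clusters is not None else max(2, int(np.sqrt(len(order))))
    flat = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return ClusteringResult(
        linkage=link,
        labels=order,
        flat_clusters=pd.Series(flat, index=order, name="cluster"),
    )


def lineage_anova(
    responses: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """One-way ANOVA of drug response across cancer lineages, per agent.

    Lineages with a single non-missing response are dropped (with a notice).
    Returns a DataFrame with F, p, and -log10 p per agent.
    """
    labels = labels.reindex(responses.index)
    rows = []
    for agent in responses.columns:
        y = responses[agent]
        groups = []
        for lineage, vals in y.groupby(labels):
            vals = vals.dropna()
            if len(vals) < 2:
                logger.info("lineage_anova[%s]: dropped singleton lineage %s", agent, lineage)
                continue
            groups.append(vals.to_numpy())
        if len(groups) < 2:
            raise ValidationError(f"agent {agent!r}: fewer than 2 usable lineages")
        f, p = stats.f_oneway(*groups)
        rows.append((agent, float(f), float(p), float(min(-np.log10(max(p, 1e-300)), NEGLOG10_CAP))))
    return pd.DataFrame(rows, columns=["agent", "F", "p", "neg_log10_p"]).set_index("agent")
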