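"""Multi-drug-resistance lncRNAs, co-expression profiles, and enrichment.

An lncRNA predictive of many agents whose target pathways are diverse is a
multi-drug-resistance (MDR) candidate: the Shannon entropy of the multiset
of target-pathway labels over its predicted agents is z-scored across all
predictive lncRNAs and flagged at z > 1. Co-expression rankings of
protein-coding genes against an lncRNA feed a preranked GSEA (weighted
running-sum statistic, gene-label permutation null, NES and FDR by the
standard positive/negative pooling), and a one-sided Fisher test asks
whether an agent's top predictors concentrate in a pathway.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import FeatureMatrix, GeneSetCollection, ValidationError
from .drugsim import fisher_one_sided
from .enselect import PairTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# entropy-based MDR detection
# ---------------------------------------------------------------------------


def pathway_vectors(
    pairs: PairTable, agent_pathway: dict[str, str]
) -> dict[str, list[str]]:
    """Per predictive lncRNA, the multiset of its agents' target pathways.

    Duplicates are preserved: two drugs hitting the same pathway contribute
    two elements. Every agent in the pair table must be mapped.
    """
    unmapped = sorted(set(pairs.table["agent"]) - set(agent_pathway))
    if unmapped:
        raise ValidationError(f"agents without a pathway mapping: {unmapped}")
    vectors: dict[str, list[str]] = {}
    for feature, agent in zip(pairs.table["feature"], pairs.table["agent"]):
        vectors.setdefault(feature, []).append(agent_pathway[agent])
    return vectors


def shannon_entropy(labels: list[str]) -> float:
    """Base-2 Shannon entropy of label frequencies (0 * log 0 := 0)."""
    if not labels:
        raise ValidationError("entropy of an empty multiset is undefined")
    counts = Counter(labels)
    m = len(labels)
    return -sum((c / m) * math.log2(c / m) for c in counts.values())


def flag_mdr(entropies: pd.Series) -> pd.DataFrame:
    """z-score entropies across all predictive lncRNAs; flag z > 1 (strict).

    With zero entropy variance nothing is flagged (notice logged). Requires
    at least 3 lncRNAs.
    """
    if len(entropies) < 3:
        raise ValidationError("need >= 3 predictive lncRNAs to standardize entropy")
    sd = entropies.std(ddof=1)
    if sd == 0:
        logger.warning("flag_mdr: zero entropy variance; nothing flagged")
        z = pd.Series(0.0, index=entropies.index)
    else:
        z = (entropies - entropies.mean()) / sd
    return pd.DataFrame(
        {"entropy": entropies, "z": z, "mdr": z > 1.0}
    ).sort_values("z", ascending=False)


def mdr_lncrnas(pairs: PairTable, agent_pathway: dict[str, str]) -> pd.DataFrame:
    """Pair table -> entropy table with MDR flags."""
    vectors = pathway_vectors(pairs, agent_pathway)
    entropies = pd.Series({f: shannon_entropy(v) for f, v in vectors.items()},
                          name="entropy")
    return flag_mdr(entropies)


# ---------------------------------------------------------------------------
# co-expression ranking
# ---------------------------------------------------------------------------


def correlation_profile(
    lnc_values: pd.Series, pcg_expr: FeatureMatrix | pd.DataFrame
) -> pd.Series:
    """Pearson r of every protein-coding gene against one lncRNA, ranked.

    Genes are sorted by descending r, ties broken by gene ID. Constant genes
    get r = 0 (flagged in the log).
    """
    pcg = pcg_expr.data if isinstance(pcg_expr, FeatureMatrix) else pcg_expr
    shared = lnc_values.index.intersection(pcg.index)
    if len(shared) < 3:
        raise ValidationError("need >= 3 shared samples")
    x = lnc_values.loc[shared].to_numpy(dtype=float)
    M = pcg.loc[shared].to_numpy(dtype=float)
    xc = x - x.mean()
    Mc = M - M.mean(axis=0)
    denom = np.sqrt((xc**2).sum()) * np.sqrt((Mc**2).sum(axis=0))
    constant = denom == 0
    if constant.any():
        logger.warning("correlation_profile: %d constant gene(s) set to r=0",
                       int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(constant, 0.0, (xc @ Mc) / np.where(denom == 0, 1.0, denom))
    out = pd.Series(r, index=pcg.columns, name="pearson_r")
    return out.iloc[np.lexsort((out.index, -out.to_numpy()))]


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------


def _es_from_positions(
    positions: np.ndarray, weights_cum_source: np.ndarray, n_genes: int
) -> np.ndarray:
    """Enrichment scores for one or many hit-position vectors.

    ``positions``: (n_rows, set_size) sorted 0-based indices into the ranked
    list. ``weights_cum_source``: |score|^w per ranked position. The running
    sum gains (hit weight / set total) at hits and loses 1/(N - s) per miss;
    the ES is the extreme deviation, evaluated at the peaks right after each
    hit and the troughs just before each hit.
    """
    n_rows, s = positions.shape
    dec = 1.0 / (n_genes - s)
    w = weights_cum_source[positions]  # (n_rows, s)
    totals = w.sum(axis=1, keepdims=True)
    totals = np.where(totals == 0, 1.0, totals)
    cum = np.cumsum(w, axis=1) / totals
    j = np.arange(1, s + 1)
    up = cum - (positions + 1 - j) * dec
    prev = np.concatenate([np.zeros((n_rows, 1)), cum[:, :-1]], axis=1)
    down = prev - (positions - (j - 1)) * dec
    hi = up.max(axis=1)
    lo = down.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


@dataclass
class EnrichmentResult:
    """ES / NES / nominal p / FDR q per gene set."""

    table: pd.DataFrame

    def significant(self, fdr: float = 0.25) -> pd.DataFrame:
        return self.table[self.table["fdr"] <= fdr]


def gsea_preranked(
    ranked: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_size: int = 5,
) -> EnrichmentResult:
    """Preranked GSEA with a gene-label permutation null.

    ``ranked`` maps gene -> score, sorted descending (it is re-sorted
    defensively, ties broken by gene ID). Sets are intersected with the
    ranked universe; sets with fewer than ``min_size`` surviving members are
    skipped. ES uses weight exponent 1 on |score| by default; the nominal p
    is the one-tailed (b + 1)/(n + 1) estimator over null ES of the matching
    sign (so p is never 0 and is uniform under the null); NES divides by the
    mean |null ES| of matching sign; FDR follows the standard pooled
    positive/negative NES procedure, significant at FDR <= 0.25.
    """
    if ranked.empty:
        raise ValidationError("empty ranked universe")
    ranked = ranked.iloc[np.lexsort((ranked.index, -ranked.to_numpy()))]
    gene_pos = {g: i for i, g in enumerate(ranked.index)}
    n_genes = len(ranked)
    wsource = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    rng = np.random.default_rng(seed)

    kept: list[tuple[str, np.ndarray]] = []
    for name, members in sets.sets.items():
        pos = np.array(sorted(gene_pos[g] for g in members if g in gene_pos))
        if len(pos) < min_size:
            logger.info("gsea_preranked: set %r skipped (<%d members in universe)",
                        name, min_size)
            continue
        if len(pos) >= n_genes:
            continue
        kept.append((name, pos))
    if not kept:
        return EnrichmentResult(table=pd.DataFrame(
            columns=["es", "nes", "p", "fdr", "size"]))

    null_cache: dict[int, np.ndarray] = {}

    def null_es(size: int) -> np.ndarray:
        if size not in null_cache:
            draws = np.argpartition(
                rng.random((n_perm, n_genes)), size - 1, axis=1
            )[:, :size]
            draws.sort(axis=1)
            null_cache[size] = _es_from_positions(draws, wsource, n_genes)
        return null_cache[size]

    rows = []
    pooled_null_nes: list[np.ndarray] = []
    for name, pos in kept:
        es = float(_es_from_positions(pos[None, :], wsource, n_genes)[0])
        nulls = null_es(len(pos))
        # one-tailed within the matching sign, (b+1)/(n+1) so p is never 0
        if es >= 0:
            same = nulls[nulls >= 0]
            b = int((same >= es).sum())
        else:
            same = nulls[nulls < 0]
            b = int((same <= es).sum())
        p = (b + 1) / (len(same) + 1)
        pos_mean = np.abs(nulls[nulls >= 0]).mean() if (nulls >= 0).any() else np.nan
        neg_mean = np.abs(nulls[nulls < 0]).mean() if (nulls < 0).any() else np.nan
        norm = pos_mean if es >= 0 else neg_mean
        nes = es / norm if norm and np.isfinite(norm) and norm > 0 else np.nan
        null_nes = np.where(
            nulls >= 0,
            nulls / (pos_mean if np.isfinite(pos_mean) and pos_mean > 0 else np.nan),
            nulls / (neg_mean if np.isfinite(neg_mean) and neg_mean > 0 else np.nan),
        )
        pooled_null_nes.append(null_nes[np.isfinite(null_nes)])
        rows.append((name, es, nes, p, len(pos)))

    table = pd.DataFrame(rows, columns=["set", "es", "nes", "p", "size"]).set_index("set")
    pooled = np.concatenate(pooled_null_nes)
    obs = table["nes"].to_numpy()
    fdr = np.ones(len(table))
    pos_null, neg_null = pooled[pooled >= 0], pooled[pooled < 0]
    pos_obs, neg_obs = obs[obs >= 0], obs[obs < 0]
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            fdr[i] = np.nan
            continue
        if nes >= 0:
            num = (pos_null >= nes).mean() if pos_null.size else 0.0
            den = (pos_obs >= nes).mean() if pos_obs.size else 1.0
        else:
            num = (neg_null <= nes).mean() if neg_null.size else 0.0
            den = (neg_obs <= nes).mean() if neg_obs.size else 1.0
        fdr[i] = min(1.0, num / den) if den > 0 else 1.0
    table["fdr"] = fdr
    return EnrichmentResult(table=table[["es", "nes", "p", "fdr", "size"]])


# ---------------------------------------------------------------------------
# top-predictor pathway enrichment
# ---------------------------------------------------------------------------


def top_predictor_pathway_enrichment(
    top_sets: dict[str, list[str]],
    enrichment_sig: pd.DataFrame,
    k: int = 20,
) -> pd.DataFrame:
    """Are an agent's top-k predictors concentrated in a pathway?

    ``enrichment_sig``: lncRNA x pathway boolean matrix (GSEA FDR <= 0.25
    dichotomization) over the scored lncRNA universe. Per (agent, pathway):
    the count of top predictors that are enriched, plus a one-sided Fisher p
    against the universe margins. Agents with fewer than k scored lncRNAs
    use all available (notice logged).
    """
    universe = enrichment_sig.index
    rows = []
    for agent, top in top_sets.items():
        scored = [f for f in top if f in universe]
        if len(scored) < k:
            logger.info(
                "top_predictor_pathway_enrichment[%s]: %d of %d top predictors scored",
                agent, len(scored), k,
            )
        if not scored:
            continue
        in_top = universe.isin(scored)
        for pathway in enrichment_sig.columns:
            sig = enrichment_sig[pathway].to_numpy(dtype=bool)
            count = int((sig & in_top).sum())
            table = [
                [count, int(in_top.sum()) - count],
                [int((sig & ~in_top).sum()), int((~sig & ~in_top).sum())],
            ]
            odds, p = fisher_one_sided(table)
            rows.append((agent, pathway, count, float(odds), float(p)))
    return pd.DataFrame(
        rows, columns=["agent", "pathway", "n_enriched", "odds_ratio", "p"]
    )
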