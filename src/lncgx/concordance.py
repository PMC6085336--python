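"""Tumor / cell-line concordance of feature alterations and type matching.

Per cancer type and genomic feature class (expression, methylation, copy
number) a bootstrapped fold-change profile is computed against a resampled
background of the other types; tumor-type vs cell-line-type Pearson
correlations of these profiles, averaged over 10 resampling iterations,
form an asymmetric concordance matrix. A rank-sum scheme integrates the
matrices of several feature classes, and a nearest-neighbor scheme scores
how often a tumor type's correct cell-line counterpart appears within its
top-k neighbors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import FeatureMatrix, ValidationError

logger = logging.getLogger(__name__)

MIN_TUMORS = 16   # "more than 15"
MIN_CELL_LINES = 21  # "more than 20"


@dataclass
class ConcordanceMatrix:
    """Tumor types (rows) x cell-line types (columns), averaged Pearson r."""

    matrix: pd.DataFrame
    feature_name: str
    n_iterations: int

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            if self.feature_name != "integrated":
                raise ValidationError("correlations outside [-1, 1]")


@dataclass
class MatchingResult:
    """Top-k matching percentages with empirical random expectation."""

    match_percentage: dict[int, float]
    random_expectation: dict[int, float]
    random_sd: dict[int, float]


def retained_types(labels: pd.Series, min_samples: int) -> list[str]:
    counts = labels.value_counts()
    kept = sorted(counts[counts >= min_samples].index)
    dropped = sorted(set(counts.index) - set(kept))
    if dropped:
        logger.info("retention filter dropped types %s (<%d samples)", dropped, min_samples)
    return kept


def fold_changes(
    matrix: FeatureMatrix | pd.DataFrame,
    labels: pd.Series,
    target_type: str,
    rng: np.random.Generator,
) -> pd.Series:
    """Per-feature mean difference: target type minus resampled background.

    The background is drawn without replacement from the pooled other
    types, matched to the target group size.
    """
    data = matrix.data if isinstance(matrix, FeatureMatrix) else matrix
    labels = labels.reindex(data.index)
    if target_type not in set(labels):
        raise ValidationError(f"target type {target_type!r} not present")
    target_mask = (labels == target_type).to_numpy()
    target = data.loc[target_mask]
    others = data.loc[~target_mask]
    size = min(len(target), len(others))
    bg_idx = rng.choice(len(others), size=size, replace=False)
    background = others.iloc[bg_idx]
    return target.mean(axis=0) - background.mean(axis=0)


def correlate_fold_changes(
    tumor_fcs: pd.DataFrame, cell_fcs: pd.DataFrame
) -> pd.DataFrame:
    """Pairwise Pearson r between tumor-type and cell-type fold-change rows."""
    shared = tumor_fcs.columns.intersection(cell_fcs.columns)
    if len(shared) < 2:
        raise ValidationError("need at least 2 shared features")
    out = pd.DataFrame(index=tumor_fcs.index, columns=cell_fcs.index, dtype=float)
    for t in tumor_fcs.index:
        for c in cell_fcs.index:
            out.at[t, c] = stats.pearsonr(
                tumor_fcs.loc[t, shared], cell_fcs.loc[c, shared]
            ).statistic
    return out


def concordance_matrix(
    tumor_matrix: FeatureMatrix,
    tumor_labels: pd.Series,
    cell_matrix: FeatureMatrix,
    cell_labels: pd.Series,
    feature_name: str = "expression",
    n_iter: int = 10,
    seed: int = 0,
    min_tumors: int = MIN_TUMORS,
    min_cell_lines: int = MIN_CELL_LINES,
) -> ConcordanceMatrix:
    """Average over ``n_iter`` resampling iterations of fold-change correlations.

    Only cancer types passing the retention filter on both panels are kept,
    so the matrix is square over the common retained type set.
    """
    t_types = retained_types(tumor_labels, min_tumors)
    c_types = retained_types(cell_labels, min_cell_lines)
    common = sorted(set(t_types) & set(c_types))
    if len(common) < 2:
        raise ValidationError("fewer than 2 cancer types pass the retention filter")
    shared = tumor_matrix.data.columns.intersection(cell_matrix.data.columns)
    if len(shared) < 2:
        raise ValidationError("need at least 2 shared features")
    rng = np.random.default_rng(seed)
    acc = np.zeros((len(common), len(common)))
    for _ in range(n_iter):
        t_fcs = pd.DataFrame(
            {t: fold_changes(tumor_matrix.data[shared], tumor_labels, t, rng)
             for t in common}
        ).T
        c_fcs = pd.DataFrame(
            {c: fold_changes(cell_matrix.data[shared], cell_labels, c, rng)
             for c in common}
        ).T
        acc += correlate_fold_changes(t_fcs, c_fcs).to_numpy()
    out = pd.DataFrame(acc / n_iter, index=common, columns=common)
    return ConcordanceMatrix(matrix=out, feature_name=feature_name, n_iterations=n_iter)


TIE_BREAK_EPS = 1e-6


def integrate_features(matrices: list[ConcordanceMatrix]) -> ConcordanceMatrix:
    """Rank-sum integration over feature classes.

    Within each matrix every cell is ranked by descending correlation
    (average ranks on ties); a cell's rank-sum across matrices is negated so
    higher remains more concordant, with the mean correlation added at eps
    scale purely as a tie-break (average ranks are multiples of 0.5, so the
    tie-break can never reorder distinct rank-sums).
    """
    if not matrices:
        raise ValidationError("no matrices to integrate")
    base = matrices[0].matrix
    for m in matrices[1:]:
        if not (m.matrix.index.equals(base.index) and m.matrix.columns.equals(base.columns)):
            raise ValidationError("concordance matrices must share the type set")
    ranksum = np.zeros(base.shape)
    mean_corr = np.zeros(base.shape)
    for m in matrices:
        vals = m.matrix.to_numpy()
        ranks = stats.rankdata(-vals, axis=None).reshape(vals.shape)
        ranksum += ranks
        mean_corr += vals
    mean_corr /= len(matrices)
    score = -ranksum + TIE_BREAK_EPS * mean_corr
    return ConcordanceMatrix(
        matrix=pd.DataFrame(score, index=base.index, columns=base.columns),
        feature_name="integrated",
        n_iterations=matrices[0].n_iterations,
    )


def _match_counts(
    values: np.ndarray, row_types: list[str], col_types: list[str], ks: list[int]
) -> dict[int, float]:
    n_rows = len(row_types)
    pct = {}
    order_cache = []
    for i in range(n_rows):
        order = sorted(range(len(col_types)), key=lambda j: (-values[i, j], col_types[j]))
        order_cache.append([col_types[j] for j in order])
    for k in ks:
        hits = sum(1 for i, t in enumerate(row_types) if t in order_cache[i][:k])
        pct[k] = 100.0 * hits / n_rows
    return pct


def nn_matching(
    matrix: ConcordanceMatrix,
    ks: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7),
    n_perm: int = 1000,
    seed: int = 0,
    transpose: bool = False,
) -> MatchingResult:
    """Tumor types query their cell-line-type nearest neighbors.

    For each row, neighbors are columns sorted by descending score (ties
    broken lexicographically by type name); the row matches at k if its own
    type is within the top k. The random expectation (and Monte-Carlo sd)
    comes from ``n_perm`` independent row-wise score permutations.
    """
    df = matrix.matrix.T if transpose else matrix.matrix
    if df.shape[0] != df.shape[1]:
        raise ValidationError("matching requires a square matrix")
    values = df.to_numpy()
    row_types, col_types = list(df.index), list(df.columns)
    ks = [k for k in ks if k <= len(col_types)]
    pct = _match_counts(values, row_types, col_types, ks)
    rng = np.random.default_rng(seed)
    perm_pct = {k: [] for k in ks}
    for _ in range(n_perm):
        permuted = np.array([rng.permutation(row) for row in values])
        p = _match_counts(permuted, row_types, col_types, ks)
        for k in ks:
            perm_pct[k].append(p[k])
    expectation = {k: float(np.mean(perm_pct[k])) for k in ks}
    sd = {k: float(np.std(perm_pct[k], ddof=1)) for k in ks}
    return MatchingResult(match_percentage=pct, random_expectation=expectation, random_sd=sd)


def significant_pairs(matrix: ConcordanceMatrix, n_tumors: pd.Series,
                      n_cells: pd.Series) -> pd.DataFrame:
    """Diagnostic: flag (t, c) correlations whose p-value falls in the lowest
    decile of all pairwise p-values in the matrix.

    The correlation p-value is approximated from the averaged r using the
    pooled sample size (the averaging makes an exact test unavailable).
    """
    df = matrix.matrix
    ps = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for t in df.index:
        for c in df.columns:
            n = int(min(n_tumors.get(t, 0), n_cells.get(c, 0)))
            r = df.at[t, c]
            if n < 3 or not np.isfinite(r):
                ps.at[t, c] = 1.0
                continue
            tstat = r * np.sqrt((n - 2) / max(1e-12, 1 - r**2))
            ps.at[t, c] = 2 * stats.t.sf(abs(tstat), df=n - 2)
    cutoff = np.quantile(ps.to_numpy().ravel(), 0.10)
    return ps <= cutoff
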