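# Methods

This note documents the models implemented in `lncgx`, the defaults and the
conventions behind them, what the synthetic-data generator does and does not
emulate, and the numerical choices that were genuinely open.

## Elastic-net predictive scores

For each agent with response vector $y \in \mathbb{R}^N$ (ln-transformed
IC50 by default, AUC as an alternative) over $N$ cell lines and an
expression matrix $X \in \mathbb{R}^{N \times p}$, we solve

$$\min_{\beta_0,\beta}\ \frac{1}{2N}\lVert y-\beta_0-X\beta\rVert_2^2
+ \lambda\Big[\tfrac{1-\alpha}{2}\lVert\beta\rVert_2^2
+ \alpha\lVert\beta\rVert_1\Big].$$

Hyperparameters are tuned by exhaustive grid search — 10 mixing ratios
$\alpha$ evenly spaced on $[0.2, 1.0]$ and 200 penalties $\lambda=e^\tau$
with $\tau$ evenly spaced on $[-5, 5]$ — minimizing mean 10-fold CV MSE with
seeded fold assignment. CV-MSE ties are broken toward larger $\lambda$, then
larger $\alpha$ (the sparser model). The solver is scikit-learn's coordinate
descent; its `alpha`/`l1_ratio` parametrization coincides with
$(\lambda, \alpha)$ above.

The tuned pair is then **frozen** and the model is refit on 200 bootstrap
resamples of the rows (with replacement, one seeded stream). The predictive
score of feature $u$ is the fraction of replicates in which its coefficient
is nonzero, with "nonzero" meaning $|\beta| > 10^{-8}$ — coordinate descent
returns exact zeros for truly inactive features, so the tolerance only
guards against solver round-off. Features are standardized once on the full
panel, not per resample; a resample with zero response variance is skipped
and the effective number of replicates reduced. Features with
$PS \geq 0.25$ (inclusive) define lncRNA–drug predictive pairs; the cutoff
can be examined against an external panel via the KS-distance specificity
curve (`calibrate_cutoff`), but that calibration is advisory and the
pipeline default stays 0.25. Per-replicate retuning is available
(`bootstrap_ps(..., retune_per_replicate=True)`) but is off by default,
matching the tune-once design.

Missing responses are handled per agent by dropping the affected cell lines
before tuning. Cancer-specific selection is the identical procedure
restricted to one lineage's cell lines (`--mode per-type`); protein-coding
models are the same code path with a different feature universe.

## LENP models

The drug-response model per agent is an elastic net refit on the top-20
features by descending PS (ties at rank 20 broken by larger |mean nonzero
bootstrap coefficient|, then feature ID). Selected columns are standardized
and the means/sds stored in the model JSON, so predictions on new panels
are deterministic affine maps; missing model features on a new panel are a
hard error, never an implicit zero. Performance is reported as 10 iterations
of 10-fold CV at the tuned hyperparameters, pooling out-of-fold predictions
per iteration and computing Pearson *r* and Kendall τ; fold standardization
is re-estimated inside each training fold. A model with fewer than two
positive-PS features is marked untrainable and predicts the training mean.
External validation correlates predictions with the other panel's observed
response over the shared cell lines (at least 10 required), flagging agents
with Spearman p < 0.05 as validated.

## Tumor / cell-line concordance

Per genomic feature class the per-type alteration profile is a fold-change
vector: mean over the type's samples minus the mean of a background drawn
without replacement from the pooled other types, matched to the target group
size (the background size and sampling scheme are our convention). Types
with at most 15 tumors or at most 20 cell lines are dropped. The tumor-type
× cell-line-type matrix of Pearson correlations between these profiles is
averaged over 10 background resamplings. Several feature classes are
integrated by rank sums: every cell is ranked (descending, average ranks on
ties) within its own matrix, rank-sums are negated so higher stays more
concordant, and the mean correlation is added at $10^{-6}$ scale purely as
a tie-break — average ranks make rank-sums multiples of 0.5, so the
tie-break can never reorder distinct rank-sums.

Top-*k* matching treats tumor types as queries over cell-line-type
neighbors sorted by descending score (ties broken lexicographically by type
name); the reported random expectation and its Monte-Carlo sd come from
1000 independent row-wise score permutations. Under the null the own-type
rank is exchangeable, but matrix entries share row/column structure
(finite-sample fold-change noise is common to a row), so single-realization
match percentages have somewhat more variance than the permutation sd —
worth remembering when reading null runs. A "significant correlation"
diagnostic flags cells whose approximate correlation p-value falls in the
lowest decile of the matrix; it is a diagnostic only.

## Patient predictions and survival

Stage-I patients are excluded before prediction except for leukemia (LAML)
cohorts, where stage is uninformative; unknown stages are retained with a
warning. Per agent, patients in the lowest quartile of predicted response
(nearest-rank: the $\lceil n/4\rceil$-th smallest value, ties included) are
labeled sensitive — low predicted IC50 means sensitive throughout. Type
sensitivity percentages are complemented by a two-sided KS test of each
type's predicted-response distribution against all other types.

The consensus score ranks patients within their cancer type per approved
drug (ascending predicted response, average ranks) and averages ranks with
weights 1.0 (first-line) and 0.5 (second-line):
$R' = \sum_i w_i R_i / \sum_i w_i$. Response categories by ascending $R'$
percentile (nearest-rank): first 30% sensitive, 30–50% partial response,
50–70% partial resistance, remainder resistance. Every rank-based step is
invariant to monotone transforms of the predictions.

Cox models use lifelines. The univariate fit standardizes the continuous
predictor so the HR is per sd, and requires at least 10 events. The
multivariate fit uses the ordinal category (0–3, resistance high) by
default — the continuous $R'$ is available via `covariate="rank"` since the
choice between them is genuinely open — plus ordinal stage (I–IV → 1–4) and
age dichotomized at 65 (age 65 itself is "old"); degenerate covariates are
dropped with a notice. Treated-patient analysis restricts to patients whose
treatment record contains the drug, splits at the median predicted response
(odd cohorts put the median patient in the resistant group, so group sizes
differ by at most one), and reports the log-rank p, the Cox HR of the
split, and KM survival tables.

## Drug similarity and lineage effects

Predictive scores are dichotomized at the pair cutoff into binary selection
vectors; each agent pair's 2×2 table (both / only A / only B / neither)
gets a one-sided (enrichment) Fisher exact test, with the Haldane 0.5
correction for odds ratios on zero margins. The similarity matrix is
$-\log_{10} p$ capped at 300 (keeping Euclidean distances finite), with the
diagonal set to the maximum finite off-diagonal value; odds ratios are kept
alongside and can drive the clustering instead. Clustering is average
linkage on Euclidean distances between similarity rows, with agents
pre-sorted by name so the dendrogram is order-independent; trees export as
Newick. Lineage effects are per-agent one-way ANOVA of response across
cancer types (singleton lineages dropped), reported as $-\log_{10} p$.

## MDR lncRNAs, co-expression, and enrichment

For every lncRNA in the pair table, the multiset of its agents' target
pathways (duplicates preserved) has base-2 Shannon entropy
$H=-\sum_k p_{C_k}\log_2 p_{C_k}$. Entropies are z-scored across **all**
predictive lncRNAs (including single-pathway ones, whose $H=0$ naturally
anchors the left tail) and lncRNAs with $z>1$ (strict) are flagged
multi-drug-resistance related. Zero entropy variance flags nothing.

Co-expression profiles are vectorized Pearson correlations of every
protein-coding gene against one lncRNA, sorted descending with ties broken
by gene ID; constant genes get $r=0$ with a flag. Preranked GSEA uses the
weighted running-sum statistic (weight exponent 1 on |score|), set sizes
5 ≤ size < universe after intersection, and a seeded gene-label permutation
null (phenotype permutation is impossible for correlation-ranked lists);
the null is computed once per unique set size and shared. The nominal p is
the one-tailed $(b+1)/(n+1)$ estimator over null ES of the matching sign —
this keeps p strictly positive and uniform under the null. NES divides ES
by the mean |null ES| of its sign, and FDR follows the standard pooled
positive/negative null-NES procedure, with significance at FDR ≤ 0.25.
Top-predictor pathway enrichment counts, per agent, how many of its top-20
predictors are significantly enriched in each pathway and tests the count
with a one-sided Fisher test against the universe margins.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
the biology that produces it:

- **Expression** is i.i.d. standard normal per feature, plus a mean shift
  of `type_shift` z-units on each cancer type's disjoint block of signature
  features, for cell lines and tumors alike (this is what makes type
  matching recoverable).
- **Response**: $\ln IC50_j = \sum_u \beta_{ju} x_u + $ per-(type, agent)
  lineage offset $\sim N(0,\texttt{lineage\_effect\_sd})$ $+\,
  N(0,\texttt{noise\_sd})$, with exactly `k_true_per_agent` nonzero
  coefficients of magnitude `effect_size` and random sign. Agents sharing a
  target pathway share a planted core of $\lceil k/2\rceil$ support
  features, so drug-similarity clustering has a recoverable truth. AUC is a
  per-agent logistic transform of ln IC50 centered at the panel median plus
  $N(0, 0.01)$ noise, clipped to $[0,1]$ — any monotone surrogate serves,
  and the logistic keeps the GDSC convention that a larger viability AUC is
  more resistant.
- **Survival** is exponential (constant baseline hazard, chosen for
  analytic tractability) with log hazard `log_hr_resistance` per sd of the
  true resistance score (the standardized mean planted-model response over
  agents, kept in the clinical table as `true_resistance`). Censoring is an
  independent exponential whose rate is calibrated so the expected censored
  fraction at score zero equals `censoring_rate`. Stage is uniform over
  I–IV and age uniform over 30–90 years so the stage filter and the
  65-year dichotomization are both exercised; each tumor receives 1–3 drugs
  from its type's approved list (2 first-line + 1 second-line, assigned
  cyclically).
- **Multi-omics**: copy-number segments (blocks of 10 features, value
  0.2 × mean signature shift + noise) and methylation betas
  (0.5 + 0.08 × shift + noise, clipped to [0,1]) carry the same type
  signatures, giving concordant cross-modality fold-changes; two probes map
  to each lncRNA to exercise probe summarization.
- **Co-expression**: each pathway gets one planted gene set of 30
  protein-coding genes generated as partner-lncRNA expression × loading
  (default 0.8) plus matched residual noise, so the set is enriched near
  the top of that lncRNA's correlation ranking; size-matched random sets
  are added as calibration controls.

Defaults (100 cell lines, 500 lncRNAs, 10 planted lncRNAs per agent, effect
0.8, noise sd 0.5, B = 200) are the conditions the recovery studies are run
at. What the generator does **not** emulate: correlated lncRNA expression
(real co-expression would make bootstrap selection split credit between
proxies, lowering individual PS), heavy-tailed or batch-structured
measurement noise, dose–response curve fitting, copy-number breakpoint
realism, and informative censoring. Passing recovery tests therefore shows
the statistics behave as designed under their own assumptions, not that
real GDSC/TCGA effect sizes are attainable.

The IC50 noise sd is a free knob, not an estimated quantity — the public
panels do not publish a replicate-level noise model.

## Numerical conventions and study sizes

- Normalization: $\ln(x + 1)$ then per-feature z-score with sample sd
  (ddof = 1); constant features become all-zero with a warning; normalizing
  twice is refused. Natural log matches the ln-IC50 convention.
- Genomic intervals are 0-based half-open everywhere; segment→region values
  are overlap-length-weighted means with the covered fraction reported.
- Probe→feature aggregation is an unweighted mean (an optional convenience;
  probe-level data can be kept).
- All randomness flows through `numpy.random.default_rng` seeds; every CLI
  stage is byte-deterministic for a fixed `--seed`.
- Recovery studies run at: selection/LENP on 100 × 500 panels (B = 200);
  concordance on 6 types × 300 features with 150 cell lines and 120 tumors;
  survival on 20 replicate cohorts of 1000 tumors (400 for treated-patient
  power); GSEA calibration on 100 random sets over a 2000-gene universe
  with 1000 permutations, planted-set detection over 20 replicate panels
  with 500 permutations. These sizes were chosen so each study's Monte-Carlo
  error is well inside the margins being asserted.

## Known limitations

- The replication/overlap statistics depend on an explicit feature × agent
  universe; with real catalogs the universe definition (which lncRNAs were
  scoreable for which agents) materially changes odds ratios.
- The GSEA FDR is the pooled empirical procedure; with very few gene sets
  the q-values are coarse.
- `calibrate_cutoff`'s knee detection (maximum discrete second difference)
  is a heuristic on a 0.05-step grid; it locates the specificity plateau
  but should not be over-interpreted.
- Average-linkage clustering of $-\log_{10} p$ rows inherits the p-value
  cap; agents with many capped similarities become indistinguishable.
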