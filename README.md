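# lncgx

**lncRNA pharmacogenomics: predicting cancer drug response from non-coding
expression.**

Long non-coding RNAs (lncRNAs) are among the most prevalent transcriptional
changes in cancer, yet most pharmacogenomic models are built from
protein-coding features only. `lncgx` implements a complete pipeline for
linking lncRNA expression to drug response in cell-line panels and carrying
those models into patient tumors:

1. **Predictive-pair discovery.** For each agent, an elastic net

   $$\min_{\beta_0,\beta}\; \frac{1}{2N}\sum_i (y_i-\beta_0-x_i^\top\beta)^2
   + \lambda P_\alpha(\beta),\qquad
   P_\alpha(\beta)=\tfrac{1-\alpha}{2}\lVert\beta\rVert_2^2
   + \alpha\lVert\beta\rVert_1$$

   is tuned by 10-fold CV over a 10 × 200 $(\alpha,\lambda)$ grid
   ($\alpha \in [0.2,1.0]$, $\lambda = e^\tau$, $\tau \in [-5,5]$) and refit
   on 200 bootstrap resamples at the frozen optimum. The **predictive score**
   of lncRNA $u$ is its selection frequency,
   $PS_u=\frac{1}{200}\sum_b I(\beta^{BS}_{u,b}\neq 0)$; pairs with
   $PS\geq 0.25$ define the lncRNA–drug predictive-pair table.
2. **LENP models.** A per-agent elastic net refit on the top-20 lncRNAs by
   PS, evaluated by 10 iterations of 10-fold CV (Pearson *r*, Kendall τ) and
   by external-panel correlation.
3. **Tumor/cell-line concordance.** Bootstrapped per-type fold-change
   profiles, Pearson-correlation matrices averaged over 10 resamplings,
   rank-sum integration across omics, and top-*k* nearest-neighbor
   tissue-of-origin matching.
4. **Patient predictions and survival.** Stage-filtered per-patient
   predicted responses, lowest-quartile sensitivity labels, weighted
   consensus ranks $R'=\sum_i w_iR_i/\sum_i w_i$ over approved drugs
   (first-line $w=1.0$, second-line $w=0.5$), univariate/multivariate Cox
   models and median-split Kaplan–Meier analysis of treated patients.
5. **Multi-drug resistance and co-expression.** Shannon entropy
   $H_i=-\sum_k p_{C_k}\log_2 p_{C_k}$ of each lncRNA's target-pathway
   multiset (MDR flag at entropy z-score > 1), Pearson co-expression
   rankings against protein-coding genes, preranked GSEA (NES, permutation
   FDR), and one-sided Fisher enrichment of top predictors in pathways.
6. **Synthetic studies.** A fully seeded generator plants sparse
   drug-response effects, cancer-type signatures shared between cell lines
   and tumors, proportional-hazards survival, and co-expressed gene sets —
   with the ground truth returned for recovery testing.

All real-data formats are plain text: expression/response TSV, SEG-like
copy-number segments, methylation beta matrices, GMT gene sets, YAML
approved-drug maps, JSON models.

## Worked example

```python
from lncgx.simdata import SimulationConfig, simulate_cell_line_panel
from lncgx import enselect, lenp

config = SimulationConfig(n_cell_lines=100, n_lncRNAs=500, n_agents=10, seed=1)
expr, panel, lineages, truth = simulate_cell_line_panel(config)

agent = "DRUG000"
y = panel.ln_ic50[agent]
alpha, lam = enselect.tune_hyperparams(expr, y, seed=1)
bootstrap, ps = enselect.bootstrap_ps(expr.data, y, alpha, lam,
                                      B=200, seed=2, agent_id=agent)
pairs = enselect.define_pairs([ps], expr, panel.ln_ic50,
                              {agent: bootstrap}, cutoff=0.25)
model = lenp.train_lenp(expr, y, ps, k=20, seed=3, bootstrap=bootstrap)
report = lenp.evaluate_cv(expr, y, model.features, model.alpha, model.lam, seed=4)

print(f"tuned alpha={alpha:.2f}, lambda={lam:.4f}")
print(f"{len(pairs.table)} lncRNA-drug predictive pairs (PS >= 0.25)")
print(pairs.table.sort_values("ps", ascending=False).head(3).to_string(index=False))
print(f"10x10-fold CV: Pearson r = {report.mean_r:.3f} +/- {report.sd_r:.3f}, "
      f"Kendall tau = {report.mean_tau:.3f}")
planted = truth.true_coefficients.loc[agent]
recovered = set(pairs.table.feature) & set(planted[planted != 0].index)
print(f"planted predictive lncRNAs recovered: {len(recovered)}/10")
```

prints:

```
tuned alpha=1.00, lambda=0.0585
50 lncRNA-drug predictive pairs (PS >= 0.25)
feature   agent  ps  sign  spearman_rho
 LNC034 DRUG000 1.0    -1     -0.407453
 LNC399 DRUG000 1.0    -1     -0.381374
 LNC470 DRUG000 1.0     1      0.336958
10x10-fold CV: Pearson r = 0.976 +/- 0.001, Kendall tau = 0.877
planted predictive lncRNAs recovered: 10/10
```

The panel plants 10 predictive lncRNAs per agent (effect 0.8 ln-IC50 units
per z-unit, response noise sd 0.5); all 10 come back with PS = 1.0, the
`sign` column matches the planted coefficient signs, and the refit top-20
model explains the response nearly up to the noise floor.

The same stages are available from the shell:

```sh
lncgx simulate --config sim.yaml --out data/ --seed 1
lncgx select --expr data/cell_expression.tsv --response data/ \
      --bootstraps 200 --cutoff 0.25 --seed 1 --out sel/
lncgx train --expr data/cell_expression.tsv --response data/ \
      --ps sel/ps_matrix.tsv --out models/
lncgx patient-predict --models models/ --tumor-expr data/tumor_expression.tsv \
      --clinical data/clinical.tsv --out preds.tsv
lncgx survival --predictions preds.tsv --clinical data/clinical.tsv \
      --approved approved.yaml --out survival.json
```

Every stage is byte-deterministic for a fixed `--seed`.

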