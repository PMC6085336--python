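"""Synthetic pharmacogenomic panels with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: z-scored lncRNA expression with cancer-type mean shifts, drug
response driven by a sparse linear model over planted predictive lncRNAs
plus lineage offsets and Gaussian noise, tumor cohorts sharing the
cell-line type signatures, proportional-hazards survival tied to the true
resistance score, concordant copy-number/methylation alterations, and
pathway-structured lncRNA-PCG co-expression. Every quantity needed to score
recovery (true coefficients, type signatures, planted gene sets, hazard
effects) is returned as :class:`GroundTruth`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import (
    ClinicalTable,
    DrugResponsePanel,
    FeatureMatrix,
    GeneSetCollection,
    ValidationError,
    write_seg,
)


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation settings."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults are the conditions the recovery analyses are run at: a
    GDSC-sized-down panel of 100 cell lines and 500 lncRNAs with 10 planted
    predictive lncRNAs per agent at effect size 0.8 ln-IC50 units per
    z-unit and response noise sd 0.5.
    """

    n_cell_lines: int = 100
    n_tumors: int = 500
    n_lncRNAs: int = 500
    n_pcgs: int = 2000
    n_agents: int = 10
    n_cancer_types: int = 6
    n_pathways: int = 5
    k_true_per_agent: int = 10
    effect_size: float = 0.8
    noise_sd: float = 0.5
    type_shift: float = 1.0
    lineage_effect_sd: float = 0.5
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    log_hr_resistance: float = math.log(2.0)
    censoring_rate: float = 0.3
    coexpr_loading: float = 0.8
    geneset_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_cell_lines, self.n_tumors, self.n_lncRNAs, self.n_pcgs,
            self.n_agents, self.n_cancer_types, self.n_pathways,
            self.k_true_per_agent,
        ]
        if any(c <= 0 for c in counts):
            raise ConfigurationError("all counts must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigurationError("censoring_rate must be in [0, 1)")
        if self.k_true_per_agent >= self.n_lncRNAs:
            raise ConfigurationError("k_true_per_agent must be < n_lncRNAs")
        if self.n_pathways > self.n_pcgs:
            raise ConfigurationError("n_pathways must not exceed n_pcgs")


@dataclass
class GroundTruth:
    """Planted effects used by the recovery tests."""

    true_coefficients: pd.DataFrame  # agents x lncRNAs, sparse-by-content
    agent_pathway: dict[str, str]
    type_signatures: pd.DataFrame  # cancer types x lncRNAs mean shifts
    planted_gene_sets: dict[str, dict] = field(default_factory=dict)
    true_log_hr: dict[str, float] = field(default_factory=dict)
    approved_map: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_coefficients": {
                agent: {f: float(v) for f, v in row[row != 0].items()}
                for agent, row in self.true_coefficients.iterrows()
            },
            "agent_pathway": self.agent_pathway,
            "type_signatures": {
                t: {f: float(v) for f, v in row[row != 0].items()}
                for t, row in self.type_signatures.iterrows()
            },
            "lncRNA_ids": list(self.true_coefficients.columns),
            "planted_gene_sets": self.planted_gene_sets,
            "true_log_hr": self.true_log_hr,
            "approved_map": self.approved_map,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        lnc = payload["lncRNA_ids"]
        coef = pd.DataFrame(0.0, index=list(payload["true_coefficients"]), columns=lnc)
        for agent, row in payload["true_coefficients"].items():
            for f, v in row.items():
                coef.at[agent, f] = v
        sig = pd.DataFrame(0.0, index=list(payload["type_signatures"]), columns=lnc)
        for t, row in payload["type_signatures"].items():
            for f, v in row.items():
                sig.at[t, f] = v
        return cls(
            true_coefficients=coef,
            agent_pathway=payload["agent_pathway"],
            type_signatures=sig,
            planted_gene_sets=payload["planted_gene_sets"],
            true_log_hr=payload["true_log_hr"],
            approved_map=payload["approved_map"],
        )


def _ids(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _type_labels(config: SimulationConfig, sample_ids: list[str]) -> pd.Series:
    types = _ids("TYPE", config.n_cancer_types)
    return pd.Series(
        [types[i % len(types)] for i in range(len(sample_ids))],
        index=sample_ids, name="cancer_type",
    )


def _build_truth(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    lnc = _ids("LNC", config.n_lncRNAs)
    agents = _ids("DRUG", config.n_agents)
    pathways = _ids("PW", config.n_pathways)
    types = _ids("TYPE", config.n_cancer_types)

    agent_pathway = {a: pathways[i % len(pathways)] for i, a in enumerate(agents)}

    # Pathway-sharing support: agents in the same pathway share a "core" of
    # ceil(k/2) lncRNAs; the remainder is private per agent. Core and private
    # pools are disjoint across pathways so sharing is attributable.
    k = config.k_true_per_agent
    n_core = -(-k // 2)  # ceil
    coef = pd.DataFrame(0.0, index=agents, columns=lnc)
    pool = rng.permutation(config.n_lncRNAs)
    cursor = 0
    cores: dict[str, np.ndarray] = {}
    for pw in pathways:
        cores[pw] = pool[cursor : cursor + n_core]
        cursor += n_core
    if cursor > config.n_lncRNAs:
        raise ConfigurationError("not enough lncRNAs for disjoint planted supports")
    for a in agents:
        core = cores[agent_pathway[a]]
        n_priv = k - n_core
        priv = pool[cursor : cursor + n_priv]
        cursor += n_priv
        if cursor > config.n_lncRNAs:
            raise ConfigurationError("not enough lncRNAs for disjoint planted supports")
        idx = np.concatenate([core, priv]).astype(int)
        signs = rng.choice([-1.0, 1.0], size=idx.size)
        coef.iloc[coef.index.get_loc(a), idx] = config.effect_size * signs

    # Each type shifts a contiguous disjoint block of features.
    block = config.n_lncRNAs // config.n_cancer_types
    sig = pd.DataFrame(0.0, index=types, columns=lnc)
    for t_i, t in enumerate(types):
        lo = t_i * block
        hi = min(lo + block, config.n_lncRNAs)
        sig.iloc[t_i, lo:hi] = config.type_shift

    # Planted co-expressed gene sets: one per pathway, partnered with that
    # pathway's first core lncRNA.
    pcgs = _ids("PCG", config.n_pcgs)
    planted: dict[str, dict] = {}
    pcg_cursor = 0
    for pw in pathways:
        size = min(config.geneset_size, config.n_pcgs - pcg_cursor)
        if size < 1:
            break
        members = pcgs[pcg_cursor : pcg_cursor + size]
        pcg_cursor += size
        planted[f"SET_{pw}"] = {
            "genes": members,
            "lncRNA": lnc[int(cores[pw][0])],
            "loading": config.coexpr_loading,
        }

    # Approved-drug map: each type gets 2 first-line and 1 second-line agent,
    # assigned cyclically.
    approved: dict[str, dict[str, list[str]]] = {}
    for t_i, t in enumerate(types):
        first = [agents[(3 * t_i) % len(agents)], agents[(3 * t_i + 1) % len(agents)]]
        second = [agents[(3 * t_i + 2) % len(agents)]]
        approved[t] = {"first_line": sorted(set(first)), "second_line": second}

    return GroundTruth(
        true_coefficients=coef,
        agent_pathway=agent_pathway,
        type_signatures=sig,
        planted_gene_sets=planted,
        true_log_hr={"resistance": config.log_hr_resistance},
        approved_map=approved,
    )


def _expression(
    rng: np.random.Generator,
    sample_ids: list[str],
    labels: pd.Series,
    signatures: pd.DataFrame,
) -> pd.DataFrame:
    n, p = len(sample_ids), signatures.shape[1]
    x = rng.standard_normal((n, p))
    x += signatures.loc[labels.values].to_numpy()
    return pd.DataFrame(x, index=sample_ids, columns=signatures.columns)


def simulate_cell_line_panel(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> tuple[FeatureMatrix, DrugResponsePanel, pd.Series, GroundTruth]:
    """Cell-line expression, drug response, lineage labels, and ground truth.

    ln(IC50) of agent j is sum_u beta_ju x_u plus a per-(type, agent)
    lineage offset and N(0, noise_sd) noise. AUC is a per-agent logistic
    transform of ln(IC50) (centered at the panel median) with small
    independent noise, following the convention that a larger viability AUC
    means a more resistant line. Identical configs give identical output.

    Passing an existing ``truth`` replays the same planted effects with
    fresh sampling noise (an independent replication panel).
    """
    rng = np.random.default_rng(np.random.SeedSequence([1, config.seed]))
    if truth is None:
        truth = _build_truth(config, rng)
    else:
        _build_truth(config, rng)  # keep the noise stream aligned with fresh runs
    cells = _ids("CL", config.n_cell_lines)
    labels = _type_labels(config, cells)
    expr = _expression(rng, cells, labels, truth.type_signatures)

    beta = truth.true_coefficients.to_numpy().T  # p x agents
    ln_ic50 = expr.to_numpy() @ beta
    offsets = rng.normal(
        0.0, config.lineage_effect_sd, size=(config.n_cancer_types, config.n_agents)
    )
    type_idx = pd.Index(truth.type_signatures.index).get_indexer(labels.values)
    ln_ic50 = ln_ic50 + offsets[type_idx]
    ln_ic50 = ln_ic50 + rng.normal(0.0, config.noise_sd, size=ln_ic50.shape)
    ln_ic50_df = pd.DataFrame(ln_ic50, index=cells, columns=truth.true_coefficients.index)

    med = np.median(ln_ic50, axis=0)
    scale = ln_ic50.std(axis=0, ddof=1)
    scale = np.where(scale == 0, 1.0, scale)
    auc = 1.0 / (1.0 + np.exp(-(ln_ic50 - med) / scale))
    auc = auc + rng.normal(0.0, 0.01, size=auc.shape)
    auc = np.clip(auc, 0.0, 1.0)
    auc_df = pd.DataFrame(auc, index=cells, columns=ln_ic50_df.columns)

    meta = pd.DataFrame(
        {
            "pathway": [truth.agent_pathway[a] for a in ln_ic50_df.columns],
            "clinical_status": [
                "approved" if i % 2 == 0 else "experimental"
                for i in range(config.n_agents)
            ],
        },
        index=ln_ic50_df.columns,
    )
    panel = DrugResponsePanel(ln_ic50=ln_ic50_df, auc=auc_df, agent_meta=meta)
    fm = FeatureMatrix(data=expr, normalized=True)
    return fm, panel, labels, truth


def true_resistance_score(expr: FeatureMatrix, truth: GroundTruth) -> pd.Series:
    """Standardized mean planted-model response over agents, per sample.

    This is the latent score the survival generator ties hazard to.
    """
    beta = truth.true_coefficients.reindex(columns=expr.feature_ids).to_numpy().T
    raw = expr.data.to_numpy() @ beta
    score = raw.mean(axis=1)
    sd = score.std(ddof=1)
    z = (score - score.mean()) / (sd if sd > 0 else 1.0)
    return pd.Series(z, index=expr.data.index, name="true_resistance")


def simulate_tumor_cohort(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[FeatureMatrix, ClinicalTable]:
    """Tumor expression sharing the cell-line type signatures, plus clinical data.

    Survival times come from an exponential proportional-hazards model whose
    log hazard is ``log_hr_resistance`` per standard deviation of the true
    resistance score; censoring is an independent exponential calibrated so
    the expected censored fraction at score 0 equals ``censoring_rate``. The
    generator's latent score is kept in the clinical table as the
    ``true_resistance`` column for recovery checks.
    """
    if truth is None:
        raise ValidationError("ground truth required (run simulate_cell_line_panel first)")
    rng = np.random.default_rng(np.random.SeedSequence([2, config.seed]))
    tumors = _ids("PT", config.n_tumors)
    labels = _type_labels(config, tumors)
    expr_df = _expression(rng, tumors, labels, truth.type_signatures)
    expr = FeatureMatrix(data=expr_df, normalized=True)

    score = true_resistance_score(expr, truth)
    hazard = config.baseline_hazard * np.exp(config.log_hr_resistance * score.to_numpy())
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        cens_rate = config.baseline_hazard * config.censoring_rate / (1 - config.censoring_rate)
        cens_time = rng.exponential(1.0 / cens_rate, size=config.n_tumors)
    else:
        cens_time = np.full(config.n_tumors, np.inf)
    os_time = np.minimum(event_time, cens_time)
    os_event = (event_time <= cens_time).astype(int)

    stages = rng.choice(["I", "II", "III", "IV"], size=config.n_tumors)
    ages = rng.integers(30, 91, size=config.n_tumors)
    treatments = []
    for t in labels.values:
        approved = truth.approved_map.get(t, {"first_line": [], "second_line": []})
        drugs = approved["first_line"] + approved["second_line"]
        n_take = int(rng.integers(1, min(3, len(drugs)) + 1)) if drugs else 0
        take = sorted(rng.choice(drugs, size=n_take, replace=False)) if n_take else []
        treatments.append(list(take))

    clinical = ClinicalTable(
        data=pd.DataFrame(
            {
                "cancer_type": labels.values,
                "stage": stages,
                "age": ages,
                "os_time": os_time,
                "os_event": os_event,
                "treatments": treatments,
                "true_resistance": score.to_numpy(),
            },
            index=tumors,
        )
    )
    return expr, clinical


def simulate_multiomics_and_genesets(
    config: SimulationConfig,
    truth: GroundTruth,
    lnc_expr: FeatureMatrix,
    labels: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str], GeneSetCollection, FeatureMatrix]:
    """Copy-number segments, methylation betas, gene sets, and PCG expression.

    CNV segment values and methylation betas carry the same cancer-type
    signatures as expression (scaled to their own dynamic ranges), so
    fold-changes are concordant across modalities. PCG expression for each
    planted gene set's members is partner-lncRNA expression x loading plus
    sqrt(1 - loading^2) noise. Returns (segments, beta matrix, probe map,
    gene sets, PCG matrix); segments use 0-based half-open coordinates with
    each lncRNA i occupying [1000*i, 1000*i + 600) on chr1.
    """
    if config.n_pathways > config.n_pcgs:
        raise ConfigurationError("n_pathways must not exceed n_pcgs")
    rng = np.random.default_rng(np.random.SeedSequence([3, config.seed]))
    lnc = list(truth.type_signatures.columns)
    p = len(lnc)
    samples = list(labels.index)
    shifts = truth.type_signatures.loc[labels.values].to_numpy()  # n x p

    # CNV: piecewise-constant segments over blocks of 10 features.
    block = 10
    rows = []
    for si, sample in enumerate(samples):
        for lo in range(0, p, block):
            hi = min(lo + block, p)
            value = 0.2 * shifts[si, lo:hi].mean() + rng.normal(0.0, 0.05)
            rows.append((sample, "chr1", 1000 * lo, 1000 * (hi - 1) + 600, value))
    segments = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "value"])

    # Methylation: two probes per lncRNA; betas shifted with the signature.
    probe_map = {}
    probe_cols = []
    for f in lnc:
        for j in (1, 2):
            probe = f"{f}_p{j}"
            probe_map[probe] = f
            probe_cols.append(probe)
    base = 0.5 + 0.08 * np.repeat(shifts, 2, axis=1)
    betas = np.clip(base + rng.normal(0.0, 0.05, size=base.shape), 0.0, 1.0)
    beta_df = pd.DataFrame(betas, index=samples, columns=probe_cols)

    # PCG expression with planted co-expression structure.
    pcgs = _ids("PCG", config.n_pcgs)
    pcg = rng.standard_normal((len(samples), config.n_pcgs))
    pcg_df = pd.DataFrame(pcg, index=samples, columns=pcgs)
    lnc_data = lnc_expr.data
    for info in truth.planted_gene_sets.values():
        partner = lnc_data[info["lncRNA"]].to_numpy()
        partner_z = (partner - partner.mean()) / (partner.std(ddof=0) or 1.0)
        loading = float(info["loading"])
        resid = math.sqrt(max(0.0, 1.0 - loading**2))
        for g in info["genes"]:
            pcg_df[g] = loading * partner_z + resid * rng.standard_normal(len(samples))

    sets = {name: list(info["genes"]) for name, info in truth.planted_gene_sets.items()}
    # Add size-matched random background sets for enrichment calibration.
    for i in range(config.n_pathways):
        members = sorted(rng.choice(pcgs, size=config.geneset_size, replace=False))
        sets[f"RANDOM_{i:02d}"] = members
    collection = GeneSetCollection(sets=sets)
    return segments, beta_df, probe_map, collection, FeatureMatrix(data=pcg_df)


def lncrna_regions(n_lncRNAs: int) -> pd.DataFrame:
    """Genomic intervals the generator places lncRNAs at (chr1, 1 kb grid)."""
    lnc = _ids("LNC", n_lncRNAs)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [1000 * i for i in range(n_lncRNAs)],
            "end": [1000 * i + 600 for i in range(n_lncRNAs)],
        },
        index=lnc,
    )


def write_simulation(config: SimulationConfig, outdir: str | Path) -> None:
    """Run the full generator and write every artifact as plain text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, panel, labels, truth = simulate_cell_line_panel(config)
    tumor_expr, clinical = simulate_tumor_cohort(config, truth)
    segments, betas, probe_map, sets, pcg = simulate_multiomics_and_genesets(
        config, truth, expr, labels
    )
    expr.to_tsv(outdir / "cell_expression.tsv")
    tumor_expr.to_tsv(outdir / "tumor_expression.tsv")
    panel.to_dir(outdir)
    labels.rename("cancer_type").to_csv(outdir / "cell_labels.tsv", sep="\t", index_label="sample")
    clinical.to_tsv(outdir / "clinical.tsv")
    write_seg(segments, outdir / "cnv_segments.seg")
    betas.to_csv(outdir / "methylation_betas.tsv", sep="\t", index_label="sample")
    pd.Series(probe_map, name="feature").to_csv(
        outdir / "probe_map.tsv", sep="\t", index_label="probe"
    )
    sets.to_gmt(outdir / "gene_sets.gmt")
    pcg.to_tsv(outdir / "pcg_expression.tsv")
    truth.to_json(outdir / "ground_truth.json")
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True)
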