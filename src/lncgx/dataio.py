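"""Data containers and file I/O for the pharmacogenomic pipeline.

In-memory containers are thin wrappers around pandas objects. On disk,
expression matrices are TSV with features as rows and a header row of sample
IDs (the layout expression portals distribute), drug-response panels are
cell-line x agent TSVs, gene sets are GMT, and copy-number segments are
SEG-like TSVs with 0-based half-open coordinates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("I", "II", "III", "IV")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class FeatureMatrix:
    """Samples x features real matrix with unique identifiers on both axes.

    ``data`` is indexed by sample ID with feature IDs as columns.
    ``normalized`` records whether :func:`normalize_expression` has been
    applied; normalizing twice is refused.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample identifiers")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate feature identifiers")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_tsv(self, path: str | Path) -> None:
        # stored features x samples
        self.data.T.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path: str | Path, normalized: bool = False) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(data=df.T, normalized=normalized)


@dataclass
class DrugResponsePanel:
    """Cell line x agent response readouts: ln(IC50) and AUC.

    Missing entries (untested combinations) are NaN. ``agent_meta`` maps each
    agent to its target pathway and, where known, clinical status and the
    cancer types for which it is approved (with treatment line).
    """

    ln_ic50: pd.DataFrame
    auc: pd.DataFrame
    agent_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.ln_ic50.index.equals(self.auc.index) or not self.ln_ic50.columns.equals(
            self.auc.columns
        ):
            raise ValidationError("ln_ic50 and auc must share cell line and agent index sets")
        finite = self.auc.to_numpy()[np.isfinite(self.auc.to_numpy())]
        if finite.size and (finite.min() < -0.1 or finite.max() > 1.1):
            raise ValidationError("AUC values outside [0, 1] beyond noise tolerance")

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.ln_ic50.index)

    @property
    def agent_ids(self) -> list[str]:
        return list(self.ln_ic50.columns)

    def response(self, metric: str = "ic50") -> pd.DataFrame:
        if metric == "ic50":
            return self.ln_ic50
        if metric == "auc":
            return self.auc
        raise ValidationError(f"unknown response metric: {metric!r}")

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.ln_ic50.to_csv(outdir / "ln_ic50.tsv", sep="\t", index_label="cell_line")
        self.auc.to_csv(outdir / "auc.tsv", sep="\t", index_label="cell_line")
        if self.agent_meta is not None:
            self.agent_meta.to_csv(outdir / "agent_meta.tsv", sep="\t", index_label="agent")

    @classmethod
    def from_dir(cls, indir: str | Path) -> "DrugResponsePanel":
        indir = Path(indir)
        ln_ic50 = pd.read_csv(indir / "ln_ic50.tsv", sep="\t", index_col=0)
        auc = pd.read_csv(indir / "auc.tsv", sep="\t", index_col=0)
        meta_path = indir / "agent_meta.tsv"
        meta = pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path.exists() else None
        return cls(ln_ic50=ln_ic50, auc=auc, agent_meta=meta)


@dataclass
class ClinicalTable:
    """Per-patient clinical annotations and survival endpoints.

    Columns: cancer_type, stage (I-IV), age (years), os_time (days),
    os_event (0/1), optional pfi_time/pfi_event, treatments (list of drug
    names; serialized ';'-joined).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if (d["os_time"] < 0).any():
            raise ValidationError("negative survival times")
        if not d["os_event"].isin([0, 1]).all():
            raise ValidationError("os_event must be 0/1")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        if "treatments" in out.columns:
            out["treatments"] = out["treatments"].map(
                lambda t: ";".join(t) if isinstance(t, (list, tuple)) else (t or "")
            )
        out.to_csv(path, sep="\t", index_label="patient_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClinicalTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if "treatments" in df.columns:
            df["treatments"] = df["treatments"].fillna("").map(
                lambda s: [x for x in str(s).split(";") if x] if s else []
            )
        return cls(data=df)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-compatible)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, "na", *members]) + "\n")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sets[parts[0]] = [g for g in parts[2:] if g]
        return cls(sets=sets)


# ---------------------------------------------------------------------------
# pre-processing operations
# ---------------------------------------------------------------------------


def normalize_expression(raw: FeatureMatrix, pseudocount: float = 1.0) -> FeatureMatrix:
    """ln(x + pseudocount) then per-feature z-score (sample sd, ddof=1).

    Constant features are set to all-zero and reported via a log warning.
    Refuses to run on an already-normalized matrix.
    """
    if raw.normalized:
        raise ValidationError("matrix is already normalized")
    values = raw.data.to_numpy(dtype=float)
    if np.nanmin(values) < 0:
        raise ValidationError("expression values must be non-negative before log transform")
    logged = np.log(values + pseudocount)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1) if logged.shape[0] > 1 else np.zeros(logged.shape[1])
    constant = (np.ptp(logged, axis=0) == 0) | (sd == 0)
    if constant.any():
        logger.warning(
            "normalize_expression: %d constant feature(s) set to zero: %s",
            int(constant.sum()),
            list(raw.data.columns[constant][:10]),
        )
    safe_sd = np.where(constant, 1.0, sd)
    z = (logged - mean) / safe_sd
    z[:, constant] = 0.0
    return FeatureMatrix(
        data=pd.DataFrame(z, index=raw.data.index, columns=raw.data.columns),
        normalized=True,
    )


SEG_COLUMNS = ["sample", "chrom", "start", "end", "value"]


def read_seg(path: str | Path) -> pd.DataFrame:
    seg = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in seg.columns]
    if missing:
        raise ValidationError(f"SEG file missing columns: {missing}")
    return seg


def write_seg(segments: pd.DataFrame, path: str | Path) -> None:
    segments[SEG_COLUMNS].to_csv(path, sep="\t", index=False)


def map_segments_to_regions(
    segments: pd.DataFrame, regions: pd.DataFrame
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Overlap-length-weighted mean of segment values over feature regions.

    ``segments``: columns sample, chrom, start, end, value (0-based half-open,
    per-sample non-overlapping). ``regions``: index = feature IDs, columns
    chrom, start, end. Returns the sample x feature matrix (NaN where a
    region has no overlap) and a parallel coverage-fraction matrix.
    """
    if (regions["start"] >= regions["end"]).any():
        raise ValidationError("malformed region interval (start >= end)")
    if (segments["start"] >= segments["end"]).any():
        raise ValidationError("malformed segment interval (start >= end)")
    samples = list(pd.unique(segments["sample"]))
    values = pd.DataFrame(np.nan, index=samples, columns=regions.index, dtype=float)
    coverage = pd.DataFrame(0.0, index=samples, columns=regions.index, dtype=float)
    for (sample, chrom), seg in segments.groupby(["sample", "chrom"], sort=False):
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        vals = seg["value"].to_numpy(dtype=float)
        sub = regions[regions["chrom"] == chrom]
        for fid, row in sub.iterrows():
            ov = np.minimum(ends, row["end"]) - np.maximum(starts, row["start"])
            ov = np.clip(ov, 0, None)
            total = ov.sum()
            if total > 0:
                values.at[sample, fid] = float((ov * vals).sum() / total)
                coverage.at[sample, fid] = float(total / (row["end"] - row["start"]))
    return FeatureMatrix(data=values), coverage


def summarize_probes(
    betas: pd.DataFrame, probe_map: dict[str, str]
) -> FeatureMatrix:
    """Aggregate probe-level methylation beta values to features.

    ``betas``: samples x probes, values in [0, 1]. ``probe_map``: probe ->
    feature. Per-feature value is the unweighted mean over mapped probes;
    features with no probes are absent from the output.
    """
    arr = betas.to_numpy(dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValidationError("beta values must lie in [0, 1]")
    groups: dict[str, list[str]] = {}
    for probe, feature in probe_map.items():
        if probe in betas.columns:
            groups.setdefault(feature, []).append(probe)
    cols = {feat: betas[probes].mean(axis=1) for feat, probes in sorted(groups.items())}
    data = pd.DataFrame(cols, index=betas.index) if cols else pd.DataFrame(index=betas.index)
    return FeatureMatrix(data=data)
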