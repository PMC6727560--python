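"""Core data model: annotated FPKM matrices, TSV I/O, and expression filters.

The expression dialect is tab-separated UTF-8 with a ``gene_id`` first column
and one column per sample; values are nonnegative FPKM with "." decimals and
no missing entries.  All downstream statistics operate on ``log2(x + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Ordered developmental stages: embryonic stem cells, derived cardiac
#: precursors, embryonic hearts (single cell), neonates, adults.
STAGES = ("ES", "CP", "E8.5", "E9.5", "E10.5", "P1", "Adult")

#: Aliases accepted in external tables for each canonical stage label.
STAGE_ALIASES = {
    "ES": "ES",
    "CP": "CP",
    "8.5": "E8.5",
    "9.5": "E9.5",
    "10.5": "E10.5",
    "E8.5": "E8.5",
    "E9.5": "E9.5",
    "E10.5": "E10.5",
    "p1": "P1",
    "P1": "P1",
    "Adult": "Adult",
    "Ad": "Adult",
}

SEXES = ("male", "female", "unknown")
REG_CLASSES = ("TF", "ERE", "other")


def stage_index(stage: str) -> int:
    """Position of ``stage`` in the developmental ordering."""
    try:
        return STAGES.index(STAGE_ALIASES.get(stage, stage))
    except ValueError:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}") from None


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene annotation: location, regulatory class, display symbol."""

    gene_id: str
    symbol: str = ""
    chromosome: str = ""
    tss: int = 0
    strand: str = "+"
    reg_class: str = "other"

    def __post_init__(self):
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.reg_class not in REG_CLASSES:
            raise ValueError(f"gene {self.gene_id}: reg_class must be one of {REG_CLASSES}")


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample (or per-cell) annotation."""

    sample_id: str
    sex: str = "unknown"
    stage: str = "ES"
    batch: str = ""
    cross: str = ""

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sample {self.sample_id}: sex must be one of {SEXES}, got {self.sex!r}")
        stage_index(self.stage)  # raises on unknown stage
        if self.stage not in STAGES:
            object.__setattr__(self, "stage", STAGE_ALIASES[self.stage])


@dataclass
class ExpressionMatrix:
    """Gene x sample FPKM matrix with parallel annotation lists."""

    values: pd.DataFrame
    genes: list[GeneAnnotation] = field(default_factory=list)
    samples: list[SampleAnnotation] = field(default_factory=list)

    def __post_init__(self):
        if not self.genes:
            self.genes = [GeneAnnotation(g) for g in self.values.index]
        if not self.samples:
            self.samples = [SampleAnnotation(s) for s in self.values.columns]
        self.validate()

    # -- structure -----------------------------------------------------
    def validate(self) -> None:
        v = self.values.to_numpy(dtype=float) if self.values.size else np.empty((len(self.values.index), 0))
        if v.size and (not np.isfinite(v).all()):
            raise ValueError("expression values must be finite")
        if v.size and (v < 0).any():
            i, j = np.argwhere(v < 0)[0]
            raise ValueError(
                f"negative expression value for gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        if len(self.genes) != len(self.values.index):
            raise ValueError("gene annotation length does not match row count")
        if len(self.samples) != len(self.values.columns):
            raise ValueError("sample annotation length does not match column count")
        for ann, gid in zip(self.genes, self.values.index):
            if ann.gene_id != gid:
                raise ValueError(f"gene annotation order mismatch at {gid!r}")
        for ann, sid in zip(self.samples, self.values.columns):
            if ann.sample_id != sid:
                raise ValueError(f"sample annotation order mismatch at {sid!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_annotation(self, gene_id: str) -> GeneAnnotation:
        return self.genes[self.values.index.get_loc(gene_id)]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        keep = set(gene_ids)
        idx = [i for i, g in enumerate(self.values.index) if g in keep]
        return ExpressionMatrix(
            self.values.iloc[idx].copy(),
            [self.genes[i] for i in idx],
            list(self.samples),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        keep = set(sample_ids)
        idx = [j for j, s in enumerate(self.values.columns) if s in keep]
        return ExpressionMatrix(
            self.values.iloc[:, idx].copy(),
            list(self.genes),
            [self.samples[j] for j in idx],
        )

    def samples_for(self, stage: str | None = None, sex: str | None = None) -> list[str]:
        """Sample ids restricted to a stage and/or sex."""
        out = []
        for ann in self.samples:
            if stage is not None and ann.stage != STAGE_ALIASES.get(stage, stage):
                continue
            if sex is not None and ann.sex != sex:
                continue
            out.append(ann.sample_id)
        return out


# ---------------------------------------------------------------------------
# I/O


def _read_gene_annotation(path: str | Path) -> dict[str, GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, GeneAnnotation] = {}
    for _, row in df.iterrows():
        gid = row["gene_id"]
        if gid in out:
            raise ValueError(f"duplicate gene_id {gid!r} in annotation {path}")
        out[gid] = GeneAnnotation(
            gene_id=gid,
            symbol=row.get("symbol", "") or gid,
            chromosome=row.get("chromosome", ""),
            tss=int(row["tss"]) if row.get("tss", "") else 0,
            strand=row.get("strand", "") or "+",
            reg_class=row.get("reg_class", "") or "other",
        )
    return out


def _read_sample_annotation(path: str | Path) -> dict[str, SampleAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, SampleAnnotation] = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in out:
            raise ValueError(f"duplicate sample_id {sid!r} in annotation {path}")
        out[sid] = SampleAnnotation(
            sample_id=sid,
            sex=row.get("sex", "") or "unknown",
            stage=row.get("stage", "") or "ES",
            batch=row.get("batch", ""),
            cross=row.get("cross", ""),
        )
    return out


def read_expression_tsv(
    path: str | Path,
    gene_annotation_path: str | Path | None = None,
    sample_annotation_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read the tab-separated expression dialect.

    First column is ``gene_id``; the header row carries sample ids.  Gene and
    sample annotation files are optional; unannotated fields take defaults
    (``reg_class='other'``, ``sex='unknown'``).  Samples present in the matrix
    but missing from a provided sample annotation are an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene_id {dup!r} in {path}")
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            values[col] = df[col].astype(float)
        except ValueError:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(f"non-numeric value for gene {bad!r}, sample {col!r} in {path}") from None
    arr = values.to_numpy()
    if arr.size and (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(f"negative value for gene {values.index[i]!r}, sample {values.columns[j]!r} in {path}")

    genes: list[GeneAnnotation] = []
    if gene_annotation_path is not None:
        ann = _read_gene_annotation(gene_annotation_path)
        genes = [ann.get(g, GeneAnnotation(g)) for g in values.index]
    samples: list[SampleAnnotation] = []
    if sample_annotation_path is not None:
        ann = _read_sample_annotation(sample_annotation_path)
        missing = [s for s in values.columns if s not in ann]
        if missing:
            raise ValueError(f"samples missing from annotation: {missing}")
        samples = [ann[s] for s in values.columns]
    return ExpressionMatrix(values, genes, samples)


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    """Emit the dialect read by :func:`read_expression_tsv` (6 decimals)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(m.sample_ids) + "\n")
        for gid, row in zip(m.gene_ids, m.values.to_numpy()):
            fh.write(gid + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def write_gene_annotation_tsv(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tsymbol\tchromosome\ttss\tstrand\treg_class\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.symbol}\t{g.chromosome}\t{g.tss}\t{g.strand}\t{g.reg_class}\n")


def write_sample_annotation_tsv(samples: Iterable[SampleAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tsex\tstage\tbatch\tcross\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.sex}\t{s.stage}\t{s.batch}\t{s.cross}\n")


# ---------------------------------------------------------------------------
# Expression filters


@dataclass
class ExpressionFlags:
    """Per-value and per-(gene, stage) expression calls at an FPKM threshold.

    ``not_expressed`` marks individual values below the threshold.  A gene is
    expressed at a stage when its mean FPKM over that stage's samples reaches
    the threshold in at least one sex group.
    """

    not_expressed: pd.DataFrame
    stage_presence: pd.DataFrame
    threshold: float


def filter_not_expressed(m: ExpressionMatrix, threshold: float = 1.0) -> tuple[ExpressionMatrix, ExpressionFlags]:
    """Flag values below ``threshold`` FPKM as not expressed.

    Returns the (unchanged) matrix together with value-level flags and a
    gene x stage presence table.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    not_expressed = m.values < threshold

    stages_present = sorted({s.stage for s in m.samples}, key=stage_index)
    presence = pd.DataFrame(False, index=m.values.index, columns=stages_present)
    for stage in stages_present:
        expressed_any_sex = np.zeros(len(m.values.index), dtype=bool)
        seen_group = False
        for sex in ("female", "male", "unknown"):
            cols = m.samples_for(stage=stage, sex=sex)
            if not cols:
                continue
            seen_group = True
            expressed_any_sex |= m.values[cols].mean(axis=1).to_numpy() >= threshold
        if seen_group:
            presence[stage] = expressed_any_sex
    return m, ExpressionFlags(not_expressed, presence, threshold)


def drop_zero_variance(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes whose values are identical across all samples."""
    arr = m.values.to_numpy()
    if arr.shape[1] == 0:
        return m
    keep_mask = ~(arr == arr[:, [0]]).all(axis=1)
    if not keep_mask.any():
        warnings.warn("all genes have zero variance; result is empty", stacklevel=2)
    idx = np.flatnonzero(keep_mask)
    return ExpressionMatrix(
        m.values.iloc[idx].copy(),
        [m.genes[i] for i in idx],
        list(m.samples),
    )


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every value x with log2(x + 1)."""
    arr = m.values.to_numpy(dtype=float)
    if arr.size and (arr < 0).any():
        raise ValueError("log_transform requires nonnegative values")
    return ExpressionMatrix(
        pd.DataFrame(np.log2(arr + 1.0), index=m.values.index, columns=m.values.columns),
        list(m.genes),
        list(m.samples),
    )
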