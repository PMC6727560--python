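"""Synthetic input generators with ground-truth sidecars.

Every generator is a pure function of its arguments and an explicit seed
(one ``numpy.random.default_rng`` stream per call, no global state), so a
fixed seed reproduces outputs byte for byte.  Expression noise is lognormal
(Normal on the log2 scale) because the pipeline consumes FPKM, not counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GeneAnnotation, SampleAnnotation


@dataclass
class TruthRecord:
    """Ground truth planted by a generator, for parameter-recovery tests."""

    sex_biased_genes: dict = field(default_factory=dict)  # gene_id -> {direction, effect_size, stages}
    planted_module: dict = field(default_factory=dict)  # {genes: [...], r_true: float, latent: [...]}
    cell_sexes: dict = field(default_factory=dict)  # cell_id -> "male"/"female"
    motif_placements: dict = field(default_factory=dict)  # seq_id -> [(offset, strand), ...]
    enriched_anchors: list = field(default_factory=list)  # [(contig, start, end), ...]
    community_assignment: dict = field(default_factory=dict)  # node -> community label

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def read(cls, path: str | Path) -> "TruthRecord":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        rec = cls(**d)
        rec.motif_placements = {
            k: [tuple(v) for v in vs] for k, vs in rec.motif_placements.items()
        }
        rec.enriched_anchors = [tuple(a) for a in rec.enriched_anchors]
        return rec


# ---------------------------------------------------------------------------
# Bulk expression panel (6 + 6 style design)


def simulate_bulk_panel(
    n_per_sex: int = 6,
    n_genes: int = 500,
    n_biased: int = 0,
    effect: float = 0.0,
    module_size: int = 0,
    r_module: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    stage: str = "ES",
    module_loading: float = 2.0,
) -> tuple[ExpressionMatrix, TruthRecord]:
    """Lognormal expression panel with planted sex effects and a planted module.

    Per gene, log2 expression is Normal(mu_g, noise_sd); biased genes have
    mu shifted by +/- effect/2 per sex (direction alternating XX/XY).  Module
    genes add ``module_loading * latent`` where the latent per-sample factor
    is constructed to have exactly the point-biserial correlation ``r_module``
    with the sex indicator.  Values are mapped back to FPKM as 2^x - 1.
    """
    if n_per_sex < 2:
        raise ValueError("n_per_sex must be >= 2")
    if module_size and module_size < 2:
        raise ValueError("module_size must be >= 2 (or 0 to disable)")
    if module_size > n_genes or n_biased > n_genes:
        raise ValueError("planted gene sets cannot exceed n_genes")
    if abs(r_module) > 1:
        raise ValueError("|r_module| must be <= 1")
    if effect < 0:
        raise ValueError("effect must be >= 0")

    rng = np.random.default_rng(seed)
    n_samples = 2 * n_per_sex
    sexes = np.array([1] * n_per_sex + [0] * n_per_sex)  # female=1, male=0
    sample_ids = [f"F{i+1}" for i in range(n_per_sex)] + [f"M{i+1}" for i in range(n_per_sex)]
    gene_ids = [f"g{i+1:04d}" for i in range(n_genes)]

    # sex indicator standardized to unit variance
    z_sex = (sexes - sexes.mean()) / sexes.std()

    # latent factor with exact sample correlation r_module to z_sex
    raw = rng.normal(size=n_samples)
    resid = raw - raw.mean()
    resid -= z_sex * (resid @ z_sex) / (z_sex @ z_sex)
    norm = np.linalg.norm(resid)
    if norm < 1e-12:
        resid = np.zeros_like(resid)
    else:
        resid = resid / norm * np.sqrt(n_samples)
    latent = r_module * z_sex + np.sqrt(max(0.0, 1 - r_module**2)) * resid

    mu = rng.uniform(3.0, 8.0, size=n_genes)
    log_expr = rng.normal(0.0, noise_sd, size=(n_genes, n_samples)) + mu[:, None]

    truth = TruthRecord()
    biased = gene_ids[:n_biased]
    for k, gid in enumerate(biased):
        direction = "XX" if k % 2 == 0 else "XY"
        shift = effect / 2.0 if direction == "XX" else -effect / 2.0
        log_expr[k] += np.where(sexes == 1, shift, -shift)
        truth.sex_biased_genes[gid] = {
            "direction": direction,
            "effect_size": effect,
            "stages": [stage],
        }

    module_genes = gene_ids[n_biased : n_biased + module_size]
    for k in range(n_biased, n_biased + module_size):
        log_expr[k] += module_loading * latent
    truth.planted_module = {
        "genes": list(module_genes),
        "r_true": float(r_module),
        "latent": [float(x) for x in latent],
    }
    truth.cell_sexes = {
        sid: ("female" if s == 1 else "male") for sid, s in zip(sample_ids, sexes)
    }

    fpkm = np.clip(np.exp2(log_expr) - 1.0, 0.0, None)
    values = pd.DataFrame(fpkm, index=gene_ids, columns=sample_ids)
    genes = [GeneAnnotation(g) for g in gene_ids]
    samples = [
        SampleAnnotation(sid, sex=("female" if s == 1 else "male"), stage=stage)
        for sid, s in zip(sample_ids, sexes)
    ]
    return ExpressionMatrix(values, genes, samples), truth


# ---------------------------------------------------------------------------
# Single-cell marker panels

#: probability that the "low" marker of a cell is zero before dropout
_LOW_MARKER_ZERO_P = 0.9


def simulate_cells(
    stage: str = "E9.5",
    n_cells: int = 100,
    female_fraction: float = 0.5,
    marker_mean: float = 50.0,
    dropout: float = 0.0,
    seed: int = 0,
    n_background: int = 10,
) -> tuple[ExpressionMatrix, TruthRecord]:
    """Single-cell matrix with Xist/Eif2s3y marker structure and dropout.

    Female cells express Xist highly and Eif2s3y at zero-inflated low levels;
    male cells the reverse.  Each marker value is then independently zeroed
    with probability ``dropout``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0 <= female_fraction <= 1:
        raise ValueError("female_fraction must be in [0, 1]")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")

    rng = np.random.default_rng(seed)
    n_female = int(round(n_cells * female_fraction))
    is_female = np.array([True] * n_female + [False] * (n_cells - n_female))
    cell_ids = [f"{stage}_c{i+1:04d}" for i in range(n_cells)]

    def high() -> np.ndarray:
        return marker_mean * np.exp2(rng.normal(0.0, 0.25, size=n_cells))

    def low() -> np.ndarray:
        vals = 0.05 * marker_mean * np.exp2(rng.normal(0.0, 0.25, size=n_cells))
        zero = rng.random(n_cells) < _LOW_MARKER_ZERO_P
        return np.where(zero, 0.0, vals)

    xist = np.where(is_female, high(), low())
    eif2s3y = np.where(is_female, low(), high())
    if dropout > 0:
        xist = np.where(rng.random(n_cells) < dropout, 0.0, xist)
        eif2s3y = np.where(rng.random(n_cells) < dropout, 0.0, eif2s3y)

    rows = {"Xist": xist, "Eif2s3y": eif2s3y}
    for k in range(n_background):
        rows[f"bg{k+1:03d}"] = np.exp2(rng.normal(4.0, 1.0, size=n_cells))
    values = pd.DataFrame(rows).T
    values.columns = cell_ids

    truth = TruthRecord(
        cell_sexes={cid: ("female" if f else "male") for cid, f in zip(cell_ids, is_female)}
    )
    genes = [
        GeneAnnotation(g, chromosome=("X" if g == "Xist" else "Y" if g == "Eif2s3y" else ""))
        for g in values.index
    ]
    samples = [SampleAnnotation(cid, sex="unknown", stage=stage) for cid in cell_ids]
    return ExpressionMatrix(values, genes, samples), truth


# ---------------------------------------------------------------------------
# Promoter sequences with planted motif instances

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_promoters(
    n_seqs: int,
    length: int,
    pfm,
    placement_prob: float = 0.0,
    seed: int = 0,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    out_path: str | Path | None = None,
) -> tuple[dict[str, str], TruthRecord]:
    """I.i.d. background sequences with motif instances planted at random.

    With probability ``placement_prob`` each sequence receives one instance
    sampled column-wise from the PFM probabilities, at a uniform offset and
    strand.  Returns ``{seq_id: sequence}`` and the placement truth; writes
    FASTA when ``out_path`` is given.
    """
    w = pfm.width
    if length < w:
        raise ValueError(f"length {length} shorter than motif width {w}")
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1) > 1e-9 or (bg <= 0).any():
        raise ValueError("background must be 4 positive probabilities summing to 1")

    rng = np.random.default_rng(seed)
    probs = pfm.counts / pfm.counts.sum(axis=0, keepdims=True)  # 4 x w
    seqs: dict[str, str] = {}
    truth = TruthRecord()
    for i in range(n_seqs):
        sid = f"seq{i+1:04d}"
        arr = _BASES[rng.choice(4, size=length, p=bg)]
        placements = []
        if rng.random() < placement_prob:
            inst = "".join(_BASES[rng.choice(4, p=probs[:, j])] for j in range(w))
            strand = "+" if rng.random() < 0.5 else "-"
            offset = int(rng.integers(0, length - w + 1))
            planted = inst if strand == "+" else reverse_complement(inst)
            arr[offset : offset + w] = list(planted)
            placements.append((offset, strand))
        seqs[sid] = "".join(arr)
        if placements:
            truth.motif_placements[sid] = placements
    if out_path is not None:
        write_fasta(seqs, out_path)
    return seqs, truth


def write_fasta(seqs: dict[str, str], path: str | Path, line_width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# Coverage tracks with planted enrichment


def simulate_coverage(
    anchors: Sequence[tuple[str, int, int]],
    enrichment: float = 1.0,
    width: int = 50,
    library_size: int = 100_000,
    seed: int = 0,
    contig_length: int | None = None,
    out_path: str | Path | None = None,
) -> tuple[list[tuple[str, int, int, float]], TruthRecord]:
    """Poisson background coverage, multiplied by ``enrichment`` inside anchors.

    Emits fixed-width bedGraph bins per contig.  The background Poisson mean
    per bin is ``library_size * width / contig_length``.
    """
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    contigs: dict[str, int] = {}
    for contig, start, end in anchors:
        if start < 0 or end <= start:
            raise ValueError(f"malformed interval {contig}:{start}-{end}")
        contigs[contig] = max(contigs.get(contig, 0), end)
    if not contigs:
        raise ValueError("at least one anchor/contig required")
    rng = np.random.default_rng(seed)
    lines: list[tuple[str, int, int, float]] = []
    truth = TruthRecord(enriched_anchors=[tuple(a) for a in anchors])
    for contig in sorted(contigs):
        clen = contig_length if contig_length is not None else contigs[contig] + 10 * width
        n_bins = int(np.ceil(clen / width))
        lam = library_size * width / clen
        counts = rng.poisson(lam, size=n_bins).astype(float)
        starts = np.arange(n_bins) * width
        ends = np.minimum(starts + width, clen)
        for contig_a, a_start, a_end in anchors:
            if contig_a != contig:
                continue
            hit = (starts < a_end) & (ends > a_start)
            counts[hit] *= enrichment
        lines.extend(
            (contig, int(s), int(e), float(c)) for s, e, c in zip(starts, ends, counts)
        )
    if out_path is not None:
        write_bedgraph(lines, out_path)
    return lines, truth


def write_bedgraph(lines: Sequence[tuple[str, int, int, float]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for contig, start, end, value in lines:
            fh.write(f"{contig}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# Planted-partition interaction graphs


def simulate_interactions(
    n_nodes: int,
    n_communities: int,
    p_in: float,
    p_out: float,
    seed: int = 0,
    score: float = 0.9,
    out_path: str | Path | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Stochastic block model edge list with the planted partition recorded."""
    if not 0 <= p_out < p_in <= 1:
        raise ValueError("need 0 <= p_out < p_in <= 1")
    if n_communities > n_nodes:
        raise ValueError("n_communities cannot exceed n_nodes")
    rng = np.random.default_rng(seed)
    nodes = [f"n{i+1:03d}" for i in range(n_nodes)]
    community = {nodes[i]: i % n_communities for i in range(n_nodes)}
    rows = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            p = p_in if community[nodes[i]] == community[nodes[j]] else p_out
            if rng.random() < p:
                rows.append((nodes[i], nodes[j], score))
    edges = pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])
    truth = TruthRecord(community_assignment={n: int(c) for n, c in community.items()})
    if out_path is not None:
        edges.to_csv(out_path, sep="\t", index=False)
    return edges, truth
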