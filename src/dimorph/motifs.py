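"""Known-motif promoter scanning with exact p-value score thresholds.

Position frequency matrices (JASPAR text format) are converted to log-odds
position weight matrices with a background-proportional pseudocount.  The
score threshold for a p-value cutoff comes from the exact null score
distribution, computed by dynamic programming over columns on a fixed score
grid (default grain 1e-3 bits); PWM scores are quantized to the same grid so
the DP distribution is exact for the scores actually used in scanning.

Promoter windows cover [-5000, +1000) around the TSS (half-open, 0-based,
strand-oriented, length 6000), truncated with a flag at contig ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneAnnotation
from .synth import reverse_complement

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DEFAULT_P_CUTOFF = 1e-5
DEFAULT_GRAIN = 1e-3
PROMOTER_UPSTREAM = 5000
PROMOTER_DOWNSTREAM = 1000


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix (rows A, C, G, T)."""

    motif_id: str
    name: str
    counts: np.ndarray  # 4 x w

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != 4 or c.shape[1] < 1:
            raise ValueError(f"motif {self.motif_id}: counts must be 4 x w with w >= 1")
        if (c < 0).any():
            raise ValueError(f"motif {self.motif_id}: negative counts")
        if (c.sum(axis=0) <= 0).any():
            raise ValueError(f"motif {self.motif_id}: zero column sum")
        object.__setattr__(self, "counts", c)

    @property
    def width(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class PWM:
    """Log-odds matrix over a background, scores quantized to ``grain`` bits."""

    motif_id: str
    name: str
    matrix: np.ndarray  # 4 x w, log2 odds
    background: np.ndarray
    pseudocount: float
    grain: float = DEFAULT_GRAIN

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.matrix.min(axis=0).sum())


def read_jaspar(path: str | Path) -> list[PFM]:
    """Parse JASPAR-format PFMs (``>ID NAME`` header + bracketed A/C/G/T rows)."""
    pfms: list[PFM] = []
    header: tuple[str, str] | None = None
    rows: dict[str, list[float]] = {}

    def flush():
        nonlocal header, rows
        if header is None:
            return
        missing = [b for b in BASES if b not in rows]
        if missing:
            raise ValueError(f"motif {header[0]}: missing base row(s) {missing}")
        widths = {len(rows[b]) for b in BASES}
        if len(widths) != 1:
            raise ValueError(f"motif {header[0]}: ragged count rows")
        pfms.append(PFM(header[0], header[1], np.array([rows[b] for b in BASES])))
        header, rows = None, {}

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                header = (parts[0], parts[1] if len(parts) > 1 else parts[0])
            else:
                base = line[0].upper()
                if base not in BASE_INDEX:
                    raise ValueError(f"unexpected row {line!r} in {path}")
                nums = line[1:].replace("[", " ").replace("]", " ").split()
                rows[base] = [float(x) for x in nums]
    flush()
    return pfms


def write_jaspar(pfms: Iterable[PFM], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.motif_id} {pfm.name}\n")
            for b in BASES:
                vals = " ".join(f"{x:g}" for x in pfm.counts[BASE_INDEX[b]])
                fh.write(f"{b} [ {vals} ]\n")


def pfm_to_pwm(
    pfm: PFM,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 1.0,
    grain: float = DEFAULT_GRAIN,
) -> PWM:
    """Log-odds PWM: prob_b = (count_b + pc*bg_b) / (total + pc)."""
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1) > 1e-9:
        raise ValueError("background must be 4 probabilities summing to 1")
    if (bg <= 0).any():
        raise ValueError("background entries must be positive")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    totals = pfm.counts.sum(axis=0)
    probs = (pfm.counts + pseudocount * bg[:, None]) / (totals + pseudocount)
    scores = np.log2(probs / bg[:, None])
    scores = np.round(scores / grain) * grain
    return PWM(pfm.motif_id, pfm.name, scores, bg, pseudocount, grain)


def score_distribution(pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the (quantized) score under the background.

    Returns (scores, probabilities) on the quantization grid, via column-wise
    dynamic programming (convolution of per-column score distributions).
    """
    grid = np.round(pwm.matrix / pwm.grain).astype(np.int64)  # 4 x w
    offset = grid.min(axis=0)  # per-column minimum
    dist = np.array([1.0])
    for j in range(pwm.width):
        col = grid[:, j] - offset[j]
        span = col.max() + 1
        step = np.zeros(span)
        for b in range(4):
            step[col[b]] += pwm.background[b]
        dist = np.convolve(dist, step)
    base = offset.sum()
    scores = (base + np.arange(dist.size)) * pwm.grain
    keep = dist > 0
    return scores[keep], dist[keep]


def score_threshold(pwm: PWM, p_cutoff: float = DEFAULT_P_CUTOFF) -> tuple[float, bool]:
    """Smallest score s with P(score >= s) <= p_cutoff under the background.

    Returns ``(threshold, attainable)``; when even the maximum score has tail
    probability above the cutoff, the maximum score is returned with
    ``attainable=False``.
    """
    if not 0 < p_cutoff <= 1:
        raise ValueError("p_cutoff must be in (0, 1]")
    scores, probs = score_distribution(pwm)
    tail = np.cumsum(probs[::-1])[::-1]  # tail[i] = P(score >= scores[i])
    ok = tail <= p_cutoff
    if not ok.any():
        return float(scores[-1]), False
    return float(scores[ok][0]), True


def hit_pvalue(pwm: PWM, score: float) -> float:
    scores, probs = score_distribution(pwm)
    return float(probs[scores >= score - 1e-12].sum())


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int  # 0-based forward-strand start
    strand: str
    score: float
    p: float


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def scan(
    sequences: Mapping[str, str],
    pwm: PWM,
    threshold: float,
) -> list[MotifHit]:
    """Scan both strands; windows containing non-ACGT bases are skipped.

    Hits are reported with forward-strand offsets and exact tail p-values.
    """
    w = pwm.width
    scores_grid, probs_grid = score_distribution(pwm)
    tail = np.cumsum(probs_grid[::-1])[::-1]

    def pval(s: float) -> float:
        idx = np.searchsorted(scores_grid, s - 1e-9)
        return float(tail[idx]) if idx < tail.size else 0.0

    hits: list[MotifHit] = []
    for sid, seq in sequences.items():
        enc = _encode(seq)
        n = enc.size
        if n < w:
            continue
        rc_matrix = pwm.matrix[::-1, ::-1]  # reverse complement scoring
        valid = enc >= 0
        for start in range(n - w + 1):
            win = enc[start : start + w]
            if not valid[start : start + w].all():
                continue
            fwd = float(pwm.matrix[win, np.arange(w)].sum())
            rev = float(rc_matrix[win, np.arange(w)].sum())
            if fwd >= threshold - 1e-12:
                hits.append(MotifHit(sid, start, "+", fwd, pval(fwd)))
            if rev >= threshold - 1e-12:
                hits.append(MotifHit(sid, start, "-", rev, pval(rev)))
    return hits


def hits_to_bed(hits: Sequence[MotifHit], pwm: PWM, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.offset}\t{h.offset + pwm.width}\t"
                f"{pwm.motif_id}\t{h.score:.4f}\t{h.strand}\n"
            )


# ---------------------------------------------------------------------------
# Promoter extraction


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    contig: str
    start: int  # 0-based half-open on the forward strand
    end: int
    strand: str
    truncated: bool
    sequence: str


def extract_promoters(
    genes: Sequence[GeneAnnotation],
    genome: Mapping[str, str] | str | Path,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> list[PromoterWindow]:
    """Strand-oriented promoter windows [-upstream, +downstream) of the TSS.

    ``genome`` may be a {contig: sequence} mapping or a FASTA path (read via
    pyfaidx).  Minus-strand windows are reverse-complemented.  Windows
    clipped at contig bounds carry ``truncated=True``.
    """
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(genome))
        contigs = {name: str(fa[name][:]) for name in fa.keys()}
    else:
        contigs = dict(genome)
    out = []
    for g in genes:
        if g.chromosome not in contigs:
            raise ValueError(f"gene {g.gene_id}: contig {g.chromosome!r} not in genome")
        seq = contigs[g.chromosome]
        if g.strand == "+":
            lo, hi = g.tss - upstream, g.tss + downstream
        else:
            lo, hi = g.tss - downstream, g.tss + upstream
        start, end = max(0, lo), min(len(seq), hi)
        truncated = (start != lo) or (end != hi)
        window = seq[start:end]
        if g.strand == "-":
            window = reverse_complement(window)
        out.append(PromoterWindow(g.gene_id, g.chromosome, start, end, g.strand, truncated, window))
    return out


def motif_enrichment(
    target_hits: Mapping[str, bool],
    background_hits: Mapping[str, bool],
) -> float:
    """One-sided hypergeometric upper-tail p for motif presence (ZOOPS).

    ``background_hits`` defines the universe (one flag per gene, zero-or-one
    occurrence); ``target_hits`` must be a subset of it.
    """
    universe = set(background_hits)
    targets = set(target_hits)
    if not targets <= universe:
        raise ValueError("target genes must be a subset of the background universe")
    N = len(universe)
    K = sum(bool(v) for v in background_hits.values())
    n = len(targets)
    x = sum(bool(v) for v in target_hits.values())
    if x > min(K, n):
        raise ValueError(f"inconsistent inputs: x={x} exceeds min(K={K}, n={n})")
    return float(stats.hypergeom.sf(x - 1, N, K, n))
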