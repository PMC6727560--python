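"""Gene x stage bias trajectories and their classification.

Stage codes are XX (female-enriched), XY (male-enriched), nb (expressed but
not biased), and absent (not expressed).  Trajectories are classified into:

* group I    -- biased in ES cells and absent at every later stage;
* group II   -- biased in ES cells with later bias only in the same direction;
* group III  -- biased in ES cells with a later bias in the opposite
                direction (takes precedence over II);
* lost       -- biased in ES cells, later stages expressed (>= 1 nb) but
                never biased again;
* group IV   -- first bias after ES but before gonadogenesis (CP..E10.5);
* group V    -- first bias at P1 or Adult (after gonadogenesis);
* never_biased otherwise.

The gonadogenesis boundary sits between E10.5 and P1.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import STAGES, STAGE_ALIASES, GeneAnnotation, stage_index

CODES = ("XX", "XY", "nb", "absent")
BIASED = ("XX", "XY")
PRE_GONADAL_STAGES = ("CP", "E8.5", "E9.5", "E10.5")
POST_GONADAL_STAGES = ("P1", "Adult")

#: external TSV column headers for the seven stages
_TSV_STAGE_COLUMNS = ("ES", "CP", "8.5", "9.5", "10.5", "p1", "Adult")


@dataclass
class BiasTable:
    """Per-gene, per-stage bias codes plus chromosome annotation."""

    codes: pd.DataFrame  # index gene, columns STAGES, values in CODES
    chromosomes: pd.Series = field(default_factory=pd.Series)  # gene -> chromosome

    def __post_init__(self):
        bad = set(self.codes.to_numpy().ravel()) - set(CODES)
        if bad:
            raise ValueError(f"unknown bias codes: {sorted(bad)}")
        if list(self.codes.columns) != list(STAGES):
            raise ValueError(f"stage columns must be {STAGES}, got {list(self.codes.columns)}")
        if self.codes.index.has_duplicates:
            dup = self.codes.index[self.codes.index.duplicated()][0]
            raise ValueError(f"duplicate gene entry {dup!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.codes.index)

    def row(self, gene: str) -> tuple[str, ...]:
        return tuple(self.codes.loc[gene])


def build_bias_table(
    stage_results: Mapping[str, pd.DataFrame],
    presence: Mapping[str, pd.Series] | None = None,
    chromosomes: Mapping[str, str] | None = None,
) -> BiasTable:
    """Assemble codes from per-stage DE tables and presence flags.

    Per gene and stage: ``absent`` when not expressed there (or the stage has
    no data for the gene), else the DE bias call (XX/XY/nb).
    """
    genes: list[str] = []
    seen = set()
    for stage, de in stage_results.items():
        if de["gene_id"].duplicated().any():
            dup = de["gene_id"][de["gene_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate gene entry {dup!r} at stage {stage}")
        for g in de["gene_id"]:
            if g not in seen:
                genes.append(g)
                seen.add(g)
    codes = pd.DataFrame("absent", index=pd.Index(genes, name="gene"), columns=list(STAGES))
    for stage, de in stage_results.items():
        canon = STAGE_ALIASES.get(stage, stage)
        bias = de.set_index("gene_id")["bias"]
        for g in bias.index:
            code = bias[g]
            if presence is not None and canon in presence:
                if not presence[canon].get(g, False):
                    code = "absent"
            codes.loc[g, canon] = code if code in CODES else "absent"
    chrom = pd.Series({g: (chromosomes or {}).get(g, "") for g in genes})
    return BiasTable(codes, chrom)


def read_bias_table_tsv(path: str | Path) -> BiasTable:
    """Read a bias table with columns gene, ES, CP, 8.5, 9.5, 10.5, p1, Adult, Chr.

    Empty cells map to ``absent``; codes are strict (case-sensitive XX/XY/nb).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("gene", *_TSV_STAGE_COLUMNS, "Chr") if c not in df.columns]
    if missing:
        raise ValueError(f"bias table {path} missing columns {missing}")
    codes = {}
    for col, stage in zip(_TSV_STAGE_COLUMNS, STAGES):
        vals = df[col].replace("", "absent")
        bad = set(vals) - set(CODES)
        if bad:
            row = df.index[vals.isin(bad)][0]
            raise ValueError(f"unknown code {sorted(bad)[0]!r} in row {row + 2} of {path}")
        codes[stage] = vals
    table = pd.DataFrame(codes)
    table.index = pd.Index(df["gene"], name="gene")
    chrom = pd.Series(df["Chr"].to_numpy(), index=table.index)
    return BiasTable(table, chrom)


def write_bias_table_tsv(table: BiasTable, path: str | Path) -> None:
    out = table.codes.replace("absent", "").copy()
    out.columns = list(_TSV_STAGE_COLUMNS)
    out.insert(0, "gene", out.index)
    out["Chr"] = table.chromosomes.reindex(out.index).fillna("").to_numpy()
    out.to_csv(path, sep="\t", index=False)


@dataclass
class TrajectoryClass:
    group: str  # I, II, III, IV, V, lost, never_biased
    first_bias_stage: str | None
    transitions: list[tuple[tuple[str, str], str]]


def _transitions(row: Sequence[str]) -> list[tuple[tuple[str, str], str]]:
    """Transitions between consecutive stages where both codes are not absent."""
    out = []
    for i in range(len(STAGES) - 1):
        a, b = row[i], row[i + 1]
        if a == "absent" or b == "absent":
            continue
        if a in BIASED and b in BIASED:
            kind = "maintain" if a == b else "reverse"
        elif a in BIASED:
            kind = "lose"
        elif b in BIASED:
            kind = "acquire"
        else:
            continue
        out.append(((STAGES[i], STAGES[i + 1]), kind))
    return out


def classify(row: Sequence[str]) -> TrajectoryClass:
    """Classify one gene trajectory (codes ordered as STAGES)."""
    row = list(row)
    if len(row) != len(STAGES):
        raise ValueError(f"expected {len(STAGES)} codes, got {len(row)}")
    bad = set(row) - set(CODES)
    if bad:
        raise ValueError(f"unknown codes {sorted(bad)}")
    first_bias = next((STAGES[i] for i, c in enumerate(row) if c in BIASED), None)
    transitions = _transitions(row)
    es = row[0]
    later = row[1:]
    if es in BIASED:
        later_biased = [c for c in later if c in BIASED]
        if all(c == "absent" for c in later):
            group = "I"
        elif any(c != es for c in later_biased):
            group = "III"
        elif later_biased:
            group = "II"
        else:  # expressed later but never biased again
            group = "lost"
    elif first_bias is None:
        group = "never_biased"
    elif first_bias in PRE_GONADAL_STAGES:
        group = "IV"
    else:
        group = "V"
    return TrajectoryClass(group, first_bias, transitions)


def classify_table(table: BiasTable) -> pd.DataFrame:
    rows = []
    for g in table.genes:
        tc = classify(table.row(g))
        rows.append(
            {
                "gene": g,
                "group": tc.group,
                "first_bias_stage": tc.first_bias_stage or "",
                "transitions": ";".join(f"{a}>{b}:{k}" for (a, b), k in tc.transitions),
            }
        )
    return pd.DataFrame(rows)


def conserved_count(table: BiasTable, stage_a: str, stage_b: str, direction: str = "either") -> int:
    """Genes with the same XX/XY code at both stages (optionally one direction)."""
    a = STAGE_ALIASES.get(stage_a, stage_a)
    b = STAGE_ALIASES.get(stage_b, stage_b)
    for s in (a, b):
        if s not in table.codes.columns:
            raise ValueError(f"unknown stage {s!r}")
    ca, cb = table.codes[a], table.codes[b]
    same = (ca == cb) & ca.isin(BIASED)
    if direction in BIASED:
        same &= ca == direction
    elif direction != "either":
        raise ValueError("direction must be 'XX', 'XY', or 'either'")
    return int(same.sum())


def conserved_genes(table: BiasTable, stage_a: str, stage_b: str, direction: str = "either") -> list[str]:
    a = STAGE_ALIASES.get(stage_a, stage_a)
    b = STAGE_ALIASES.get(stage_b, stage_b)
    ca, cb = table.codes[a], table.codes[b]
    same = (ca == cb) & ca.isin(BIASED)
    if direction in BIASED:
        same &= ca == direction
    return list(table.codes.index[same])


def x_linked_count(subset: Iterable[str], annotation: Sequence[GeneAnnotation] | pd.Series) -> int:
    """How many genes of ``subset`` sit on the X chromosome."""
    if isinstance(annotation, pd.Series):
        chrom = annotation
    else:
        chrom = pd.Series({g.gene_id: g.chromosome for g in annotation})
    count = 0
    for g in subset:
        if g not in chrom.index:
            raise ValueError(f"gene {g!r} has no annotation")
        if chrom[g] == "X":
            count += 1
    return count


def transition_summary(table: BiasTable, stage_a: str, stage_b: str) -> dict[str, int]:
    """Counts of maintain / lose / acquire / reverse between two stages.

    Genes absent at either stage are excluded from every count.
    """
    a = STAGE_ALIASES.get(stage_a, stage_a)
    b = STAGE_ALIASES.get(stage_b, stage_b)
    for s in (a, b):
        if s not in table.codes.columns:
            raise ValueError(f"unknown stage {s!r}")
    out = {"maintain": 0, "lose": 0, "acquire": 0, "reverse": 0}
    for g in table.genes:
        ca, cb = table.codes.loc[g, a], table.codes.loc[g, b]
        if ca == "absent" or cb == "absent":
            continue
        if ca in BIASED and cb in BIASED:
            out["maintain" if ca == cb else "reverse"] += 1
        elif ca in BIASED:
            out["lose"] += 1
        elif cb in BIASED:
            out["acquire"] += 1
    return out


# ---------------------------------------------------------------------------
# Published stage-bias tables (transcribed fixture)

FIXTURE_NAME = "tables_2_3_transcription.tsv"


def published_tables_path() -> Path:
    """Path of the transcribed female/male stage-bias fixture shipped in-package."""
    return Path(importlib.resources.files("dimorph") / "data" / FIXTURE_NAME)


def load_published_tables(path: str | Path | None = None) -> tuple[BiasTable, BiasTable]:
    """Load the transcribed tables; returns (female_table, male_table)."""
    src = Path(path) if path is not None else published_tables_path()
    df = pd.read_csv(src, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for which in ("female", "male"):
        sub = df[df["table"] == which].drop(columns=["table"])
        # same cell semantics as read_bias_table_tsv, without a temp file
        codes = {}
        for col, stage in zip(_TSV_STAGE_COLUMNS, STAGES):
            codes[stage] = sub[col].replace("", "absent")
        table = pd.DataFrame(codes)
        table.index = pd.Index(sub["gene"], name="gene")
        out.append(BiasTable(table, pd.Series(sub["Chr"].to_numpy(), index=table.index)))
    return out[0], out[1]
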