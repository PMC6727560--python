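"""Single-cell sex assignment from the Xist/Eif2s3y expression ratio.

A cell is called female when the ratio is at least 1.5 and male when it is
below 1.  The interval [1, 1.5) is not covered by either published threshold
and is labeled ``ambiguous``; cells with both markers at zero have an
undefined ratio and are ``unassigned``.  Both categories are excluded from
downstream differential testing.  Ratios are computed on raw FPKM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .core import ExpressionMatrix

FEMALE_RATIO = 1.5
MALE_RATIO = 1.0

CALLS = ("female", "male", "ambiguous", "unassigned")


def sex_ratio(xist: float, eif2s3y: float) -> float | None:
    """Xist/Eif2s3y ratio; +inf when only Eif2s3y is zero, None when both are."""
    if xist < 0 or eif2s3y < 0:
        raise ValueError("marker FPKM must be nonnegative")
    if eif2s3y == 0:
        return None if xist == 0 else math.inf
    return xist / eif2s3y


def call_sex(ratio: float | None) -> str:
    """Map a ratio to female / male / ambiguous / unassigned."""
    if ratio is None:
        return "unassigned"
    if ratio >= FEMALE_RATIO:
        return "female"
    if ratio < MALE_RATIO:
        return "male"
    return "ambiguous"


@dataclass
class SexCallTable:
    """Per-cell marker values, ratio, and call."""

    table: pd.DataFrame  # columns: xist, eif2s3y, ratio, call; index cell_id

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]

    def cells_with_call(self, call: str) -> list[str]:
        return list(self.table.index[self.table["call"] == call])

    @property
    def assigned(self) -> pd.DataFrame:
        """Rows with a definite female/male call."""
        return self.table[self.table["call"].isin(["female", "male"])]

    def counts(self) -> dict[str, int]:
        base = {c: 0 for c in CALLS}
        base.update(self.table["call"].value_counts().to_dict())
        return base

    def write_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "cell_id", out.index)
        out.to_csv(path, sep="\t", index=False)


def sex_cells(m: ExpressionMatrix, xist_id: str = "Xist", eif2s3y_id: str = "Eif2s3y") -> SexCallTable:
    """Assign a sex call to every cell of ``m`` from the two marker rows."""
    for marker in (xist_id, eif2s3y_id):
        if marker not in m.values.index:
            raise ValueError(f"marker gene {marker!r} not present in matrix")
    xist = m.values.loc[xist_id]
    eif = m.values.loc[eif2s3y_id]
    rows = []
    for cell in m.sample_ids:
        r = sex_ratio(float(xist[cell]), float(eif[cell]))
        rows.append(
            {
                "xist": float(xist[cell]),
                "eif2s3y": float(eif[cell]),
                "ratio": (float("nan") if r is None else r),
                "call": call_sex(r),
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(m.sample_ids, name="cell_id"))
    return SexCallTable(table)
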