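"""Per-stage differential testing between sexes with FDR control.

Testing uses the unequal-variance (Welch) two-sample t statistic on
log2(FPKM + 1) values and Benjamini-Hochberg step-up adjustment.  A gene is
called XX-biased when q < alpha with a positive female-minus-male difference,
XY-biased when the difference is negative, and nb (not biased) otherwise.
Default alpha is 0.05 for single-cell stages and 0.01 for the cardiac
precursor bulk comparison.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, drop_zero_variance, filter_not_expressed, log_transform
from .sexing import SexCallTable

DEFAULT_ALPHA = 0.05
CARDIAC_PRECURSOR_ALPHA = 0.01


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch t statistic, Welch-Satterthwaite df, and two-sided p.

    Conventions for degenerate inputs: both groups zero-variance with equal
    means -> (0, n-2, 1); zero overall variance with unequal means ->
    (+/-inf, n-2, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0 and vb == 0:
        df = float(len(a) + len(b) - 2)
        if diff == 0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, diff), df, 0.0
    sa, sb = va / len(a), vb / len(b)
    t = diff / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, original order restored."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_bias(de: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Assign XX/XY/nb bias codes from q values and effect signs (strict q < alpha)."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    de = de.copy()
    sig = de["q"] < alpha
    de["bias"] = np.where(
        sig & (de["delta"] > 0), "XX", np.where(sig & (de["delta"] < 0), "XY", "nb")
    )
    return de


def stage_de(
    m: ExpressionMatrix,
    stage: str,
    sex_source: SexCallTable | None = None,
    alpha: float = DEFAULT_ALPHA,
    fpkm_threshold: float = 1.0,
) -> pd.DataFrame:
    """Female-vs-male testing for one stage.

    Sample sexes come from ``sex_source`` (single-cell calls; ambiguous and
    unassigned cells are excluded) or, when None, from the sample annotation.
    Genes expressed in neither sex at the stage are reported ``absent`` and
    not tested.  Returns a table with columns gene_id, mean_female,
    mean_male, delta, t_stat, df, p, q, bias.
    """
    stage_samples = m.samples_for(stage=stage)
    if not stage_samples:
        raise ValueError(f"no samples at stage {stage!r}")
    sub = m.subset_samples(stage_samples)

    if sex_source is not None:
        calls = sex_source.calls
        females = [s for s in sub.sample_ids if calls.get(s) == "female"]
        males = [s for s in sub.sample_ids if calls.get(s) == "male"]
    else:
        females = sub.samples_for(sex="female")
        males = sub.samples_for(sex="male")
    if len(females) < 2 or len(males) < 2:
        raise ValueError(
            f"stage {stage!r}: need >= 2 usable samples per sex "
            f"(got {len(females)} female, {len(males)} male)"
        )

    used = sub.subset_samples(females + males)
    _, flags = filter_not_expressed(used, threshold=fpkm_threshold)
    present = flags.stage_presence[used.samples[0].stage]
    testable = used.subset_genes(list(present.index[present]))
    testable = drop_zero_variance(testable)
    logm = log_transform(testable)

    fem_vals = logm.values[females].to_numpy()
    male_vals = logm.values[males].to_numpy()
    records = []
    for i, gid in enumerate(logm.gene_ids):
        t, df, p = welch_t(fem_vals[i], male_vals[i])
        records.append(
            {
                "gene_id": gid,
                "mean_female": fem_vals[i].mean(),
                "mean_male": male_vals[i].mean(),
                "delta": fem_vals[i].mean() - male_vals[i].mean(),
                "t_stat": t,
                "df": df,
                "p": p,
            }
        )
    de = pd.DataFrame(
        records,
        columns=["gene_id", "mean_female", "mean_male", "delta", "t_stat", "df", "p"],
    )
    de["q"] = bh_fdr(de["p"].to_numpy()) if len(de) else []
    de = call_bias(de, alpha=alpha)

    # genes failing presence in both sexes, or untestable (zero variance)
    tested = set(de["gene_id"])
    absent_rows = [
        {
            "gene_id": gid,
            "mean_female": np.nan,
            "mean_male": np.nan,
            "delta": np.nan,
            "t_stat": np.nan,
            "df": np.nan,
            "p": np.nan,
            "q": np.nan,
            "bias": "absent" if not present.get(gid, False) else "nb",
        }
        for gid in used.gene_ids
        if gid not in tested
    ]
    if absent_rows:
        de = pd.concat([de, pd.DataFrame(absent_rows)], ignore_index=True)
    de = de.set_index("gene_id").loc[used.gene_ids].reset_index()
    return de


def write_de_tsv(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index=False, float_format="%.6g")
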