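"""Weighted co-expression networks: similarity, soft threshold, topological
overlap, module detection, eigengenes, and module-trait correlation.

The network is unsigned: S_mn = |cor(m, n)|, a_mn = S_mn^beta with the
diagonal treated as zero for connectivity, and the standard unsigned
topological overlap

    T_mn = (sum_u a_mu a_un + a_mn) / (min(k_m, k_n) + 1 - a_mn).

Modules are branches of an average-linkage tree on 1 - T, obtained by a
static top-down cut at a quantile of the merge heights (a stand-in for the
full dynamic tree cut), with a minimum module size and iterative merging of
modules with highly correlated eigengenes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import ExpressionMatrix

#: WGCNA-like color palette used to label modules (largest first).
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
]

UNASSIGNED = "unassigned"
MAX_GS = 300.0


def similarity(m: ExpressionMatrix) -> pd.DataFrame:
    """Absolute Pearson correlation between genes (rows) of ``m``."""
    arr = m.values.to_numpy(dtype=float)
    if arr.shape[1] < 3:
        raise ValueError("similarity requires at least 3 samples")
    if (arr.std(axis=1) == 0).any():
        bad = m.values.index[np.flatnonzero(arr.std(axis=1) == 0)[0]]
        raise ValueError(f"zero-variance gene present: {bad!r}; remove before similarity")
    S = np.abs(np.corrcoef(arr))
    np.fill_diagonal(S, 1.0)
    S = np.clip(S, 0.0, 1.0)
    return pd.DataFrame(S, index=m.values.index, columns=m.values.index)


def adjacency(S: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Soft-thresholded adjacency S^beta (diagonal zeroed for connectivity)."""
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    A = S.to_numpy(dtype=float) ** beta
    np.fill_diagonal(A, 0.0)
    return pd.DataFrame(A, index=S.index, columns=S.columns)


def connectivity(A: pd.DataFrame) -> np.ndarray:
    return A.to_numpy().sum(axis=1)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 and slope of the log-log degree-distribution regression.

    Connectivities are binned into ``n_bins`` equal-occupancy bins; when there
    are at most ``n_bins`` distinct values the distinct values themselves act
    as bins.  The per-bin frequency is a density (count / bin width, or the
    raw count for atomic bins) and log10(density) is regressed on
    log10(mean k).  The returned R^2 carries the slope's sign flipped so that
    a negative slope (scale-free-like decay) yields a positive value.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.unique(k).size == 1:
        raise ValueError("degenerate connectivity distribution (all values identical)")
    uniq, counts = np.unique(k, return_counts=True)
    if uniq.size <= n_bins:
        xs = uniq
        dens = counts.astype(float)
    else:
        edges = np.unique(np.quantile(k, np.linspace(0, 1, n_bins + 1)))
        idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
        xs, dens = [], []
        for b in range(len(edges) - 1):
            mask = idx == b
            if not mask.any():
                continue
            width = edges[b + 1] - edges[b]
            if width <= 0:
                continue
            xs.append(k[mask].mean())
            dens.append(mask.sum() / width)
        xs = np.asarray(xs)
        dens = np.asarray(dens, dtype=float)
    if len(xs) < 3:
        raise ValueError("too few usable connectivity bins for a scale-free fit")
    lx, ly = np.log10(xs), np.log10(dens)
    slope, _, r, _, _ = stats.linregress(lx, ly)
    r2 = float(r**2)
    return (-np.sign(slope) * r2 if slope != 0 else 0.0), float(slope)


def pick_soft_threshold(
    S: pd.DataFrame,
    powers: tuple[int, ...] = tuple(range(1, 21)),
    r2_cut: float = 0.8,
) -> tuple[int, pd.DataFrame, bool]:
    """Lowest power whose signed scale-free R^2 reaches ``r2_cut``.

    Returns ``(beta, fit_table, reached)``.  When no power qualifies the
    power with the highest R^2 is returned and ``reached`` is False.
    """
    if len(powers) < 2:
        raise ValueError("need at least 2 candidate powers")
    rows = []
    for p in powers:
        A = adjacency(S, p)
        k = connectivity(A)
        r2, slope = scale_free_fit(k)
        rows.append({"power": p, "r2": r2, "slope": slope, "mean_k": float(k.mean())})
    fit = pd.DataFrame(rows)
    qualifying = fit[fit["r2"] >= r2_cut]
    if len(qualifying):
        return int(qualifying["power"].iloc[0]), fit, True
    best = int(fit.loc[fit["r2"].idxmax(), "power"])
    warnings.warn(
        f"no power reached scale-free R^2 {r2_cut}; using power {best} "
        f"(max R^2 {fit['r2'].max():.3f})",
        stacklevel=2,
    )
    return best, fit, False


def tom(A: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap of an adjacency matrix (diagonal = 1)."""
    a = A.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # sum_u a_mu a_un; diag(a)=0 so u=m,n contribute nothing
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(T, 1.0)
    T = np.clip(T, 0.0, 1.0)
    return pd.DataFrame(T, index=A.index, columns=A.columns)


def cluster_genes(T: pd.DataFrame) -> np.ndarray:
    """Average-linkage linkage matrix on dissimilarity 1 - T."""
    if len(T) < 2:
        raise ValueError("clustering requires at least 2 genes")
    d = 1.0 - T.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return hierarchy.linkage(squareform(d, checks=False), method="average")


@dataclass
class ModuleSet:
    """Module labels, dendrogram, eigengenes, and trait correlations."""

    labels: pd.Series  # gene_id -> module color or "unassigned"
    dendrogram: np.ndarray | None = None
    min_size: int = 50
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # sample x module
    trait_correlation: pd.DataFrame = field(default_factory=pd.DataFrame)  # module x (r, p)

    @property
    def module_names(self) -> list[str]:
        return [c for c in self.labels.unique() if c != UNASSIGNED]

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def cut_modules(
    dendrogram: np.ndarray,
    gene_ids: list[str],
    min_size: int = 50,
    cut_height_q: float = 0.99,
) -> ModuleSet:
    """Static cut at a merge-height quantile; small clusters are unassigned."""
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    heights = dendrogram[:, 2]
    cut = float(np.quantile(heights, cut_height_q))
    raw = hierarchy.fcluster(dendrogram, t=cut, criterion="distance")
    labels = pd.Series(UNASSIGNED, index=pd.Index(gene_ids, name="gene_id"), dtype=object)
    sizes = pd.Series(raw).value_counts()
    big = [c for c in sizes.index if sizes[c] >= min_size]
    big.sort(key=lambda c: (-sizes[c], c))
    if not big:
        warnings.warn("no cluster reached min_size; all genes unassigned", stacklevel=2)
    for color, c in zip(MODULE_COLORS, big):
        labels[np.asarray(raw) == c] = color
    return ModuleSet(labels=labels, dendrogram=dendrogram, min_size=min_size)


def module_eigengene(m: ExpressionMatrix, members: list[str]) -> np.ndarray:
    """First principal component across samples of the z-scored member rows.

    Unit norm; sign fixed so that the mean correlation with member profiles
    is nonnegative.
    """
    if len(members) < 2:
        raise ValueError("a module needs at least 2 member genes")
    missing = [g for g in members if g not in m.values.index]
    if missing:
        raise ValueError(f"member genes missing from matrix: {missing}")
    if m.shape[1] < 3:
        raise ValueError("eigengene requires at least 3 samples")
    sub = m.values.loc[members].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mu) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    eig = eig / np.linalg.norm(eig)
    cors = np.array([_safe_corr(eig, row) for row in z])
    if np.nanmean(cors) < 0:
        eig = -eig
    return eig


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def compute_eigengenes(m: ExpressionMatrix, modules: ModuleSet) -> pd.DataFrame:
    cols = {}
    for mod in modules.module_names:
        cols[mod] = module_eigengene(m, modules.members(mod))
    return pd.DataFrame(cols, index=m.values.columns)


def merge_close_modules(
    m: ExpressionMatrix, modules: ModuleSet, merge_cut: float = 0.25
) -> ModuleSet:
    """Iteratively merge the closest module pair with eigengene correlation
    above ``1 - merge_cut``, recomputing eigengenes after each merge."""
    if not 0 < merge_cut < 1:
        raise ValueError("merge_cut must be in (0, 1)")
    labels = modules.labels.copy()
    while True:
        names = [c for c in labels.unique() if c != UNASSIGNED]
        if len(names) < 2:
            break
        eigs = {mod: module_eigengene(m, list(labels.index[labels == mod])) for mod in names}
        best: tuple[float, str, str] | None = None
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                r = _safe_corr(eigs[names[i]], eigs[names[j]])
                if r > 1 - merge_cut and (best is None or r > best[0]):
                    best = (r, names[i], names[j])
        if best is None:
            break
        _, keep, drop = best
        if (labels == drop).sum() > (labels == keep).sum():
            keep, drop = drop, keep
        labels[labels == drop] = keep
    out = ModuleSet(labels=labels, dendrogram=modules.dendrogram, min_size=modules.min_size)
    out.eigengenes = compute_eigengenes(m, out)
    return out


def module_trait_correlation(
    eigengenes: pd.DataFrame, trait: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Pearson r and t-distribution p between each eigengene and a trait.

    For sex the convention is female=1, male=0, so positive r is
    female-associated.
    """
    t = np.asarray(trait, dtype=float)
    if len(t) != len(eigengenes.index):
        raise ValueError("trait length does not match sample count")
    if t.std() == 0:
        raise ValueError("trait is constant; correlation undefined")
    rows = []
    n = len(t)
    for mod in eigengenes.columns:
        e = eigengenes[mod].to_numpy()
        r = _safe_corr(e, t)
        if abs(r) >= 1.0:
            p = 0.0
        else:
            tval = r * np.sqrt((n - 2) / (1 - r**2))
            p = float(2 * stats.t.sf(abs(tval), n - 2))
        rows.append({"module": mod, "r": r, "p": p})
    return pd.DataFrame(rows).set_index("module")


def significance(de_p: pd.Series, modules: ModuleSet, max_gs: float = MAX_GS) -> pd.DataFrame:
    """Gene significance GS = -log10(p) and per-module mean (MS)."""
    p = de_p.astype(float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        gs = -np.log10(p)
    gs = gs.clip(upper=max_gs)
    rows = []
    for mod in modules.module_names:
        members = [g for g in modules.members(mod) if g in gs.index]
        ms = float(gs.loc[members].mean()) if members else np.nan
        rows.append({"module": mod, "ms": ms, "n_members": len(members)})
    table = pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame(columns=["ms", "n_members"])
    return pd.DataFrame({"gs": gs}), table


def run_wgcna(
    m: ExpressionMatrix,
    trait: np.ndarray | pd.Series | None = None,
    powers: tuple[int, ...] = tuple(range(1, 21)),
    r2_cut: float = 0.8,
    min_size: int = 50,
    cut_height_q: float = 0.99,
    merge_cut: float = 0.25,
) -> tuple[ModuleSet, pd.DataFrame, int]:
    """End-to-end module discovery; returns (modules, fit table, beta)."""
    S = similarity(m)
    beta, fit, _ = pick_soft_threshold(S, powers=powers, r2_cut=r2_cut)
    A = adjacency(S, beta)
    T = tom(A)
    Z = cluster_genes(T)
    modules = cut_modules(Z, list(m.values.index), min_size=min_size, cut_height_q=cut_height_q)
    if modules.module_names:
        modules = merge_close_modules(m, modules, merge_cut=merge_cut)
        if trait is not None:
            modules.trait_correlation = module_trait_correlation(modules.eigengenes, trait)
    return modules, fit, beta
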