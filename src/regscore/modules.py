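"""Weighted co-expression modules: soft threshold, TOM, eigengenes, hubs.

A deliberately compact variant of weighted correlation network analysis:
unsigned adjacency |cor|^beta with beta chosen by scale-free topology fit,
unsigned topological overlap similarity, average-linkage clustering with a
static tree cut, module eigengenes (first PC of each module's standardized
expression, sign-oriented to the module mean profile), iterative merging of
modules whose eigengenes correlate above a cutoff, and the usual gene
significance / module membership statistics for hub-gene extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .data_model import ExpressionMatrix

logger = logging.getLogger("regscore")

__all__ = ["ModuleResult", "pick_soft_threshold", "tom_similarity",
           "detect_modules", "module_trait", "hub_genes"]

GREY = "grey"


@dataclass
class ModuleResult:
    beta: int
    module_of: pd.Series                      # gene -> module label
    eigengenes: pd.DataFrame                  # modules x samples, unit variance
    expr: ExpressionMatrix = field(repr=False, default=None)
    module_trait_r: pd.DataFrame | None = None
    module_trait_p: pd.DataFrame | None = None
    gs: pd.DataFrame | None = None            # gene x trait |r|
    gs_p: pd.DataFrame | None = None
    mm: pd.DataFrame | None = None            # gene x module r with eigengene

    @property
    def modules(self) -> list[str]:
        return list(self.eigengenes.index)


def _adjacency(x: np.ndarray, power: float) -> np.ndarray:
    c = np.corrcoef(x)
    if not np.isfinite(c).all():
        raise ValueError("constant gene in expression; filter before module detection")
    a = np.abs(np.clip(c, -1.0, 1.0)) ** power
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit of a connectivity vector.

    Bins connectivities, regresses log10(frequency) on log10(mean k) and
    returns (signed R^2, slope); the sign convention makes a decreasing
    degree distribution (negative slope) score positively.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        freq = mask.mean()
        if mean_k > 0 and freq > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(freq))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r * r), float(slope)


def pick_soft_threshold(expr: ExpressionMatrix,
                        powers: list[int] | None = None,
                        r2_target: float = 0.85) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by scale-free topology fit.

    Returns the smallest power whose signed R^2 reaches *r2_target*, else
    the argmax of the fit; the full fit table (power, signed R^2, slope,
    mean/median connectivity) accompanies the choice so a user can force a
    different power.
    """
    if powers is None:
        powers = list(range(1, 13)) + [14, 16, 18, 20]
    powers = list(powers)
    if expr.shape[0] < 30:
        logger.warning("pick_soft_threshold: fewer than 30 genes; fit unstable")
    x = expr.values
    rows = []
    for p in powers:
        a = _adjacency(x, p)
        k = a.sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append({"power": p, "sft_r2": r2, "slope": slope,
                     "mean_k": float(k.mean()), "median_k": float(np.median(k))})
    table = pd.DataFrame(rows)
    ok = table[table["sft_r2"] >= r2_target]
    beta = int(ok["power"].iloc[0]) if len(ok) else int(
        table.loc[table["sft_r2"].idxmax(), "power"])
    return beta, table


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap from an adjacency with zero diagonal.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_u a_iu a_uj; diagonal set to 1.
    """
    a = adjacency
    k = a.sum(axis=1)
    L = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def _eigengene(z: np.ndarray, sample_ids: list[str]) -> np.ndarray:
    """First PC of a standardized genes x samples block, unit variance,
    sign-oriented to correlate positively with the mean profile."""
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(e, mean_profile - mean_profile.mean()) < 0:
        e = -e
    sd = e.std(ddof=1)
    return e / sd if sd > 0 else e


def detect_modules(expr: ExpressionMatrix, beta: int,
                   min_module_size: int = 30,
                   merge_cut: float = 0.75,
                   cut_height: float = 0.99) -> ModuleResult:
    """Cluster genes into co-expression modules on TOM dissimilarity.

    Average-linkage tree on 1 - TOM, static cut at *cut_height*; clusters
    below *min_module_size* go grey. Module pairs whose eigengenes correlate
    above *merge_cut* (default 0.75) are merged iteratively, most-correlated
    pair first. Labels M1, M2, ... are assigned by decreasing module size.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    x = expr.values
    genes = expr.gene_ids
    a = _adjacency(x, beta)
    tom = tom_similarity(a)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    link = average(squareform(np.maximum(diss, 0.0), checks=False))
    raw = fcluster(link, t=cut_height, criterion="distance")

    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    z = (x - mu) / sd

    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(raw):
        clusters.setdefault(int(c), []).append(i)
    modules = {c: idx for c, idx in clusters.items() if len(idx) >= min_module_size}
    grey = [i for c, idx in clusters.items() if c not in modules for i in idx]
    if not modules:
        logger.warning("detect_modules: no cluster reaches min_module_size=%d; "
                       "all genes grey", min_module_size)

    member: dict[int, list[int]] = {i: idx for i, idx in enumerate(modules.values())}
    eigs = {c: _eigengene(z[idx], expr.sample_ids) for c, idx in member.items()}

    # iterative merge of the most-correlated eigengene pair above merge_cut
    while len(member) > 1:
        keys = sorted(member)
        best, best_r = None, merge_cut
        for i_pos, ci in enumerate(keys):
            for cj in keys[i_pos + 1:]:
                r = float(np.corrcoef(eigs[ci], eigs[cj])[0, 1])
                if r > best_r:
                    best, best_r = (ci, cj), r
        if best is None:
            break
        ci, cj = best
        member[ci] = member[ci] + member.pop(cj)
        eigs.pop(cj)
        eigs[ci] = _eigengene(z[member[ci]], expr.sample_ids)

    ordered = sorted(member, key=lambda c: (-len(member[c]), min(member[c])))
    labels = pd.Series(GREY, index=genes, name="module")
    eig_rows = {}
    for rank, c in enumerate(ordered, start=1):
        name = f"M{rank}"
        labels.iloc[member[c]] = name
        eig_rows[name] = eigs[c]
    eigengenes = pd.DataFrame(eig_rows, index=expr.sample_ids).T if eig_rows \
        else pd.DataFrame(columns=expr.sample_ids)
    return ModuleResult(beta=beta, module_of=labels, eigengenes=eigengenes,
                        expr=expr)


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def module_trait(mr: ModuleResult, traits: pd.DataFrame) -> ModuleResult:
    """Fill eigengene-trait correlations, gene significance and membership.

    traits: samples x numeric traits, aligned (or alignable) to the
    expression samples. Constant traits are flagged with NaN columns, not
    errors. GS is the absolute per-gene Pearson correlation with each
    trait; MM the signed per-gene correlation with each module eigengene.
    """
    if mr.expr is None:
        raise ValueError("ModuleResult lacks its expression matrix")
    samples = mr.expr.sample_ids
    t = traits.reindex(samples)
    if t.isna().any().any():
        raise ValueError("traits missing for some samples")
    x = mr.expr.values

    r_tab = pd.DataFrame(index=mr.modules, columns=t.columns, dtype=float)
    p_tab = r_tab.copy()
    for m in mr.modules:
        e = mr.eigengenes.loc[m].to_numpy()
        for trait in t.columns:
            tv = t[trait].to_numpy(dtype=float)
            if np.std(tv) == 0:
                logger.warning("module_trait: trait %r constant; flagged NaN", trait)
                r_tab.loc[m, trait] = np.nan
                p_tab.loc[m, trait] = np.nan
            else:
                r, p = _pearson_with_p(e, tv)
                r_tab.loc[m, trait] = r
                p_tab.loc[m, trait] = p

    genes = mr.expr.gene_ids
    gs = pd.DataFrame(index=genes, columns=t.columns, dtype=float)
    gs_p = gs.copy()
    for trait in t.columns:
        tv = t[trait].to_numpy(dtype=float)
        if np.std(tv) == 0:
            continue
        for i, g in enumerate(genes):
            r, p = _pearson_with_p(x[i], tv)
            gs.loc[g, trait] = abs(r)
            gs_p.loc[g, trait] = p

    mm = pd.DataFrame(index=genes, columns=mr.modules, dtype=float)
    for m in mr.modules:
        e = mr.eigengenes.loc[m].to_numpy()
        for i, g in enumerate(genes):
            r, _ = _pearson_with_p(x[i], e)
            mm.loc[g, m] = r

    mr.module_trait_r, mr.module_trait_p = r_tab, p_tab
    mr.gs, mr.gs_p, mr.mm = gs, gs_p, mm
    return mr


def hub_genes(mr: ModuleResult, module: str, trait: str,
              gs_min: float = 0.2, mm_min: float = 0.8) -> list[str]:
    """Genes of *module* with GS >= gs_min for *trait* and MM >= mm_min."""
    if module not in mr.modules:
        raise KeyError(f"no module {module!r}")
    if mr.gs is None or mr.mm is None:
        raise ValueError("run module_trait first")
    in_mod = mr.module_of[mr.module_of == module].index
    keep = [g for g in in_mod
            if mr.gs.loc[g, trait] >= gs_min and mr.mm.loc[g, module] >= mm_min]
    return keep
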