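"""Resampling-based consensus clustering with CDF/delta-area model selection.

Samples are repeatedly subsampled (together with an optional gene
subsample), clustered with an inner algorithm, and the fraction of times two
samples land in the same cluster among the resamples where both were drawn
forms the consensus matrix. The empirical CDF of consensus values and the
relative change of its area under the curve across k guide the choice of the
number of clusters, after which the consensus matrix itself is clustered
hierarchically for the final assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .data_model import ExpressionMatrix, GroupAssignment

logger = logging.getLogger("regscore")

__all__ = ["ConsensusResult", "consensus_run", "cdf_and_delta", "select_k"]

CDF_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class ConsensusResult:
    k: int
    consensus: pd.DataFrame                  # samples x samples in [0, 1]
    assignment: GroupAssignment
    cdf: np.ndarray                          # empirical CDF on CDF_GRID
    auc: float
    delta_area: float | None = None          # filled by cdf_and_delta
    never_cosampled: int = 0
    resample_assignments: list | None = field(default=None, repr=False)


def _corr_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between columns (samples) of x."""
    c = np.corrcoef(x, rowvar=False)
    c = np.clip(c, -1.0, 1.0)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    # guard tiny negative values from float error before squareform
    return np.maximum(d, 0.0)


def _cluster_once(x: np.ndarray, k: int, inner: str, rng: np.random.Generator) -> np.ndarray:
    """Cluster columns of the genes x samples block into k groups."""
    if inner == "hierarchical":
        d = _corr_distance(x)
        z = average(squareform(d, checks=False))
        return fcluster(z, t=k, criterion="maxclust")
    if inner == "kmeans":
        km = KMeans(n_clusters=k, n_init=10,
                    random_state=int(rng.integers(0, 2**31 - 1)))
        return km.fit_predict(x.T) + 1
    raise ValueError(f"unknown inner clusterer {inner!r}")


def consensus_run(
    expr: ExpressionMatrix,
    genes: list[str],
    k: int,
    n_resamples: int = 1000,
    sample_frac: float = 0.8,
    gene_frac: float = 1.0,
    inner: str = "hierarchical",
    seed: int = 0,
    keep_resamples: bool = False,
) -> ConsensusResult:
    """One consensus-clustering run at a fixed k.

    Per resample, ceil(sample_frac * n) samples and ceil(gene_frac * m) genes
    are drawn without replacement, the subsample is clustered into k groups,
    and co-cluster / co-sample counts are accumulated. Per-resample RNG
    substreams are derived from (seed, k, resample index), so results do not
    depend on execution order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not (0 < sample_frac <= 1) or not (0 < gene_frac <= 1):
        raise ValueError("sample_frac and gene_frac must lie in (0, 1]")
    if n_resamples < 10:
        raise ValueError("need n_resamples >= 10")

    sub = expr.subset_genes(genes)
    x_full = sub.values
    n = x_full.shape[1]
    m = x_full.shape[0]
    n_sub = int(np.ceil(sample_frac * n))
    m_sub = int(np.ceil(gene_frac * m))

    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    stored = [] if keep_resamples else None

    attempts = 0
    b = 0
    while b < n_resamples:
        attempts += 1
        if attempts > 10 * n_resamples:
            raise RuntimeError("too many resamples with fewer samples than k")
        rng = np.random.default_rng([seed, k, attempts])
        s_idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        g_idx = np.sort(rng.choice(m, size=m_sub, replace=False))
        if n_sub < k:
            continue
        labels = _cluster_once(x_full[np.ix_(g_idx, s_idx)], k, inner, rng)
        if stored is not None:
            stored.append((s_idx.copy(), labels.copy()))
        same = labels[:, None] == labels[None, :]
        co_sample[np.ix_(s_idx, s_idx)] += 1.0
        co_cluster[np.ix_(s_idx, s_idx)] += same
        b += 1

    off_diag_zero = (co_sample == 0) & ~np.eye(n, dtype=bool)
    never = int(off_diag_zero.sum() // 2)  # off-diagonal pairs
    if never:
        logger.warning("consensus_run: %d sample pairs never co-sampled; "
                       "consensus set to 0 for those pairs", never)
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    # final assignment: average-linkage clustering of 1 - consensus
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    z = average(squareform(np.maximum(d, 0.0), checks=False))
    raw = fcluster(z, t=k, criterion="maxclust")
    labels = _relabel_by_size(raw)
    assignment = GroupAssignment(
        pd.Series([f"CL{c}" for c in labels], index=sub.sample_ids)
    )

    upper = consensus[np.triu_indices(n, k=1)]
    cdf = np.array([np.mean(upper <= t) for t in CDF_GRID])
    auc = float(np.trapezoid(cdf, CDF_GRID))

    cons_df = pd.DataFrame(consensus, index=sub.sample_ids, columns=sub.sample_ids)
    return ConsensusResult(k=k, consensus=cons_df, assignment=assignment,
                           cdf=cdf, auc=auc, never_cosampled=never,
                           resample_assignments=stored)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Deterministic labels: 1 = largest cluster, ties by first occurrence."""
    uniq, counts = np.unique(labels, return_counts=True)
    first = {u: int(np.argmax(labels == u)) for u in uniq}
    order = sorted(uniq, key=lambda u: (-counts[list(uniq).index(u)], first[u]))
    mapping = {u: i + 1 for i, u in enumerate(order)}
    return np.array([mapping[u] for u in labels])


def cdf_and_delta(results: list[ConsensusResult]) -> pd.DataFrame:
    """AUC of the consensus CDF per k and its relative change vs k-1.

    The AUC is a trapezoid-rule integral on the fixed 101-point grid; the
    delta area at the smallest k (k=2) is defined as the AUC itself.
    """
    ks = [r.k for r in results]
    if ks != list(range(2, 2 + len(ks))):
        raise ValueError(f"ks must be consecutive starting at 2, got {ks}")
    rows = []
    prev_auc = None
    for r in results:
        auc = float(np.trapezoid(r.cdf, CDF_GRID))
        if prev_auc is None:
            delta = auc
        else:
            delta = (auc - prev_auc) / prev_auc
        r.auc = auc
        r.delta_area = delta
        rows.append({"k": r.k, "auc": auc, "delta_area": delta})
        prev_auc = auc
    return pd.DataFrame(rows)


def select_k(table: pd.DataFrame, k_max: int, threshold: float = 0.1) -> int:
    """Smallest k whose next delta-area falls below *threshold* (default 0.1).

    If no k qualifies the cap k_max is returned with a warning; the full
    table remains available for manual override.
    """
    tab = table.set_index("k")["delta_area"]
    for k in range(2, k_max):
        if k + 1 in tab.index and tab.loc[k + 1] < threshold:
            return k
    logger.warning("select_k: all delta areas >= %g; returning k_max=%d",
                   threshold, k_max)
    return k_max
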