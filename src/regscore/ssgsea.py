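"""Single-sample gene-set enrichment (ssGSEA) and score-group comparisons.

The enrichment statistic is the integrated running-sum form: per sample,
genes are ranked by expression, and the score of a set is the accumulated
gap between the weighted in-set cumulative distribution (weights
``rank^alpha``) and the uniform out-of-set cumulative distribution, summed
over all gene positions rather than taking the maximum deviation. A 0-floor
min-max normalization per signature row brings every score to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionMatrix, GroupAssignment, SignatureSet
from .utils import bh_adjust, stars

logger = logging.getLogger("regscore")

__all__ = ["ScoreMatrix", "ssgsea_score", "floor_normalize", "group_score_test"]


@dataclass
class ScoreMatrix:
    """Signatures x samples enrichment scores."""

    scores: pd.DataFrame
    normalized: bool = False

    @property
    def signature_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="signature",
                           float_format="%.10g")


def _sample_es(order: np.ndarray, ranks: np.ndarray, in_set: np.ndarray,
               alpha: float) -> float:
    """Integrated running-sum enrichment for one sample.

    order: gene indices from highest to lowest expression; ranks: within-
    sample ranks (highest expression = largest rank, average ties); in_set:
    boolean per gene.
    """
    ind = in_set[order]
    w = np.where(ind, np.abs(ranks[order]) ** alpha, 0.0)
    denom_hit = w.sum()
    n_miss = int((~ind).sum())
    p_hit = np.cumsum(w) / denom_hit
    p_miss = np.cumsum(~ind) / n_miss
    return float(np.sum(p_hit - p_miss))


def ssgsea_score(expr: ExpressionMatrix, sigs: SignatureSet,
                 alpha: float = 0.25) -> ScoreMatrix:
    """ssGSEA enrichment scores for every signature in every sample.

    Ranks are computed within each sample over the full gene universe of the
    matrix (average ranks for ties); ``alpha`` (default 0.25) exponentiates
    the rank weights, alpha=0 giving uniform in-set weights. Signatures that
    lose all genes to restriction, or that cover the whole universe (no
    out-of-set genes), are dropped with a warning.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    restricted, dropped = sigs.restrict(expr)
    if dropped:
        logger.info("ssgsea_score: %d signatures lost genes on restriction",
                    len(dropped))

    x = expr.values
    n_genes, n_samples = x.shape
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}

    # per-sample ranks (ascending: largest expression -> rank n_genes)
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    # deterministic walk order: descending rank, gene index breaks ties
    order = np.lexsort((np.arange(n_genes)[:, None].repeat(n_samples, 1), -ranks),
                       axis=0)

    rows = {}
    for sig, genes in restricted.sets.items():
        in_set = np.zeros(n_genes, dtype=bool)
        in_set[[gene_index[g] for g in genes]] = True
        if in_set.all():
            logger.warning("ssgsea_score: signature %r covers all genes; dropped", sig)
            continue
        es = np.empty(n_samples)
        for s in range(n_samples):
            es[s] = _sample_es(order[:, s], ranks[:, s], in_set, alpha)
        rows[sig] = es
    if not rows:
        raise ValueError("no scorable signatures (all empty or universe-wide)")
    scores = pd.DataFrame(rows, index=expr.sample_ids).T
    return ScoreMatrix(scores=scores, normalized=False)


def floor_normalize(sm: ScoreMatrix) -> ScoreMatrix:
    """Min-max normalize each signature row so its minimum is exactly 0.

    Constant rows map to all-zero with a warning.
    """
    x = sm.scores.to_numpy(dtype=float)
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    const = (span == 0).ravel()
    if const.any():
        logger.warning("floor_normalize: %d constant signature rows set to 0",
                       int(const.sum()))
    out = np.where(span > 0, (x - lo) / np.where(span > 0, span, 1.0), 0.0)
    return ScoreMatrix(
        scores=pd.DataFrame(out, index=sm.scores.index, columns=sm.scores.columns),
        normalized=True,
    )


def group_score_test(sm: ScoreMatrix, groups: GroupAssignment) -> pd.DataFrame:
    """Per-signature nonparametric comparison of scores between groups.

    Two groups: two-sided Wilcoxon rank-sum (exact for small tie-free
    samples); three or more: Kruskal-Wallis. P-values are BH-adjusted across
    signatures and annotated with the usual significance stars.
    """
    common = [s for s in sm.sample_ids if s in set(groups.sample_ids)]
    labels = groups.labels.loc[common]
    group_names = sorted(labels.unique())
    if len(group_names) < 2:
        raise ValueError("need >= 2 groups")
    members = {g: labels.index[labels == g] for g in group_names}
    for g, idx in members.items():
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    rows = []
    for sig in sm.signature_ids:
        vals = {g: sm.scores.loc[sig, idx].to_numpy() for g, idx in members.items()}
        if len(group_names) == 2:
            a, b = (vals[g] for g in group_names)
            method = "exact" if (len(a) + len(b) <= 25
                                 and len(np.unique(np.concatenate([a, b])))
                                 == len(a) + len(b)) else "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            stat, p = float(res.statistic), float(res.pvalue)
            test = "wilcoxon"
        else:
            res = stats.kruskal(*[vals[g] for g in group_names])
            stat, p = float(res.statistic), float(res.pvalue)
            test = "kruskal"
        row = {"signature": sig, "statistic": stat, "p": p, "test": test}
        for g in group_names:
            row[f"mean_{g}"] = float(np.mean(vals[g]))
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["stars"] = out["p"].map(stars)
    return out


def category_mean_scores(sm: ScoreMatrix, sigs: SignatureSet) -> pd.DataFrame:
    """Per-sample mean score of each signature category (e.g. pro/anti-tumor)."""
    cats: dict[str, list[str]] = {}
    for sig in sm.signature_ids:
        cat = sigs.category.get(sig)
        if cat is not None:
            cats.setdefault(cat, []).append(sig)
    if not cats:
        raise ValueError("no categorized signatures")
    return pd.DataFrame(
        {cat: sm.scores.loc[members].mean(axis=0) for cat, members in cats.items()}
    ).T
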