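"""Dual-method differential expression and cross-cohort signature overlap.

Mirrors a two-caller design: method A is a moderated two-sample t-test
whose per-gene pooled variance is shrunk toward the grand median variance,
method B a Wilcoxon rank-sum test, and a gene is called differential only
when both methods agree (each passing its own BH-adjusted threshold) and
the log-fold-change clears the cutoff. The procedural core — intersecting
two independent callers, then intersecting the resulting gene lists across
cohorts — is preserved exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionMatrix, GroupAssignment
from .utils import bh_adjust

__all__ = ["de_test", "call_degs", "cross_cohort_signature"]

#: prior weight scale for variance moderation toward the grand median
_SHRINK_PRIOR = 50.0


def de_test(expr: ExpressionMatrix, groups: GroupAssignment) -> pd.DataFrame:
    """Per-gene two-group differential test with two independent methods.

    Groups are taken in sorted label order (g1, g2); ``log_fc`` is
    mean(g2) - mean(g1) on the (log-scale) expression values. Method A:
    moderated t with pooled variance shrunk toward the grand median with
    weight w = n_genes / (n_genes + 50) on the median (heavier moderation
    for larger panels), df = n1 + n2 - 2. Method B: two-sided Wilcoxon
    rank-sum (exact for small tie-free samples, normal approximation with
    tie correction otherwise). BH adjustment within each method.
    """
    common = [s for s in expr.sample_ids if s in set(groups.sample_ids)]
    labels = groups.labels.loc[common]
    names = sorted(labels.unique())
    if len(names) != 2:
        raise ValueError(f"de_test needs exactly 2 groups, got {len(names)}")
    idx1 = [s for s in common if labels[s] == names[0]]
    idx2 = [s for s in common if labels[s] == names[1]]
    if len(idx1) < 3 or len(idx2) < 3:
        raise ValueError("each group needs >= 3 samples")

    x1 = expr.data[idx1].to_numpy()
    x2 = expr.data[idx2].to_numpy()
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    log_fc = m2 - m1

    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    n_genes = len(pooled)
    w = n_genes / (n_genes + _SHRINK_PRIOR)
    moderated = (1.0 - w) * pooled + w * float(np.median(pooled))
    se = np.sqrt(moderated * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log_fc / se, 0.0)
    df = n1 + n2 - 2
    p_a = 2.0 * stats.t.sf(np.abs(t), df)

    exact_ok = (n1 + n2) <= 12
    p_b = np.empty(n_genes)
    for i in range(n_genes):
        a, b = x1[i], x2[i]
        ties = len(np.unique(np.concatenate([a, b]))) < n1 + n2
        method = "exact" if (exact_ok and not ties) else "asymptotic"
        p_b[i] = stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue

    out = pd.DataFrame({
        "gene": expr.gene_ids,
        "log_fc": log_fc,
        "t": t,
        "p_a": p_a,
        "p_b": p_b,
        "q_a": bh_adjust(p_a),
        "q_b": bh_adjust(p_b),
    })
    out["direction"] = np.where(out["log_fc"] >= 0, "up", "down")
    out.attrs["group1"], out.attrs["group2"] = names[0], names[1]
    return out


def call_degs(de: pd.DataFrame, alpha: float = 0.05, lfc: float = 1.0,
              use_adjusted: bool = True) -> list[str]:
    """Genes both methods call significant with |log_fc| above the cutoff.

    Significance uses BH-adjusted q-values by default; ``use_adjusted=False``
    switches to raw p-values for both methods.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if lfc < 0:
        raise ValueError("lfc must be >= 0")
    pa = de["q_a"] if use_adjusted else de["p_a"]
    pb = de["q_b"] if use_adjusted else de["p_b"]
    keep = (pa < alpha) & (pb < alpha) & (de["log_fc"].abs() > lfc)
    return de.loc[keep, "gene"].tolist()


def cross_cohort_signature(list_1: list[str], list_2: list[str]) -> list[str]:
    """Set intersection of two gene lists, in the order of the first."""
    second = set(list_2)
    seen = set()
    out = []
    for g in list_1:
        if g in second and g not in seen:
            out.append(g)
            seen.add(g)
    return out
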