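"""Per-sample modification-pattern score from a prognostic gene signature.

The score is built in four steps: (1) filter a candidate gene signature by
univariate Cox significance; (2) standardize each retained gene across the
training cohort and take the first two principal components; (3) score each
sample as its projection on PC1 plus its projection on PC2, then
standardize by the training-cohort mean X and standard deviation SD,

    score_s = [sum_g (PC1_g + PC2_g) x_gs  -  X] / SD;

(4) orient the sign so that a higher score means higher hazard, and split
the scored cohort at its median into high/low groups (ties go to "low").

The module exposes both the individual operations and a statsmodels-style
``M6AScoreModel`` whose :meth:`~M6AScoreModel.fit` returns an
:class:`M6AScoreResults` carrying the scores, the Cox fit of the score, the
Kaplan-Meier split and a ``summary()`` table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix, GroupAssignment, SurvivalTable, align
from .survival import CoxFit, KMCurve, cox_fit, km_fit, logrank

logger = logging.getLogger("regscore")

__all__ = ["ScoreModel", "ScoreVector", "prognostic_filter", "fit_score_model",
           "apply_score", "sign_orient", "M6AScoreModel", "M6AScoreResults"]


@dataclass
class ScoreModel:
    """Frozen transform from expression to the standardized pattern score."""

    genes: list[str]
    centering: np.ndarray        # per-gene training means
    scaling: np.ndarray          # per-gene training standard deviations
    loadings_pc1: np.ndarray     # unit-norm gene loadings
    loadings_pc2: np.ndarray | None
    X: float                     # training mean of raw PC1+PC2 sums
    SD: float                    # training SD (ddof=1) of raw sums
    training_scores: pd.Series = field(default=None, repr=False)
    oriented: bool = False

    def raw_scores(self, expr: ExpressionMatrix) -> pd.Series:
        """Unstandardized per-sample PC1+PC2 projection sums."""
        missing = [g for g in self.genes if g not in set(expr.gene_ids)]
        if missing:
            raise KeyError(f"model genes missing from matrix: {missing[:10]}")
        x = expr.data.loc[self.genes].to_numpy()
        z = (x - self.centering[:, None]) / self.scaling[:, None]
        r = self.loadings_pc1 @ z
        if self.loadings_pc2 is not None:
            r = r + self.loadings_pc2 @ z
        return pd.Series(r, index=expr.sample_ids, name="raw_score")

    def to_json(self, path) -> None:
        obj = {
            "genes": self.genes,
            "centering": self.centering.tolist(),
            "scaling": self.scaling.tolist(),
            "loadings_pc1": self.loadings_pc1.tolist(),
            "loadings_pc2": (None if self.loadings_pc2 is None
                             else self.loadings_pc2.tolist()),
            "X": self.X, "SD": self.SD, "oriented": self.oriented,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScoreModel":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls(
            genes=obj["genes"],
            centering=np.asarray(obj["centering"]),
            scaling=np.asarray(obj["scaling"]),
            loadings_pc1=np.asarray(obj["loadings_pc1"]),
            loadings_pc2=(None if obj["loadings_pc2"] is None
                          else np.asarray(obj["loadings_pc2"])),
            X=obj["X"], SD=obj["SD"], oriented=obj.get("oriented", False),
        )


@dataclass
class ScoreVector:
    """Standardized scores with the high/low median split."""

    scores: pd.Series
    groups: GroupAssignment
    cutoff: float

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"score": self.scores,
                             "group": self.groups.labels})


def prognostic_filter(genes: list[str], expr: ExpressionMatrix,
                      surv: SurvivalTable, alpha: float = 0.05,
                      use_adjusted: bool = False) -> tuple[list[str], pd.DataFrame]:
    """Keep genes whose univariate Cox Wald p-value is below *alpha*.

    Raw p-values by default (``use_adjusted=True`` switches to BH-adjusted).
    Returns the surviving genes plus a per-gene report of HR and p.
    """
    expr_a, surv_a = align(expr, surv)
    rows = []
    for g in genes:
        st = surv_a.with_covariate("__gene__", expr_a.data.loc[g])
        fit = cox_fit(st, ["__gene__"])
        rows.append({"gene": g, "HR": float(fit.hr[0]), "beta": float(fit.beta[0]),
                     "p": float(fit.p[0])})
    report = pd.DataFrame(rows)
    if use_adjusted:
        from .utils import bh_adjust
        report["q"] = bh_adjust(report["p"].to_numpy())
        keep = report["q"] < alpha
    else:
        keep = report["p"] < alpha
    kept = report.loc[keep, "gene"].tolist()
    if not kept:
        raise ValueError(
            f"no gene passes the prognostic filter at alpha={alpha}; "
            "increase alpha")
    return kept, report


def fit_score_model(expr: ExpressionMatrix, genes: list[str]) -> ScoreModel:
    """Correlation-PCA score model on the signature submatrix.

    Each gene is centered and scaled to unit variance across the training
    samples; the SVD of the standardized genes x samples matrix provides the
    first two principal directions. Loadings carry a deterministic sign
    (largest-|loading| entry positive). Rank-1 matrices fall back to PC1
    only with a warning.
    """
    if len(genes) < 2:
        raise ValueError("need >= 2 signature genes")
    sub = expr.subset_genes(genes)
    if sub.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    x = sub.values
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = [g for g, s in zip(genes, sd) if s == 0]
        raise ValueError(f"constant signature genes: {bad[:5]}")
    z = (x - mu[:, None]) / sd[:, None]

    u, s, _ = np.linalg.svd(z, full_matrices=False)
    pc1 = u[:, 0]
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    pc2 = None
    if len(s) > 1 and s[1] > 1e-12 * s[0]:
        pc2 = u[:, 1]
        if pc2[np.argmax(np.abs(pc2))] < 0:
            pc2 = -pc2
    else:
        logger.warning("fit_score_model: rank-1 signature matrix; PC1 only")

    r = pc1 @ z
    if pc2 is not None:
        r = r + pc2 @ z
    X = float(np.mean(r))
    SD = float(np.std(r, ddof=1))
    if SD == 0:
        raise ValueError("degenerate signature: raw scores are constant")
    model = ScoreModel(genes=list(genes), centering=mu, scaling=sd,
                       loadings_pc1=pc1, loadings_pc2=pc2, X=X, SD=SD)
    model.training_scores = pd.Series((r - X) / SD, index=sub.sample_ids,
                                      name="score")
    return model


def apply_score(model: ScoreModel, expr: ExpressionMatrix,
                cutoff: float | None = None) -> ScoreVector:
    """Score a cohort with a fitted model and split at the median.

    New samples are centered/scaled with the training parameters and
    standardized by the training X and SD; the high/low split uses the
    scored cohort's own median unless a fixed *cutoff* is supplied. Samples
    at or below the cutoff go to "low".
    """
    raw = model.raw_scores(expr)
    score = (raw - model.X) / model.SD
    cut = float(np.median(score)) if cutoff is None else float(cutoff)
    labels = pd.Series(np.where(score > cut, "high", "low"),
                       index=score.index)
    return ScoreVector(scores=score.rename("score"),
                       groups=GroupAssignment(labels), cutoff=cut)


def sign_orient(model: ScoreModel, surv: SurvivalTable) -> ScoreModel:
    """Flip the score sign so a higher score carries higher hazard.

    Fits a univariate Cox model of the training-cohort scores against the
    supplied survival table; a negative coefficient flips the joint sign of
    both principal-component loadings (and of X), leaving SD unchanged.
    Deterministic and idempotent.
    """
    if model.training_scores is None:
        raise ValueError("sign_orient needs a model with stored training scores")
    common = [s for s in model.training_scores.index if s in set(surv.sample_ids)]
    if not common:
        raise ValueError("no samples shared between model and survival table")
    st = surv.subset(common).with_covariate("__score__",
                                            model.training_scores.loc[common])
    fit = cox_fit(st, ["__score__"])
    if fit.beta[0] >= 0:
        out = ScoreModel(**{**model.__dict__})
        out.oriented = True
        return out
    flipped = ScoreModel(
        genes=model.genes, centering=model.centering, scaling=model.scaling,
        loadings_pc1=-model.loadings_pc1,
        loadings_pc2=None if model.loadings_pc2 is None else -model.loadings_pc2,
        X=-model.X, SD=model.SD,
        training_scores=-model.training_scores, oriented=True,
    )
    return flipped


class M6AScoreModel:
    """Statsmodels-style front end for building the pattern score.

    Parameters
    ----------
    expr : ExpressionMatrix
        Training-cohort expression (log scale, genes x samples).
    signature : list of str
        Candidate signature genes (e.g. the cross-cohort DEG overlap).
    surv : SurvivalTable
        Survival outcomes used for the prognostic filter and orientation.
    """

    def __init__(self, expr: ExpressionMatrix, signature: list[str],
                 surv: SurvivalTable):
        self.expr, self.surv = align(expr, surv)
        missing = [g for g in signature if g not in set(expr.gene_ids)]
        if missing:
            raise KeyError(f"signature genes missing: {missing[:10]}")
        self.signature = list(signature)

    @classmethod
    def from_dataframe(cls, expr_df: pd.DataFrame, signature: list[str],
                       clinical: pd.DataFrame) -> "M6AScoreModel":
        return cls(ExpressionMatrix(expr_df), signature, SurvivalTable(clinical))

    def fit(self, alpha: float = 0.05, use_adjusted: bool = False) -> "M6AScoreResults":
        kept, report = prognostic_filter(self.signature, self.expr, self.surv,
                                         alpha=alpha, use_adjusted=use_adjusted)
        model = fit_score_model(self.expr, kept)
        model = sign_orient(model, self.surv)
        sv = apply_score(model, self.expr)
        score_cox = cox_fit(
            self.surv.with_covariate("score", sv.scores), ["score"])
        chi2, df, p = logrank(self.surv, sv.groups)
        curves = km_fit(self.surv, sv.groups)
        return M6AScoreResults(model=model, scores=sv, filter_report=report,
                               score_cox=score_cox,
                               logrank_=(chi2, df, p), km_curves=curves)


@dataclass
class M6AScoreResults:
    """Fitted score model, per-sample scores and survival diagnostics."""

    model: ScoreModel
    scores: ScoreVector
    filter_report: pd.DataFrame
    score_cox: CoxFit
    logrank_: tuple[float, int, float]
    km_curves: dict[str, KMCurve]

    def summary(self) -> pd.DataFrame:
        chi2, df, p = self.logrank_
        lo, hi = self.score_cox.ci95
        rows = [
            ("signature genes (candidates)", len(self.filter_report)),
            ("signature genes (prognostic)", len(self.model.genes)),
            ("samples scored", len(self.scores.scores)),
            ("score HR per unit", float(self.score_cox.hr[0])),
            ("score HR 95% CI low", float(lo[0])),
            ("score HR 95% CI high", float(hi[0])),
            ("score Cox p", float(self.score_cox.p[0])),
            ("log-rank chi2 (high vs low)", chi2),
            ("log-rank p (high vs low)", p),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])
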