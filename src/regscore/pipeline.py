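"""End-to-end orchestration plus correlation/association utilities.

``run_pipeline`` drives the full analysis from a single config: consensus
clustering of each cohort on the regulator panel, dual-method differential
expression between the two clusters, cross-cohort signature overlap,
univariate-Cox prognostic filtering on the training cohort, the PCA score
model with sign orientation, scoring and median stratification of every
cohort, survival comparisons of the score groups, and signature-score group
tests — writing each intermediate table and a JSON manifest.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .consensus import cdf_and_delta, consensus_run, select_k
from .data_model import align, read_clinical, read_expression, read_gmt
from .diffexpr import call_degs, cross_cohort_signature, de_test
from .score import (ScoreVector, apply_score, fit_score_model,
                    prognostic_filter, sign_orient)
from .ssgsea import floor_normalize, group_score_test, ssgsea_score
from .survival import cox_fit, forest_table, logrank
from .utils import bh_adjust

logger = logging.getLogger("regscore")

__all__ = ["PipelineConfig", "run_pipeline", "correlate",
           "score_association_panel", "response_group_test"]


# ---------------------------------------------------------------------------
# correlation / association utilities

def correlate(x, y, method: str = "spearman") -> tuple[float, float]:
    """Correlation coefficient with a two-sided p-value.

    Pearson or Spearman; the p-value uses the t approximation except for
    n <= 9, where the exact permutation distribution of the coefficient is
    enumerated. Constant inputs yield (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("correlate: constant vector; coefficient undefined")
        return float("nan"), float("nan")

    if method == "pearson":
        r = float(stats.pearsonr(x, y)[0])
        xe, ye = x, y
    elif method == "spearman":
        r = float(stats.spearmanr(x, y)[0])
        xe, ye = stats.rankdata(x), stats.rankdata(y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")

    if n <= 9:
        # exact permutation null: correlation under every relabeling of y
        xs = (xe - xe.mean()) / (xe.std() * math.sqrt(n))
        ys = (ye - ye.mean()) / (ye.std() * math.sqrt(n))
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        r_perm = ys[perms] @ xs
        p = float(np.mean(np.abs(r_perm) >= abs(r) - 1e-12))
    else:
        if method == "pearson":
            p = float(stats.pearsonr(x, y)[1])
        else:
            p = float(stats.spearmanr(x, y)[1])
    return r, float(p)


def score_association_panel(scores: ScoreVector, covariates: pd.DataFrame,
                            method: str = "spearman") -> pd.DataFrame:
    """Correlation of the score with each numeric covariate, BH across panel."""
    common = [s for s in scores.sample_ids if s in covariates.index]
    sc = scores.scores.loc[common].to_numpy()
    rows = []
    for name in covariates.columns:
        v = covariates.loc[common, name].to_numpy(dtype=float)
        r, p = correlate(sc, v, method=method)
        rows.append({"covariate": name, "r": r, "p": p})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    q = np.full(len(out), np.nan)
    if valid.any():
        q[valid.to_numpy()] = bh_adjust(out.loc[valid, "p"].to_numpy())
    out["q"] = q
    return out


def response_group_test(scores: ScoreVector, response: pd.Series):
    """Score-by-response comparison plus a score-group contingency test.

    Returns a dict with the per-response-group score medians, the
    Wilcoxon (2 groups) or Kruskal-Wallis (>=3) statistic and p-value, the
    high/low x response contingency table, and its chi-square p-value.
    Empty response categories are dropped with a warning.
    """
    common = [s for s in scores.sample_ids if s in response.index
              and pd.notna(response.loc[s])]
    resp = response.loc[common].astype(str)
    sc = scores.scores.loc[common]
    counts = resp.value_counts()
    cats = sorted(counts[counts > 0].index)
    if len(cats) < 2:
        raise ValueError("need >= 2 non-empty response categories")
    vals = [sc[resp == c].to_numpy() for c in cats]
    if len(cats) == 2:
        a, b = vals
        method = "exact" if (len(a) + len(b) <= 25
                             and len(np.unique(np.concatenate(vals)))
                             == len(a) + len(b)) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test = "wilcoxon"
    else:
        res = stats.kruskal(*vals)
        test = "kruskal"
    medians = {c: float(np.median(v)) for c, v in zip(cats, vals)}

    table = pd.crosstab(scores.groups.labels.loc[common], resp)
    if table.shape[0] > 1 and table.shape[1] > 1:
        chi2, chi2_p, _, _ = stats.chi2_contingency(table, correction=False)
    else:
        chi2, chi2_p = float("nan"), float("nan")
    return {"medians": medians, "test": test,
            "statistic": float(res.statistic), "p": float(res.pvalue),
            "contingency": table, "chi2": float(chi2), "chi2_p": float(chi2_p)}


# ---------------------------------------------------------------------------
# pipeline configuration and runner

@dataclass
class CohortSpec:
    name: str
    expression: str
    clinical: str


@dataclass
class PipelineConfig:
    cohorts: list[CohortSpec]
    regulators_gmt: str
    out_dir: str
    training_cohort: str | None = None
    signatures_gmt: str | None = None
    k_max: int = 5
    n_resamples: int = 200
    sample_frac: float = 0.8
    gene_frac: float = 1.0
    inner: str = "hierarchical"
    de_alpha: float = 0.05
    de_lfc: float = 1.0
    de_use_adjusted: bool = True
    score_alpha: float = 0.05
    refit_per_cohort: bool = False
    min_variance: float = 0.0
    ssgsea_alpha: float = 0.25
    run_modules: bool = False
    merge_cut: float = 0.75
    min_module_size: int = 30
    seed: int = 0

    def __post_init__(self):
        if not self.cohorts:
            raise ValueError("config needs >= 1 cohort")
        if self.training_cohort is None:
            self.training_cohort = self.cohorts[0].name
        names = [c.name for c in self.cohorts]
        if self.training_cohort not in names:
            raise ValueError(f"training cohort {self.training_cohort!r} unknown")
        for c in self.cohorts:
            for path in (c.expression, c.clinical):
                if not os.path.exists(path):
                    raise FileNotFoundError(f"cohort {c.name}: missing file {path}")
        for path in filter(None, (self.regulators_gmt, self.signatures_gmt)):
            if not os.path.exists(path):
                raise FileNotFoundError(f"missing gene-set file {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        cohorts = [CohortSpec(**c) for c in raw.pop("cohorts")]
        return cls(cohorts=cohorts, **raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Every intermediate table is written under ``cfg.out_dir``; a stage
    failure aborts with the stage name while earlier outputs remain on disk.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict = {
        "tool": "regscore", "version": __version__, "seed": cfg.seed,
        "parameters": {k: v for k, v in cfg.__dict__.items() if k != "cohorts"},
        "cohorts": {c.name: {"expression": c.expression, "clinical": c.clinical,
                             "expression_sha256": _sha256(c.expression),
                             "clinical_sha256": _sha256(c.clinical)}
                    for c in cfg.cohorts},
        "stages": {},
    }
    stage = "load"
    try:
        regulators_set = read_gmt(cfg.regulators_gmt)
        regulators = sorted({g for genes in regulators_set.sets.values()
                             for g in genes})
        cohorts = {}
        for c in cfg.cohorts:
            expr = read_expression(c.expression, min_variance=cfg.min_variance)
            surv = read_clinical(c.clinical)
            expr, surv = align(expr, surv)
            cohorts[c.name] = {"expr": expr, "surv": surv}

        stage = "consensus_cluster"
        deg_lists = {}
        for name, co in cohorts.items():
            expr = co["expr"]
            present = [g for g in regulators if g in set(expr.gene_ids)]
            if len(present) < 2:
                raise ValueError(f"cohort {name}: <2 regulators in matrix")
            results = []
            for k in range(2, cfg.k_max + 1):
                results.append(consensus_run(
                    expr, present, k, n_resamples=cfg.n_resamples,
                    sample_frac=cfg.sample_frac, gene_frac=cfg.gene_frac,
                    inner=cfg.inner, seed=cfg.seed))
            table = cdf_and_delta(results)
            k_sel = select_k(table, cfg.k_max)
            res2 = results[k_sel - 2]
            co["clusters"] = res2.assignment
            co["k_selected"] = k_sel
            _write(table, os.path.join(cfg.out_dir, f"{name}_cdf_delta.tsv"),
                   index=False)
            _write(res2.consensus,
                   os.path.join(cfg.out_dir, f"{name}_consensus_k{k_sel}.tsv"))
            res2.assignment.to_tsv(os.path.join(cfg.out_dir, f"{name}_clusters.tsv"))
            manifest["stages"].setdefault("consensus", {})[name] = {
                "k_selected": int(k_sel),
                "delta_area": table.set_index("k")["delta_area"].to_dict()}

            stage = "differential_expression"
            # DE always between the top-2 consensus clusters
            two = res2.assignment if res2.assignment.n_groups() == 2 else \
                consensus_run(expr, present, 2, n_resamples=cfg.n_resamples,
                              sample_frac=cfg.sample_frac, gene_frac=cfg.gene_frac,
                              inner=cfg.inner, seed=cfg.seed).assignment
            de = de_test(expr, two)
            degs = call_degs(de, alpha=cfg.de_alpha, lfc=cfg.de_lfc,
                             use_adjusted=cfg.de_use_adjusted)
            deg_lists[name] = degs
            co["de_groups"] = two
            _write(de, os.path.join(cfg.out_dir, f"{name}_de.tsv"), index=False)
            with open(os.path.join(cfg.out_dir, f"{name}_degs.txt"), "w") as fh:
                fh.write("\n".join(degs) + ("\n" if degs else ""))
            manifest["stages"].setdefault("de", {})[name] = {"n_degs": len(degs)}
            stage = "consensus_cluster"

        stage = "cross_cohort_signature"
        names = [c.name for c in cfg.cohorts]
        signature = deg_lists[names[0]]
        for nm in names[1:]:
            signature = cross_cohort_signature(signature, deg_lists[nm])
        with open(os.path.join(cfg.out_dir, "signature_genes.txt"), "w") as fh:
            fh.write("\n".join(signature) + ("\n" if signature else ""))
        manifest["stages"]["signature"] = {"n_genes": len(signature)}
        if not signature:
            raise ValueError("empty cross-cohort signature; relax DE thresholds")

        stage = "score_model"
        train = cohorts[cfg.training_cohort]
        sig_in_train = [g for g in signature
                        if g in set(train["expr"].gene_ids)]
        kept, report = prognostic_filter(sig_in_train, train["expr"],
                                         train["surv"], alpha=cfg.score_alpha)
        _write(report, os.path.join(cfg.out_dir, "prognostic_filter.tsv"),
               index=False)
        model = fit_score_model(train["expr"], kept)
        model = sign_orient(model, train["surv"])
        model.to_json(os.path.join(cfg.out_dir, "score_model.json"))
        manifest["stages"]["score_model"] = {"n_prognostic_genes": len(kept)}

        stage = "score_and_survival"
        for name, co in cohorts.items():
            expr, surv = co["expr"], co["surv"]
            if cfg.refit_per_cohort and name != cfg.training_cohort:
                present = [g for g in kept if g in set(expr.gene_ids)]
                m = sign_orient(fit_score_model(expr, present), surv)
            else:
                m = model
            sv = apply_score(m, expr)
            co["score"] = sv
            _write(sv.to_frame(), os.path.join(cfg.out_dir, f"{name}_scores.tsv"),
                   index_label="sample_id")
            chi2, dfree, p = logrank(surv, sv.groups)
            uni = cox_fit(surv.with_covariate("score", sv.scores), ["score"])
            extra = [cname for cname in surv.covariates.columns
                     if surv.covariates[cname].nunique() > 1]
            multi = cox_fit(surv.with_covariate("score", sv.scores),
                            ["score"] + extra) if extra else uni
            _write(forest_table([uni, multi]),
                   os.path.join(cfg.out_dir, f"{name}_cox.tsv"), index=False)
            manifest["stages"].setdefault("survival", {})[name] = {
                "logrank_chi2": chi2, "logrank_p": p,
                "score_hr": float(uni.hr[0]), "score_p": float(uni.p[0])}

        stage = "ssgsea"
        if cfg.signatures_gmt:
            sigs = read_gmt(cfg.signatures_gmt)
            for name, co in cohorts.items():
                sm = floor_normalize(
                    ssgsea_score(co["expr"], sigs, alpha=cfg.ssgsea_alpha))
                sm.to_tsv(os.path.join(cfg.out_dir, f"{name}_ssgsea.tsv"))
                by_cluster = group_score_test(sm, co["de_groups"])
                by_score = group_score_test(sm, co["score"].groups)
                _write(by_cluster, os.path.join(
                    cfg.out_dir, f"{name}_ssgsea_by_cluster.tsv"), index=False)
                _write(by_score, os.path.join(
                    cfg.out_dir, f"{name}_ssgsea_by_score.tsv"), index=False)
                manifest["stages"].setdefault("ssgsea", {})[name] = {
                    "n_signatures": len(sm.signature_ids)}

        stage = "modules"
        if cfg.run_modules:
            from .modules import detect_modules, module_trait, pick_soft_threshold
            train = cohorts[cfg.training_cohort]
            sig_expr = train["expr"].subset_genes(
                [g for g in signature if g in set(train["expr"].gene_ids)])
            beta, fit_tab = pick_soft_threshold(sig_expr)
            mr = detect_modules(sig_expr, beta, min_module_size=cfg.min_module_size,
                                merge_cut=cfg.merge_cut)
            traits = pd.DataFrame(
                {"score": train["score"].scores.loc[sig_expr.sample_ids]})
            mr = module_trait(mr, traits)
            _write(fit_tab, os.path.join(cfg.out_dir, "sft_fit.tsv"), index=False)
            mr.module_of.to_csv(os.path.join(cfg.out_dir, "modules.tsv"),
                                sep="\t", index_label="gene")
            _write(mr.eigengenes, os.path.join(cfg.out_dir, "eigengenes.tsv"))
            manifest["stages"]["modules"] = {
                "beta": int(beta),
                "n_modules": len(mr.modules)}
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    import datetime
    manifest["timestamp"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
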