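"""Kaplan-Meier estimation, log-rank tests and Cox proportional-hazards fits.

The Cox partial likelihood is maximized by Newton-Raphson with either the
Efron (default) or Breslow tie correction; both are implemented under one
API so that results on tie-free data agree to numerical precision. The KM
estimator carries Greenwood variances, and the log-rank statistic is the
standard observed-minus-expected chi-square with g-1 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GroupAssignment, SurvivalTable

logger = logging.getLogger("regscore")

__all__ = ["KMCurve", "CoxFit", "km_fit", "logrank", "cox_fit", "forest_table"]

_BETA_CAP = 15.0


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) immediately after each event time
    at_risk: np.ndarray
    n_events: np.ndarray
    variance: np.ndarray       # Greenwood variance of S(t)
    median_survival: float | None
    n: int
    label: str = ""

    def ci95(self) -> tuple[np.ndarray, np.ndarray]:
        """Plain (linear-scale) Greenwood 95% confidence band, clipped to [0, 1]."""
        half = 1.959963984540054 * np.sqrt(self.variance)
        return (np.clip(self.survival - half, 0.0, 1.0),
                np.clip(self.survival + half, 0.0, 1.0))


@dataclass
class CoxFit:
    """Maximum partial-likelihood Cox fit with Wald inference."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    ties_method: str
    n: int
    n_events: int
    converged: bool = True
    capped: bool = False
    covariance: np.ndarray = field(default=None, repr=False)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def wald_z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.wald_z))

    @property
    def ci95(self) -> tuple[np.ndarray, np.ndarray]:
        half = 1.959963984540054 * self.se
        return np.exp(self.beta - half), np.exp(self.beta + half)

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci95
        return pd.DataFrame({
            "term": self.terms, "beta": self.beta, "HR": self.hr,
            "se": self.se, "z": self.wald_z, "p": self.p,
            "ci95_low": lo, "ci95_high": hi,
        })


def _km_single(time: np.ndarray, event: np.ndarray, label: str = "") -> KMCurve:
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    n = len(time)
    ev_times = np.unique(time[event == 1])
    surv, var_terms, at_risk, n_ev = [], [], [], []
    s = 1.0
    gw = 0.0
    for t in ev_times:
        n_i = int(np.sum(time >= t))
        d_i = int(np.sum((time == t) & (event == 1)))
        s *= 1.0 - d_i / n_i
        if n_i > d_i:
            gw += d_i / (n_i * (n_i - d_i))
            var = s * s * gw
        else:
            var = 0.0  # S hits 0; Greenwood sum diverges, variance degenerate
        surv.append(s)
        var_terms.append(var)
        at_risk.append(n_i)
        n_ev.append(d_i)
    surv = np.asarray(surv)
    median = None
    below = np.nonzero(surv <= 0.5)[0]
    if below.size:
        median = float(ev_times[below[0]])
    if len(ev_times) == 0:
        logger.warning("km_fit: group %r has no events; S(t) = 1 everywhere", label)
    return KMCurve(times=ev_times, survival=surv,
                   at_risk=np.asarray(at_risk, dtype=int),
                   n_events=np.asarray(n_ev, dtype=int),
                   variance=np.asarray(var_terms),
                   median_survival=median, n=n, label=label)


def km_fit(surv: SurvivalTable, groups: GroupAssignment | None = None):
    """Kaplan-Meier curve(s); one per group when an assignment is given."""
    if groups is None:
        return _km_single(surv.time.to_numpy(), surv.event.to_numpy())
    out = {}
    for g, members in sorted(groups.groups().items()):
        sub = surv.subset([s for s in surv.sample_ids if s in set(members)])
        out[g] = _km_single(sub.time.to_numpy(), sub.event.to_numpy(), label=g)
    return out


def logrank(surv: SurvivalTable, groups: GroupAssignment) -> tuple[float, int, float]:
    """Multi-group log-rank test: (chi-square, df, p)."""
    labels = groups.labels.loc[surv.sample_ids]
    names = sorted(labels.unique())
    g = len(names)
    if g < 2:
        raise ValueError("log-rank needs >= 2 groups")
    time = surv.time.to_numpy()
    event = surv.event.to_numpy()
    if event.sum() == 0:
        raise ValueError("log-rank needs >= 1 event")
    member = np.array([names.index(labels[s]) for s in surv.sample_ids])

    ev_times = np.unique(time[event == 1])
    O = np.zeros(g)
    E = np.zeros(g)
    V = np.zeros((g, g))
    for t in ev_times:
        at = time >= t
        n_t = int(at.sum())
        d_t = int(((time == t) & (event == 1)).sum())
        n_g = np.array([int((at & (member == j)).sum()) for j in range(g)])
        d_g = np.array([int(((time == t) & (event == 1) & (member == j)).sum())
                        for j in range(g)])
        O += d_g
        E += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            c = d_t * (n_t - d_t) / (n_t - 1)
            V += c * (np.diag(frac) - np.outer(frac, frac))
    d = (O - E)[:-1]
    Vr = V[:-1, :-1]
    chi2 = float(d @ np.linalg.pinv(Vr) @ d) if d.size else 0.0
    df = g - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def _design_matrix(surv: SurvivalTable, covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    cov = surv.covariates
    for name in covariates:
        if name not in cov.columns:
            raise KeyError(f"covariate {name!r} not in survival table")
        col = cov[name]
        if pd.api.types.is_numeric_dtype(col):
            arr = col.to_numpy(dtype=float)
            if np.ptp(arr) == 0:
                raise ValueError(f"covariate {name!r} is constant")
            cols.append(arr)
            names.append(name)
        else:
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                raise ValueError(f"covariate {name!r} is constant")
            for lev in levels[1:]:  # reference = first sorted level
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{name}[{lev}]")
    return np.column_stack(cols), names


def _partial_loglik(beta, time, event, X, ties):
    """Log partial likelihood, score vector and information matrix.

    Subjects are sorted by descending time so each tie block's risk-set sums
    S0, S1, S2 are cumulative sums up to the block end; the Efron inner loop
    over deaths within a block is broadcast over its tie fractions.
    """
    n, p = X.shape
    order = np.argsort(-time, kind="stable")
    t_s = time[order]
    e_s = event[order].astype(bool)
    Xs = X[order]
    eta = Xs @ beta
    theta = np.exp(eta)
    thX = theta[:, None] * Xs
    c0 = np.cumsum(theta)
    c1 = np.cumsum(thX, axis=0)
    c2 = np.cumsum(thX[:, :, None] * Xs[:, None, :], axis=0)

    ends = np.flatnonzero(np.r_[np.diff(t_s) != 0, True])
    starts = np.r_[0, ends[:-1] + 1]
    # deaths per tie block
    cum_e = np.r_[0, np.cumsum(e_s)]
    d_g = cum_e[ends + 1] - cum_e[starts]
    has_d = d_g > 0

    ll = float(eta[e_s].sum())
    U = Xs[e_s].sum(axis=0)
    info = np.zeros((p, p))

    # blocks handled as Breslow (no tie correction needed when d == 1)
    simple = has_d & ((d_g == 1) | (ties == "breslow"))
    if simple.any():
        b_idx = ends[simple]
        d = d_g[simple].astype(float)
        S0 = c0[b_idx]
        r = c1[b_idx] / S0[:, None]                      # (G, p)
        ll -= float(np.sum(d * np.log(S0)))
        U -= d @ r
        info += np.einsum("g,gjk->jk", d, c2[b_idx] / S0[:, None, None])
        info -= np.einsum("g,gj,gk->jk", d, r, r)

    # efron blocks with genuine ties
    for a, b, d in zip(starts[~simple & has_d], ends[~simple & has_d],
                       d_g[~simple & has_d]):
        d = int(d)
        d_mask = e_s[a:b + 1]
        S0, S1, S2 = c0[b], c1[b], c2[b]
        xd = Xs[a:b + 1][d_mask]
        th_d = theta[a:b + 1][d_mask]
        s0d = th_d.sum()
        s1d = thX[a:b + 1][d_mask].sum(axis=0)
        s2d = np.einsum("i,ij,ik->jk", th_d, xd, xd)
        f = np.arange(d) / d
        den = S0 - f * s0d                       # (d,)
        z1 = S1[None, :] - f[:, None] * s1d      # (d, p)
        zd = z1 / den[:, None]
        ll -= float(np.log(den).sum())
        U -= zd.sum(axis=0)
        info += ((S2[None] - f[:, None, None] * s2d)
                 / den[:, None, None]).sum(axis=0)
        info -= np.einsum("lj,lk->jk", zd, zd)
    return ll, U, info


def cox_fit(surv: SurvivalTable, covariates: list[str],
            ties: str = "efron") -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson.

    Convergence when the largest score component drops below 1e-8, up to 50
    iterations with step-halving; monotone-likelihood separation (any
    |beta| > 15) is capped with a warning rather than diverging.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    X, names = _design_matrix(surv, covariates)
    time = surv.time.to_numpy()
    event = surv.event.to_numpy()
    n, p = X.shape
    if event.sum() == 0:
        raise ValueError("Cox fit needs >= 1 event")
    # center covariates for numerical stability; beta is unaffected
    center = X.mean(axis=0)
    Xc = X - center

    beta = np.zeros(p)
    ll0, _, _ = _partial_loglik(beta, time, event, Xc, ties)
    ll = ll0
    converged = False
    capped = False
    for _ in range(50):
        ll, U, info = _partial_loglik(beta, time, event, Xc, ties)
        if np.max(np.abs(U)) < 1e-8:
            converged = True
            break
        try:
            step = np.linalg.solve(info, U)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, U, rcond=None)[0]
        # step-halving on genuine likelihood decrease (float-noise tolerant)
        tol = 1e-12 * (1.0 + abs(ll))
        new_beta = beta + step
        new_ll, _, _ = _partial_loglik(new_beta, time, event, Xc, ties)
        halvings = 0
        while new_ll < ll - tol and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, _, _ = _partial_loglik(new_beta, time, event, Xc, ties)
            halvings += 1
        beta = new_beta
        if np.any(np.abs(beta) > _BETA_CAP):
            logger.warning("cox_fit: |beta| > %g suggests monotone-likelihood "
                           "separation; estimate capped", _BETA_CAP)
            beta = np.clip(beta, -_BETA_CAP, _BETA_CAP)
            capped = True
            ll, U, info = _partial_loglik(beta, time, event, Xc, ties)
            break
    else:
        ll, U, info = _partial_loglik(beta, time, event, Xc, ties)
    if not converged and not capped:
        logger.warning("cox_fit: Newton-Raphson did not reach |score| < 1e-8")

    cov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return CoxFit(terms=names, beta=beta, se=se, loglik=float(ll),
                  loglik_null=float(ll0), ties_method=ties, n=n,
                  n_events=int(event.sum()), converged=converged or capped,
                  capped=capped, covariance=cov)


def forest_table(fits: list[CoxFit]) -> pd.DataFrame:
    """Tidy (term, HR, CI, p) table across fits, input order preserved."""
    rows = []
    for fit in fits:
        lo, hi = fit.ci95
        for i, term in enumerate(fit.terms):
            rows.append({"term": term, "HR": fit.hr[i],
                         "ci95_low": lo[i], "ci95_high": hi[i],
                         "p": fit.p[i], "n": fit.n, "ties": fit.ties_method})
    cols = ["term", "HR", "ci95_low", "ci95_high", "p", "n", "ties"]
    return pd.DataFrame(rows, columns=cols)
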