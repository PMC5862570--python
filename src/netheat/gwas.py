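"""Per-SNP association by cumulative-logit (proportional-odds) regression.

The genotype y in {0,1,2} is modelled as an ordinal outcome of the binary
phenotype x:

    P(y = 0 | x) = Q1 = sigmoid(alpha1 + beta*x)
    P(y <= 1 | x) = Q2 = sigmoid(alpha2 + beta*x)
    p1 = Q1,  p2 = Q2 - Q1,  p3 = 1 - Q2

with alpha1 < alpha2 and a single shared slope beta (log cumulative odds of a
lower genotype category for cases relative to controls).  The association test
is a Wald test of H0: beta = 0.

Because x is binary the likelihood depends on the data only through the 2x3
table of genotype counts per phenotype group, so each marker is fitted by a
three-parameter Newton-Raphson on that table regardless of cohort size.  A
conventional binary-logistic mode (phenotype regressed on allele dosage) is
available for comparison via ``run_gwas(..., model="binlogit")``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .containers import MISSING, GenotypeMatrix

MAX_ITER = 50
GRAD_TOL = 1e-8
# widely used genome-wide significance level, exposed as a constant
GENOME_WIDE_ALPHA = 5e-8


@dataclass
class CumulativeLogitFit:
    alpha1: float
    alpha2: float          # +inf when only two genotype categories are observed
    beta: float
    se_beta: float
    loglik: float
    converged: bool
    n_iter: int
    n_used: int


@dataclass
class AssocResult:
    snp_id: str
    beta: float
    se_beta: float
    z: float
    p: float
    n_used: int
    status: str = "ok"


def cumlogit_probs(
    alpha1: float, alpha2: float, beta: float, x: float
) -> tuple[float, float, float]:
    """Category probabilities (p1, p2, p3) at covariate value x.

    p3 is computed as the complement 1 - Q2 so the three probabilities sum to
    one exactly.
    """
    if not alpha1 < alpha2:
        raise ValueError("intercepts must satisfy alpha1 < alpha2")
    q1 = expit(alpha1 + beta * x)
    q2 = expit(alpha2 + beta * x)
    return float(q1), float(q2 - q1), float(1.0 - q2)


def _table_from_vectors(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """2x3 count table n[x, y] over complete cases."""
    ok = (y != MISSING)
    y, x = y[ok], x[ok]
    table = np.zeros((2, 3), dtype=np.int64)
    for xi in (0, 1):
        for yi in (0, 1, 2):
            table[xi, yi] = int(((x == xi) & (y == yi)).sum())
    return table


def _loglik_3cat(theta: np.ndarray, table: np.ndarray) -> float:
    a1, a2, b = theta
    ll = 0.0
    for xi in (0, 1):
        q1 = expit(a1 + b * xi)
        q2 = expit(a2 + b * xi)
        probs = (q1, q2 - q1, 1.0 - q2)
        for yi, p in enumerate(probs):
            n = table[xi, yi]
            if n:
                if p <= 0.0:
                    return -np.inf
                ll += n * np.log(p)
    return ll


def _grad_hess_3cat(theta: np.ndarray, table: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient and Hessian of the 2x3 cumulative-logit log-likelihood."""
    a1, a2, b = theta
    grad = np.zeros(3)
    hess = np.zeros((3, 3))
    for xi in (0, 1):
        n0, n1, n2 = table[xi]
        q1 = expit(a1 + b * xi)
        q2 = expit(a2 + b * xi)
        d1 = q1 * (1 - q1)              # dQ1/deta1
        d2 = q2 * (1 - q2)
        dd1 = d1 * (1 - 2 * q1)         # d2Q1/deta1^2
        dd2 = d2 * (1 - 2 * q2)
        p2 = q2 - q1
        p3 = 1.0 - q2
        # first derivatives wrt the two linear predictors
        g1 = d1 * (n0 / q1 - n1 / p2)
        g2 = d2 * (n1 / p2 - n2 / p3)
        # second derivatives
        h11 = dd1 * (n0 / q1 - n1 / p2) + d1 * d1 * (-n0 / q1**2 - n1 / p2**2)
        h22 = dd2 * (n1 / p2 - n2 / p3) + d2 * d2 * (-n1 / p2**2 - n2 / p3**2)
        h12 = d1 * d2 * n1 / p2**2
        j1 = np.array([1.0, 0.0, float(xi)])
        j2 = np.array([0.0, 1.0, float(xi)])
        grad += g1 * j1 + g2 * j2
        hess += (
            h11 * np.outer(j1, j1)
            + h22 * np.outer(j2, j2)
            + h12 * (np.outer(j1, j2) + np.outer(j2, j1))
        )
    return grad, hess


def _newton_3cat(table: np.ndarray) -> CumulativeLogitFit:
    n_used = int(table.sum())
    # moment initialisation from pooled margins, clipped away from 0/1
    tot = table.sum(axis=0).astype(float)
    c1 = np.clip(tot[0] / n_used, 0.02, 0.98)
    c2 = np.clip((tot[0] + tot[1]) / n_used, c1 + 0.01, 0.99)
    theta = np.array([np.log(c1 / (1 - c1)), np.log(c2 / (1 - c2)), 0.0])
    ll = _loglik_3cat(theta, table)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        grad, hess = _grad_hess_3cat(theta, table)
        if np.max(np.abs(grad)) < GRAD_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # Newton step with halving on overshoot or infeasibility
        scale = 1.0
        for _ in range(40):
            cand = theta - scale * step
            if cand[0] < cand[1]:
                ll_new = _loglik_3cat(cand, table)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    theta, ll = cand, ll_new
                    break
            scale *= 0.5
        else:
            break
        if np.abs(theta).max() > 40:  # separation: parameters diverging
            break
    se_beta = np.nan
    if converged:
        _, hess = _grad_hess_3cat(theta, table)
        try:
            cov = np.linalg.inv(-hess)
            if cov[2, 2] > 0:
                se_beta = float(np.sqrt(cov[2, 2]))
            else:
                converged = False
        except np.linalg.LinAlgError:
            converged = False
    return CumulativeLogitFit(
        alpha1=float(theta[0]),
        alpha2=float(theta[1]),
        beta=float(theta[2]),
        se_beta=se_beta,
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        n_used=n_used,
    )


def _newton_2cat(table2: np.ndarray) -> CumulativeLogitFit:
    """Binary collapse: P(y = low | x) = sigmoid(a1 + b*x); alpha2 is +inf."""
    n_used = int(table2.sum())
    c1 = np.clip(table2.sum(axis=0)[0] / n_used, 0.02, 0.98)
    theta = np.array([np.log(c1 / (1 - c1)), 0.0])

    def ll_f(th):
        out = 0.0
        for xi in (0, 1):
            q = expit(th[0] + th[1] * xi)
            for yi, p in enumerate((q, 1 - q)):
                n = table2[xi, yi]
                if n:
                    if p <= 0:
                        return -np.inf
                    out += n * np.log(p)
        return out

    def gh(th):
        grad = np.zeros(2)
        hess = np.zeros((2, 2))
        for xi in (0, 1):
            n0, n1 = table2[xi]
            ntot = n0 + n1
            q = expit(th[0] + th[1] * xi)
            r = n0 - ntot * q          # score wrt linear predictor
            w = -ntot * q * (1 - q)
            j = np.array([1.0, float(xi)])
            grad += r * j
            hess += w * np.outer(j, j)
        return grad, hess

    ll = ll_f(theta)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        grad, hess = gh(theta)
        if np.max(np.abs(grad)) < GRAD_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(40):
            cand = theta - scale * step
            ll_new = ll_f(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                theta, ll = cand, ll_new
                break
            scale *= 0.5
        else:
            break
        if np.abs(theta).max() > 40:
            break
    se_beta = np.nan
    if converged:
        _, hess = gh(theta)
        try:
            cov = np.linalg.inv(-hess)
            if cov[1, 1] > 0:
                se_beta = float(np.sqrt(cov[1, 1]))
            else:
                converged = False
        except np.linalg.LinAlgError:
            converged = False
    return CumulativeLogitFit(
        alpha1=float(theta[0]),
        alpha2=np.inf,
        beta=float(theta[1]),
        se_beta=se_beta,
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        n_used=n_used,
    )


def fit_cumlogit(y: np.ndarray, x: np.ndarray) -> CumulativeLogitFit:
    """Maximum-likelihood proportional-odds fit of genotype on phenotype.

    ``y`` holds genotype codes 0/1/2 (missing -1 dropped), ``x`` the binary
    phenotype.  Monomorphic markers are untestable; when exactly two genotype
    categories are observed they are relabelled 0/1 and the single-intercept
    cumulative model is fitted (``alpha2`` reported as +inf).
    """
    y = np.asarray(y)
    x = np.asarray(x)
    if y.shape != x.shape:
        raise ValueError("genotype and phenotype vectors differ in length")
    table = _table_from_vectors(y, x)
    if table.sum(axis=1).min() == 0:
        raise ValueError("need at least one case and one control")
    present = np.flatnonzero(table.sum(axis=0) > 0)
    if present.size < 2:
        raise ValueError("untestable SNP: genotype is monomorphic")
    if present.size == 2:
        return _newton_2cat(table[:, present])
    return _newton_3cat(table)


def fit_cumlogit_null(y: np.ndarray, x: np.ndarray) -> float:
    """Log-likelihood of the intercept-only model (beta fixed at 0).

    With no covariate the cumulative-logit MLE is the empirical category
    distribution, so the null log-likelihood is available in closed form.
    """
    y = np.asarray(y)
    ok = (y != MISSING)
    y = y[ok]
    n = y.size
    ll = 0.0
    for yi in (0, 1, 2):
        c = int((y == yi).sum())
        if c:
            ll += c * np.log(c / n)
    return float(ll)


def likelihood_ratio_test(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """LRT of beta=0 on the same cumulative-logit model; returns (stat, p)."""
    from scipy.stats import chi2

    fit = fit_cumlogit(y, x)
    ll0 = fit_cumlogit_null(y, x)
    stat = max(0.0, 2.0 * (fit.loglik - ll0))
    return stat, float(chi2.sf(stat, df=1))


def wald_test(fit: CumulativeLogitFit, snp_id: str = "") -> AssocResult:
    """Two-sided Wald test of beta = 0.

    P = 2*Phi(-|z|) via the normal survival function (erfc-based, so the far
    tail beyond |z| ~ 8 keeps full relative accuracy).
    """
    if not fit.converged:
        return AssocResult(snp_id, np.nan, np.nan, np.nan, np.nan, fit.n_used, "non_converged")
    if not (fit.se_beta > 0):
        return AssocResult(snp_id, fit.beta, np.nan, np.nan, np.nan, fit.n_used, "zero_se")
    z = fit.beta / fit.se_beta
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return AssocResult(snp_id, fit.beta, fit.se_beta, float(z), p, fit.n_used, "ok")


def _binlogit_assoc(y: np.ndarray, x: np.ndarray, snp_id: str) -> AssocResult:
    """Conventional direction: logistic regression of phenotype on allele dosage."""
    ok = (y != MISSING)
    y, x = y[ok].astype(float), x[ok]
    if np.unique(y).size < 2:
        raise ValueError("untestable SNP: genotype is monomorphic")
    n_used = int(y.size)
    theta = np.array([np.log(np.clip(x.mean(), 0.02, 0.98) / (1 - np.clip(x.mean(), 0.02, 0.98))), 0.0])
    X = np.column_stack([np.ones_like(y), y])
    converged = False
    for _ in range(MAX_ITER):
        mu = expit(X @ theta)
        grad = X.T @ (x - mu)
        if np.max(np.abs(grad)) < GRAD_TOL:
            converged = True
            break
        W = mu * (1 - mu)
        H = -(X.T * W) @ X
        try:
            theta = theta - np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        if np.abs(theta).max() > 40:
            break
    if not converged:
        return AssocResult(snp_id, np.nan, np.nan, np.nan, np.nan, n_used, "non_converged")
    mu = expit(X @ theta)
    H = -(X.T * (mu * (1 - mu))) @ X
    cov = np.linalg.inv(-H)
    se = float(np.sqrt(cov[1, 1]))
    z = float(theta[1] / se)
    return AssocResult(snp_id, float(theta[1]), se, z, float(min(1.0, 2 * norm.sf(abs(z)))), n_used, "ok")


def run_gwas(
    gm: GenotypeMatrix,
    snp_map: pd.DataFrame | None = None,
    model: str = "cumlogit",
) -> pd.DataFrame:
    """Association scan over every SNP in the matrix.

    Returns one row per SNP with columns snp_id, chrom, pos, beta, se, z, p,
    n_used, status.  Untestable or non-converged markers get NA statistics and
    a reason code.  When a SNP map (snp_id, chrom, pos, ...) is supplied, rows
    are ordered by (chrom, pos); otherwise input order is kept.
    """
    if model not in ("cumlogit", "binlogit"):
        raise ValueError(f"unknown model {model!r}")
    x = gm.phenotype
    records = []
    for j, snp_id in enumerate(gm.snp_ids):
        y = gm.genotypes[:, j]
        try:
            if model == "cumlogit":
                res = wald_test(fit_cumlogit(y, x), snp_id)
            else:
                res = _binlogit_assoc(y, x, snp_id)
        except ValueError as exc:
            reason = "monomorphic" if "monomorphic" in str(exc) else "untestable"
            res = AssocResult(snp_id, np.nan, np.nan, np.nan, np.nan,
                              int((y != MISSING).sum()), reason)
        records.append(res)
    df = pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se_beta for r in records],
            "z": [r.z for r in records],
            "p": [r.p for r in records],
            "n_used": [r.n_used for r in records],
            "status": [r.status for r in records],
        }
    )
    if snp_map is not None:
        pos = snp_map.set_index("snp_id")[["chrom", "pos"]]
        df.insert(1, "chrom", df["snp_id"].map(pos["chrom"]))
        df.insert(2, "pos", df["snp_id"].map(pos["pos"]))
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    else:
        df.insert(1, "chrom", pd.NA)
        df.insert(2, "pos", pd.NA)
    return df


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise error threshold alpha/m for m tests."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m
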