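"""Competitive logistic drug-set enrichment.

The model is  logit P(Y=1) = b0 + b1*X1 + b2*X2,  where Y flags drugs that
treat the disorder, X1 is the drug's total target count (the competitive
adjustment) and X2 the GWAS-implication predictor. b2 is the parameter of
interest; exp(b2) is the odds increase that a GWAS-paired drug is a known
treatment, after accounting for target count.

Fitting is Newton/IRLS to gradient norm < 1e-8 (max 100 iterations). With
the small overlap counts typical of this design, complete or quasi-complete
separation is a live possibility and ordinary maximum likelihood then
diverges silently; fits are therefore screened (|beta| > 15, se > 50, or
non-convergence) and refit with Firth's bias-reduced penalized likelihood,
which stays finite under separation. The fit path is always reported.

Cluster-robust (sandwich) standard errors grouped on the drug-class label
are available for analyses accounting for shared targets across drugs of
one class; no small-sample correction is applied, so singleton clusters
reduce exactly to HC0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import chi2, norm

from .design import DesignRow

#: Two-sided 95% normal quantile used for all confidence intervals.
Z_95 = 1.959964
GRAD_TOL = 1e-8
MAX_ITER = 100
#: Separation screen: any |beta| above this, or se2 above SE_LIMIT, or a
#: non-converged Newton fit, triggers the Firth refit.
BETA_LIMIT = 15.0
SE_LIMIT = 50.0


class DegenerateDataError(ValueError):
    """The design cannot identify the enrichment coefficient."""


@dataclass
class CoreFit:
    beta: np.ndarray
    cov: np.ndarray
    loglike: float
    converged: bool
    method: str  # "mle" | "firth"
    separation: bool


@dataclass
class EnrichmentResult:
    """Fitted enrichment for one disorder x predictor coding."""

    disorder_id: str
    mode: str
    beta0: float
    beta1: float  # nan when X1 omitted
    beta2: float
    se2: float
    or2: float
    ci95: tuple[float, float]
    wald_p: float
    lrt_p: float
    n_drugs: int
    n_treatments: int
    n_overlap_treat: int
    n_overlap_nontreat: int
    fit_method: str
    converged: bool
    separation_flag: bool
    adjusted_p: Optional[float] = None
    significant: Optional[bool] = None

    @property
    def wald_z(self) -> float:
        return self.beta2 / self.se2


def _loglike(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = np.clip(X @ beta, -35.0, 35.0)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def fit_logistic_mle(X: np.ndarray, y: np.ndarray,
                     tol: float = GRAD_TOL, maxiter: int = MAX_ITER) -> CoreFit:
    """Newton/IRLS logistic MLE with step-halving; converged when the
    score norm drops below ``tol``."""
    n, k = X.shape
    beta = np.zeros(k)
    ll = _loglike(X, y, beta)
    converged = False
    for _ in range(maxiter):
        p = expit(np.clip(X @ beta, -35.0, 35.0))
        g = X.T @ (y - p)
        if np.linalg.norm(g) < tol:
            converged = True
            break
        W = p * (1.0 - p)
        H = X.T @ (X * W[:, None])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # step-halving keeps the ascent monotone near separation
        for _ in range(30):
            cand = beta + step
            ll_new = _loglike(X, y, cand)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta, ll = cand, ll_new
    p = expit(np.clip(X @ beta, -35.0, 35.0))
    W = p * (1.0 - p)
    H = X.T @ (X * W[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return CoreFit(beta=beta, cov=cov, loglike=ll, converged=converged,
                   method="mle", separation=False)


def fit_logistic_firth(X: np.ndarray, y: np.ndarray,
                       tol: float = GRAD_TOL, maxiter: int = 200) -> CoreFit:
    """Firth bias-reduced logistic fit (Jeffreys-prior penalized score).

    The modified score is U*(b) = X'(y - p + h (1/2 - p)) with h the
    leverages of the weighted design; estimates are finite even under
    complete separation. Covariance is the inverse Fisher information at
    the penalized optimum.
    """
    n, k = X.shape
    beta = np.zeros(k)

    def penalized_ll(b):
        p = expit(np.clip(X @ b, -35.0, 35.0))
        W = np.clip(p * (1.0 - p), 1e-12, None)
        H = X.T @ (X * W[:, None])
        sign, logdet = np.linalg.slogdet(H)
        return _loglike(X, y, b) + 0.5 * (logdet if sign > 0 else -np.inf)

    pll = penalized_ll(beta)
    converged = False
    for _ in range(maxiter):
        p = expit(np.clip(X @ beta, -35.0, 35.0))
        W = np.clip(p * (1.0 - p), 1e-12, None)
        XW = X * W[:, None]
        H = X.T @ XW
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            Hinv = np.linalg.pinv(H)
        h = np.einsum("ij,jk,ik->i", X, Hinv, XW)
        U = X.T @ (y - p + h * (0.5 - p))
        if np.linalg.norm(U) < tol:
            converged = True
            break
        step = Hinv @ U
        for _ in range(30):
            cand = beta + step
            pll_new = penalized_ll(cand)
            if pll_new >= pll - 1e-12:
                break
            step *= 0.5
        beta, pll = cand, pll_new
    p = expit(np.clip(X @ beta, -35.0, 35.0))
    W = np.clip(p * (1.0 - p), 1e-12, None)
    H = X.T @ (X * W[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return CoreFit(beta=beta, cov=cov, loglike=_loglike(X, y, beta),
                   converged=converged, method="firth", separation=True)


def fit_core(X: np.ndarray, y: np.ndarray) -> CoreFit:
    """MLE first; Firth refit when the MLE shows signs of separation."""
    fit = fit_logistic_mle(X, y)
    with np.errstate(invalid="ignore"):
        ses = np.sqrt(np.clip(np.diag(fit.cov), 0.0, None))
    if (not fit.converged or np.any(np.abs(fit.beta) > BETA_LIMIT)
            or np.any(ses > SE_LIMIT) or not np.all(np.isfinite(ses))):
        return fit_logistic_firth(X, y)
    return fit


def _design_arrays(rows: Sequence[DesignRow], include_x1: bool,
                   log_x1: bool) -> tuple[np.ndarray, np.ndarray, int]:
    y = np.array([r.y for r in rows], dtype=float)
    x2 = np.array([r.x2 for r in rows], dtype=float)
    cols = [np.ones(len(rows))]
    if include_x1:
        x1 = np.array([r.x1 for r in rows], dtype=float)
        cols.append(np.log(x1) if log_x1 else x1)
    cols.append(x2)
    X = np.column_stack(cols)
    if y.min() == y.max():
        raise DegenerateDataError("outcome is constant (all y identical)")
    if x2.min() == x2.max():
        raise DegenerateDataError("degenerate predictor (x2 constant)")
    return X, y, X.shape[1] - 1  # index of the x2 column


def fit_enrichment(rows: Sequence[DesignRow],
                   disorder_id: str = "",
                   mode: str = "binary",
                   include_x1: bool = True,
                   log_x1: bool = False) -> EnrichmentResult:
    """Fit the enrichment model on one disorder's design table.

    Returns the fitted coefficients, the odds ratio exp(b2) with its
    Wald 95% CI and two-sided p, an LRT p for diagnostics, the overlap
    counts, and flags describing the fit path.
    """
    X, y, j = _design_arrays(rows, include_x1, log_x1)
    fit = fit_core(X, y)
    se2 = float(np.sqrt(max(fit.cov[j, j], 0.0)))
    beta2 = float(fit.beta[j])
    if se2 > 0 and math.isfinite(se2):
        z = beta2 / se2
        wald_p = max(float(2.0 * norm.sf(abs(z))), 5e-324)
        ci = (math.exp(beta2 - Z_95 * se2), math.exp(beta2 + Z_95 * se2))
    else:
        wald_p, ci = 1.0, (0.0, math.inf)
    # LRT against the model without X2, on the same fit path
    X0 = X[:, :j]
    if fit.method == "mle":
        ll0 = fit_logistic_mle(X0, y).loglike
        lrt_p = float(chi2.sf(max(2.0 * (fit.loglike - ll0), 0.0), 1))
    else:
        lrt_p = float("nan")
    overlap = np.array([1 if r.implicated_targets else 0 for r in rows])
    yv = np.array([r.y for r in rows])
    return EnrichmentResult(
        disorder_id=disorder_id, mode=mode,
        beta0=float(fit.beta[0]),
        beta1=float(fit.beta[1]) if include_x1 else float("nan"),
        beta2=beta2, se2=se2, or2=math.exp(beta2), ci95=ci,
        wald_p=wald_p, lrt_p=lrt_p,
        n_drugs=len(rows), n_treatments=int(yv.sum()),
        n_overlap_treat=int(((yv == 1) & (overlap == 1)).sum()),
        n_overlap_nontreat=int(((yv == 0) & (overlap == 1)).sum()),
        fit_method=fit.method, converged=fit.converged,
        separation_flag=fit.separation)


def fit_enrichment_clustered(rows: Sequence[DesignRow],
                             disorder_id: str = "",
                             mode: str = "binary",
                             include_x1: bool = True,
                             log_x1: bool = False) -> EnrichmentResult:
    """As :func:`fit_enrichment`, with cluster-robust (sandwich) errors
    grouped on the class label; point estimates are unchanged.

    The sandwich is A^{-1} B A^{-1} with bread A = X'WX and meat B summed
    over within-cluster score outer products, with no small-sample
    correction — with every drug its own cluster this is exactly HC0.
    """
    labels = [r.class_label for r in rows]
    if any(lbl is None for lbl in labels):
        raise ValueError("class_label must be present on every row")
    if len(set(labels)) < 2:
        raise ValueError("cluster-robust variance undefined with a single cluster")
    base = fit_enrichment(rows, disorder_id, mode, include_x1, log_x1)
    X, y, j = _design_arrays(rows, include_x1, log_x1)
    beta = np.array([base.beta0] + ([base.beta1] if include_x1 else []) + [base.beta2])
    p = expit(np.clip(X @ beta, -35.0, 35.0))
    W = np.clip(p * (1.0 - p), 1e-12, None)
    A = X.T @ (X * W[:, None])
    Ainv = np.linalg.pinv(A)
    resid = y - p
    meat = np.zeros_like(A)
    for lbl in set(labels):
        idx = [i for i, l in enumerate(labels) if l == lbl]
        s = X[idx].T @ resid[idx]
        meat += np.outer(s, s)
    V = Ainv @ meat @ Ainv
    se2 = float(np.sqrt(max(V[j, j], 0.0)))
    wald_p = max(float(2.0 * norm.sf(abs(base.beta2 / se2))), 5e-324) if se2 > 0 else 1.0
    ci = (math.exp(base.beta2 - Z_95 * se2), math.exp(base.beta2 + Z_95 * se2))
    return replace(base, se2=se2, wald_p=wald_p, ci95=ci)


def bonferroni_adjust(results: Sequence[EnrichmentResult],
                      alpha: float = 0.05) -> list[EnrichmentResult]:
    """Flag significance at the family-wise level across disorders tested:
    significant iff wald_p < alpha / m; adjusted_p = min(1, m * wald_p)."""
    m = len(results)
    return [replace(r, adjusted_p=min(1.0, m * r.wald_p),
                    significant=r.wald_p < alpha / m) for r in results]


RESULT_COLUMNS = (
    "disorder_id", "mode", "n_drugs", "n_treatments", "beta0", "beta1",
    "beta2", "se2", "or2", "ci_low", "ci_high", "wald_p", "lrt_p",
    "adjusted_p", "significant", "fit_method", "separation_flag",
    "n_overlap_treat", "n_overlap_nontreat",
)


def write_results(results: Iterable[EnrichmentResult], path,
                  comment: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            vals = [r.disorder_id, r.mode, r.n_drugs, r.n_treatments,
                    repr(r.beta0), repr(r.beta1), repr(r.beta2), repr(r.se2),
                    repr(r.or2), repr(r.ci95[0]), repr(r.ci95[1]),
                    repr(r.wald_p), repr(r.lrt_p),
                    "" if r.adjusted_p is None else repr(r.adjusted_p),
                    "" if r.significant is None else int(r.significant),
                    r.fit_method, int(r.separation_flag),
                    r.n_overlap_treat, r.n_overlap_nontreat]
            fh.write("\t".join(str(v) for v in vals) + "\n")
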