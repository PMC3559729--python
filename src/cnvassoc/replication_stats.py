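"""Replication-stage statistics: PC-corrected logistic association,
genomic inflation, Fisher's-method combination and the Bonferroni bar.

Replication of a discovery CNVR regresses case/control status on carrier
status plus the first three principal components of genotype structure,
absorbing residual population stratification; the reported p is a
two-sided Wald test on the carrier coefficient.  Rare CNVs frequently
produce monotone likelihoods (all carriers in one cohort): this is
detected and the model refit with Firth's penalised likelihood, which is
reported — never silently substituted.

Genomic inflation is the classic median-based factor

    lambda = median(qchisq(1 - p, df = 1)) / qchisq(0.5, df = 1)

with the null median 0.4549...; lambda near 1 indicates controlled
stratification.  Fisher's method combines k independent p-values through
X^2 = -2 * sum(log p_i) against a chi-square with 2k degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import DegenerateInputError, ValidationError

_CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class LogisticResult:
    beta_cnv: float                 # log-odds of case status per carrier
    se: float
    p_wald: float
    covariates_used: list[int]      # PC indices included (1-based)
    converged: bool
    separation_detected: bool
    method: str = "ml"              # "ml" or "firth"


@dataclass
class CombinedP:
    p_list: list[float]
    chi_sq: float
    df: int
    p_combined: float


# ---------------------------------------------------------------------------
# logistic association
# ---------------------------------------------------------------------------

def _design(carrier: np.ndarray, pcs: np.ndarray | None):
    cols = [np.ones_like(carrier, dtype=float), carrier.astype(float)]
    used: list[int] = []
    if pcs is not None and pcs.size:
        for j in range(pcs.shape[1]):
            col = pcs[:, j].astype(float)
            if np.var(col) > 1e-12:      # drop zero-variance covariates
                cols.append(col)
                used.append(j + 1)
    return np.column_stack(cols), used


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                 tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, bool]:
    """Firth-penalised logistic regression (Jeffreys-prior score
    adjustment).  Returns (beta, covariance, converged)."""
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtW = X.T * w
        info = XtW @ X
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        h = np.einsum("ij,jk,ik->i", X, cov, X) * w   # hat diagonal
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = cov @ score
        # damp very large steps for stability
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv((X.T * w) @ X)
    return beta, cov, converged


def logistic_cnv_association(carrier_status: Sequence[int],
                             cohort_label: Sequence,
                             pcs=None,
                             test: str = "wald") -> LogisticResult:
    """Logistic regression of case/control status on CNV carrier status.

    Parameters
    ----------
    carrier_status : per-sample 0/1 indicator.
    cohort_label : per-sample "case"/"control" strings or 0/1 integers
        (case = 1).
    pcs : optional (n_samples, >=3) array of principal components; the
        first three are used as covariates.  Zero-variance columns are
        dropped, so constant PCs reproduce the covariate-free model.
    test : "wald" (default) or "lr" for a likelihood-ratio p on the
        carrier term.
    """
    carrier = np.asarray(carrier_status, dtype=int)
    label = np.asarray([
        1 if (x == 1 or x == "case") else 0 for x in cohort_label])
    if carrier.shape != label.shape:
        raise ValidationError("carrier_status and cohort_label differ in length")
    if carrier.sum() == 0:
        raise DegenerateInputError("no carriers: carrier effect unidentifiable")
    if carrier.sum() == len(carrier):
        raise DegenerateInputError("all samples are carriers")
    pcs_arr = None
    if pcs is not None:
        pcs_arr = np.asarray(pcs, dtype=float)
        if pcs_arr.ndim == 1:
            pcs_arr = pcs_arr[:, None]
        pcs_arr = pcs_arr[:, :3]
    X, used = _design(carrier, pcs_arr)

    # monotone likelihood: every carrier in a single cohort
    carrier_labels = label[carrier == 1]
    separated = bool(carrier_labels.min() == carrier_labels.max())

    beta = se = None
    converged = False
    if not separated:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(label, X).fit(disp=0, maxiter=200)
                converged = bool(fit.mle_retvals.get("converged", False))
                if converged and abs(fit.params[1]) < 15:
                    beta = float(fit.params[1])
                    se = float(fit.bse[1])
                    if test == "lr":
                        X0 = np.delete(X, 1, axis=1)
                        fit0 = sm.Logit(label, X0).fit(disp=0, maxiter=200)
                        lr = 2.0 * (fit.llf - fit0.llf)
                        p = float(stats.chi2.sf(max(lr, 0.0), 1))
                    else:
                        p = 2.0 * float(stats.norm.sf(abs(beta / se)))
                else:
                    separated = True   # quasi-separation / non-convergence
            except Exception:
                separated = True
    if separated or beta is None:
        bvec, cov, converged = _firth_logit(X, label)
        beta = float(bvec[1])
        se = float(math.sqrt(cov[1, 1]))
        p = 2.0 * float(stats.norm.sf(abs(beta / se)))
        method = "firth"
    else:
        method = "ml"
    return LogisticResult(beta_cnv=beta, se=se, p_wald=min(1.0, p),
                          covariates_used=used, converged=converged,
                          separation_detected=separated, method=method)


def logistic_score_pvalues(carriers: np.ndarray, cohort_label,
                           pcs=None) -> np.ndarray:
    """Vectorised score (Rao) tests of many carrier vectors at once.

    Fits the null logistic model (case/control status on intercept plus
    optional PC covariates) a single time, then evaluates the 1-df score
    statistic for every column of ``carriers`` in closed form — the
    standard genome-wide shortcut for inflation diagnostics, where fitting
    one maximum-likelihood model per locus would be needlessly slow.
    Asymptotically equivalent to the per-locus Wald test of
    :func:`logistic_cnv_association`.
    """
    X = np.asarray(carriers, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray([1 if (v == 1 or v == "case") else 0
                    for v in cohort_label], dtype=float)
    cols = [np.ones_like(y)]
    if pcs is not None:
        p = np.asarray(pcs, dtype=float)
        if p.ndim == 1:
            p = p[:, None]
        for j in range(min(3, p.shape[1])):
            if np.var(p[:, j]) > 1e-12:
                cols.append(p[:, j])
    Z = np.column_stack(cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, Z).fit(disp=0, maxiter=200)
    mu = fit.predict(Z)
    w = mu * (1.0 - mu)
    U = X.T @ (y - mu)
    ZW = Z * w[:, None]
    A_inv = np.linalg.inv(Z.T @ ZW)
    B = ZW.T @ X
    V = (w @ (X * X)) - np.einsum("km,kl,lm->m", B, A_inv, B)
    V = np.maximum(V, 1e-300)
    T = U ** 2 / V
    return stats.chi2.sf(T, 1)


# ---------------------------------------------------------------------------
# inflation, combination, multiple testing
# ---------------------------------------------------------------------------

def stratification_inflation_study(seed: int = 0, n_draws: int = 10,
                                   n_regions: int = 4000,
                                   n_cases: int = 400, n_controls: int = 400,
                                   pc_shift: float = 1.0,
                                   pc_effect: float = 0.5
                                   ) -> tuple[float, float]:
    """Measure genomic inflation on stratified synthetic cohorts.

    Simulates ``n_draws`` independent case/control draws in which carrier
    probability follows PC1 and the control PC1 distribution is shifted,
    then pools score-test p-values across all regions and draws (the
    median-based inflation factor needs tens of thousands of tests before
    its own sampling noise drops below a few percent).  Returns
    ``(lambda_uncorrected, lambda_pc_corrected)``: the first reflects the
    planted stratification, the second should sit near 1 when the first
    three PCs are included as covariates.
    """
    from .synthetic_data import simulate_structured_dataset  # lazy: no cycle

    p_unc: list[float] = []
    p_cor: list[float] = []
    for r in range(n_draws):
        ds = simulate_structured_dataset(
            n_cases=n_cases, n_controls=n_controls, n_regions=n_regions,
            pc_shift=pc_shift, pc_effect=pc_effect,
            seed=seed + 1000 * r)
        mat = ds.carrier_matrix()
        label = np.array([1 if s.cohort == "case" else 0
                          for s in ds.samples])
        pcs = np.array([s.pcs for s in ds.samples])
        ok = (mat.sum(axis=0) > 0) & (mat.sum(axis=0) < mat.shape[0])
        p_unc.extend(logistic_score_pvalues(mat[:, ok], label, None))
        p_cor.extend(logistic_score_pvalues(mat[:, ok], label, pcs))
    return genomic_inflation(p_unc), genomic_inflation(p_cor)


def genomic_inflation(p_values: Sequence[float]) -> float:
    """Median-based genomic inflation factor over 1-df association tests."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValidationError("genomic_inflation needs at least one p-value")
    if ((p <= 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / _CHI2_1DF_MEDIAN)


def fisher_combine(p_list: Sequence[float]) -> CombinedP:
    """Fisher's method: X^2 = -2 sum(ln p_i) ~ chi-square with 2k df."""
    p = [float(x) for x in p_list]
    if not p:
        raise ValidationError("fisher_combine needs at least one p-value")
    for x in p:
        if x <= 0.0:
            raise ValidationError(
                "p = 0 passed to Fisher's method (log undefined); floor "
                "upstream, e.g. at the smallest positive float")
        if x > 1.0:
            raise ValidationError(f"p-value {x} > 1")
    chi_sq = -2.0 * sum(math.log(x) for x in p)
    df = 2 * len(p)
    return CombinedP(p_list=p, chi_sq=chi_sq, df=df,
                     p_combined=float(stats.chi2.sf(chi_sq, df)))


def bonferroni_bar(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must be in (0, 1)")
    return alpha / n_tests
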