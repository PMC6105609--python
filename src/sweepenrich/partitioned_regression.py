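"""Stratified LD-score enrichment regression.

Model: E[chi2_j] = 1 + N*a + N * sum_c tau_c * ell(j, c), fit by two-step
weighted least squares with a free intercept, with a delete-a-block jackknife
over contiguous SNP blocks supplying the coefficient covariance and the
standard error of the enrichment fold.

Per-category heritability under (possibly overlapping) annotations:
h2_c = sum_{j in c} sum_c' tau_c' a_jc' = (A'A tau)_c, h2_total = M_c . tau,
and fold_c = (h2_c / h2_total) / (M_c / M). The fold standard error is
obtained by jackknifing the ratio directly, not by the delta method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ld_annotation import LDScoreTable

__all__ = ["EnrichmentResult", "fit_stratified", "enrichment_table", "format_p"]


@dataclass
class EnrichmentResult:
    """Per-category coefficients and enrichment statistics for one phenotype.

    Arrays are ordered like `names`. `jackknife_cov` covers
    (intercept, tau_1..tau_C). Folds are NaN (and `fold_defined` False) when
    the estimated total heritability is not positive.
    """

    names: list[str]
    tau: np.ndarray
    tau_se: np.ndarray
    intercept: float
    intercept_se: float
    jackknife_cov: np.ndarray
    h2_total: float
    h2_c: np.ndarray
    M_c: np.ndarray
    M: int
    fold_c: np.ndarray
    fold_se: np.ndarray
    p_enrichment: np.ndarray
    p_coefficient: np.ndarray
    fold_defined: bool
    n_blocks: int

    def category(self, name: str) -> dict:
        """Table-row view (fold +/- s.e., p-values) for one category."""
        k = self.names.index(name)
        return {
            "category": name,
            "tau": float(self.tau[k]),
            "tau_se": float(self.tau_se[k]),
            "h2": float(self.h2_c[k]),
            "fold": float(self.fold_c[k]),
            "fold_se": float(self.fold_se[k]),
            "p_enrichment": float(self.p_enrichment[k]),
            "p_coefficient": float(self.p_coefficient[k]),
        }


def _two_sided_p(est: float, se: float) -> float:
    if not np.isfinite(est) or not np.isfinite(se):
        return float("nan")
    if se == 0:
        return 1.0 if abs(est) < 1e-10 else float(np.finfo(float).tiny)
    return float(max(2.0 * norm.sf(abs(est) / se), np.finfo(float).tiny))


def _folds(tau: np.ndarray, ld: LDScoreTable) -> tuple[np.ndarray, float]:
    h2_c = ld.overlap @ tau
    h2_total = float(ld.M_c @ tau)
    with np.errstate(divide="ignore", invalid="ignore"):
        share_h2 = h2_c / h2_total
        share_m = ld.M_c / ld.M
        fold = share_h2 / share_m
    return fold, h2_total


def fit_stratified(
    chisq: np.ndarray,
    n: np.ndarray | float,
    ldscores: LDScoreTable,
    n_blocks: int = 200,
    weight_mode: str = "two_step",
) -> EnrichmentResult:
    """Fit the partitioned model and jackknife the enrichment folds.

    Parameters
    ----------
    chisq : per-SNP squared z-scores, aligned with `ldscores` rows.
    n : per-SNP GWAS sample size (scalar or array).
    ldscores : partitioned LD scores including the base (all-SNPs) category.
    n_blocks : contiguous equal-SNP-count jackknife blocks (chromosome order).
    weight_mode : "two_step" (default), "ld" (1/max(ell_total,1) only) or
        "constant" (unweighted), the latter two mainly for validation.
    """
    chisq = np.asarray(chisq, dtype=float)
    m = len(chisq)
    if m != len(ldscores):
        raise ValueError("chisq not aligned with LD scores")
    names = list(ldscores.names)
    C = len(names)
    if C + 1 >= m:
        raise ValueError(f"{C} categories with only {m} SNPs: rank deficient")
    n = np.broadcast_to(np.asarray(n, dtype=float), (m,))

    ell = ldscores.ell
    keep = np.ones(C, dtype=bool)
    for k in range(C):
        if np.ptp(ell[:, k]) == 0:
            warnings.warn(
                f"LD-score column {names[k]!r} is constant (collinear with "
                "intercept); dropped from the regression"
            )
            keep[k] = False
    X = np.column_stack([np.ones(m), n[:, None] * ell[:, keep]])

    base_w = 1.0 / np.maximum(ldscores.ell_total, 1.0)
    if weight_mode == "constant":
        w = np.ones(m)
    elif weight_mode == "ld":
        w = base_w
    elif weight_mode == "two_step":
        theta1 = _wls(X, chisq, base_w)
        fitted = X @ theta1
        w = base_w / np.maximum(1.0, fitted) ** 2
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")

    # block sufficient statistics: full fit and all delete-one-block fits
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = chisq * sw
    n_blocks = min(n_blocks, m)
    bounds = np.linspace(0, m, n_blocks + 1).astype(int)
    p = X.shape[1]
    G_b = np.empty((n_blocks, p, p))
    c_b = np.empty((n_blocks, p))
    for b in range(n_blocks):
        s = slice(bounds[b], bounds[b + 1])
        G_b[b] = Xw[s].T @ Xw[s]
        c_b[b] = Xw[s].T @ yw[s]
    G = G_b.sum(axis=0)
    cvec = c_b.sum(axis=0)
    theta = np.linalg.solve(G, cvec)

    full_tau = np.zeros(C)
    full_tau[keep] = theta[1:]
    fold, h2_total = _folds(full_tau, ldscores)
    fold_defined = np.isfinite(h2_total) and h2_total > 1e-12
    if not fold_defined:
        fold = np.full(C, np.nan)

    theta_jk = np.empty((n_blocks, p))
    fold_jk = np.empty((n_blocks, C))
    for b in range(n_blocks):
        th = np.linalg.solve(G - G_b[b], cvec - c_b[b])
        theta_jk[b] = th
        tau_b = np.zeros(C)
        tau_b[keep] = th[1:]
        fold_jk[b], _ = _folds(tau_b, ldscores)

    dev = theta_jk - theta_jk.mean(axis=0)
    cov = (n_blocks - 1) / n_blocks * (dev.T @ dev)
    theta_se = np.sqrt(np.diag(cov))

    if fold_defined and np.isfinite(fold_jk).all():
        fdev = fold_jk - fold_jk.mean(axis=0)
        fold_var = (n_blocks - 1) / n_blocks * (fdev**2).sum(axis=0)
        fold_se = np.sqrt(fold_var)
    else:
        fold_se = np.full(C, np.nan)

    tau = full_tau
    tau_se = np.zeros(C)
    tau_se[keep] = theta_se[1:]
    h2_c = ldscores.overlap @ tau

    # expand jackknife covariance back to (intercept, all C taus)
    cov_full = np.zeros((C + 1, C + 1))
    sel = np.concatenate([[True], keep])
    cov_full[np.ix_(sel, sel)] = cov

    p_coef = np.array(
        [_two_sided_p(tau[k], tau_se[k]) for k in range(C)]
    )
    p_enr = np.array(
        [
            _two_sided_p(fold[k] - 1.0, fold_se[k]) if fold_defined else np.nan
            for k in range(C)
        ]
    )
    return EnrichmentResult(
        names=names,
        tau=tau,
        tau_se=tau_se,
        intercept=float(theta[0]),
        intercept_se=float(theta_se[0]),
        jackknife_cov=cov_full,
        h2_total=float(h2_total),
        h2_c=h2_c,
        M_c=ldscores.M_c.copy(),
        M=ldscores.M,
        fold_c=fold,
        fold_se=fold_se,
        p_enrichment=p_enr,
        p_coefficient=p_coef,
        fold_defined=bool(fold_defined),
        n_blocks=n_blocks,
    )


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    theta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return theta


_SUPERSCRIPT_MINUS = "−"


def format_p(p: float) -> str:
    """Render a p-value the way the report table prints it, e.g.
    0.0263 -> '2.63 × 10−2' (with a Unicode minus in the exponent)."""
    if not np.isfinite(p):
        return "NA"
    if p <= 0:
        raise ValueError("p must be positive")
    exponent = math.floor(math.log10(p))
    mantissa = p / 10**exponent
    if round(mantissa, 2) >= 10:  # e.g. p=0.09999 -> 10.00e-2 -> 1.00e-1
        mantissa /= 10
        exponent += 1
    if exponent == 0:
        return f"{mantissa:.2f}"
    sign = _SUPERSCRIPT_MINUS if exponent < 0 else ""
    return f"{mantissa:.2f} × 10{sign}{abs(exponent)}"


def enrichment_table(
    results: list[tuple[str, EnrichmentResult]], category: str = "HD"
) -> pd.DataFrame:
    """One row per phenotype with Fold +/- s.e.m. and the two p-values for
    the chosen category (the published-table shape plus coefficient columns)."""
    columns = [
        "phenotype",
        "fold",
        "fold_se",
        "p_enrichment",
        "p_enrichment_str",
        "tau",
        "tau_se",
        "p_coefficient",
        "p_coefficient_str",
    ]
    rows = []
    for phenotype, res in results:
        row = res.category(category)
        rows.append(
            {
                "phenotype": phenotype,
                "fold": row["fold"],
                "fold_se": row["fold_se"],
                "p_enrichment": row["p_enrichment"],
                "p_enrichment_str": format_p(row["p_enrichment"])
                if np.isfinite(row["p_enrichment"])
                else "NA",
                "tau": row["tau"],
                "tau_se": row["tau_se"],
                "p_coefficient": row["p_coefficient"],
                "p_coefficient_str": format_p(row["p_coefficient"])
                if np.isfinite(row["p_coefficient"])
                else "NA",
            }
        )
    return pd.DataFrame(rows, columns=columns)
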