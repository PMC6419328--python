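"""Per-cTOH case-control association.

Each region's binary carrier indicator enters a logistic model for disease
status together with sex and the leading genotype principal components:

    logit P(case) = b0 + b1 * carrier + b2 * sex + b3 * PC1 + ... .

Coefficients are estimated by Newton scoring (iteratively reweighted least
squares), inference is by Wald tests against the normal reference, odds
ratios and 95% CIs come from ``exp(b1 -/+ z * SE)``, and q-values across all
estimable regions are Benjamini-Hochberg step-up.  Fits that fail to
converge — typically (quasi-)separation of a rare carrier pattern — are
flagged and excluded from the FDR rather than reported with unreliable
standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri
from scipy.stats import norm

from .core import DataError
from .ctoh import CTOHRegion


@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    converged: bool
    n_iter: int


def fit_logistic(
    outcome: np.ndarray,
    design: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton scoring.

    Convergence is declared when the largest absolute score (gradient)
    component falls below ``tol``; standard errors come from the inverse
    observed information at the final estimate.  Non-convergence within
    ``max_iter`` iterations — the signature of separation — is flagged, not
    raised.

    Raises
    ------
    DataError
        For a constant outcome, misaligned shapes or a rank-deficient design.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(design, dtype=float)
    if x.ndim != 2 or y.ndim != 1 or x.shape[0] != y.shape[0]:
        raise DataError("design and outcome are misaligned")
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise DataError("outcome is constant; model not estimable")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DataError("rank-deficient design matrix")

    beta = np.zeros(x.shape[1])
    converged = False
    n_iter = 0
    info = None
    for n_iter in range(1, max_iter + 1):
        eta = x @ beta
        mu = expit(eta)
        score = x.T @ (y - mu)
        w = mu * (1.0 - mu)
        info = (x * w[:, None]).T @ x
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            converged = False
            break
        beta = beta + step

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except (np.linalg.LinAlgError, ValueError):
        se = np.full(x.shape[1], np.nan)
        converged = False
    # under (quasi-)separation the score can reach tolerance while the
    # estimate diverges; |beta| > 15 (OR > 3e6) is never a real effect here
    if converged and (
        not np.all(np.isfinite(se)) or np.max(np.abs(beta)) > 15.0
    ):
        converged = False
    return LogisticFit(beta=beta, se=se, converged=converged, n_iter=n_iter)


def wald_test(beta: float, se: float) -> float:
    """Two-sided Wald p-value ``2 * (1 - Phi(|beta/se|))``."""
    if not se > 0:
        raise DataError("Wald test requires SE > 0")
    return float(2.0 * norm.sf(abs(beta / se)))


def odds_ratio_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio ``exp(beta)`` with its Wald confidence interval."""
    if not se > 0:
        raise DataError("confidence interval requires SE > 0")
    if not 0.0 < level < 1.0:
        raise DataError("confidence level must lie in (0, 1)")
    z = ndtri(0.5 + level / 2.0)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} m * p_(j) / j`` over the sorted p-values, capped
    at 1 and mapped back to input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DataError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def associate_all(
    regions: list[CTOHRegion],
    carriers: pd.DataFrame,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit one logistic model per region and BH-adjust across regions.

    ``carriers`` is the individuals x regions 0/1 matrix (columns are region
    ids); ``covariates``, if given, must carry a ``sex`` column and any
    ``PC*`` columns, row-aligned with ``carriers``.  Regions whose carrier
    column is constant are reported as non-estimable; non-converged fits are
    flagged; both are excluded from the FDR adjustment.
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != len(carriers):
        raise DataError("phenotype and carrier matrix are misaligned")
    cov_block = np.empty((len(y), 0))
    if covariates is not None:
        if len(covariates) != len(y):
            raise DataError("covariates misaligned with carrier matrix")
        cols = [c for c in covariates.columns if c == "sex" or c.startswith("PC")]
        cov_block = covariates[cols].to_numpy(dtype=float)

    if not regions:
        warnings.warn("no cTOH regions to test", stacklevel=2)

    rows = []
    for region in regions:
        col = carriers[region.region_id].to_numpy(dtype=float)
        rec = {
            "region_id": region.region_id,
            "chrom": region.chrom,
            "length_bp": region.bp_length,
            "n_snps": region.n_snps,
            "n_carriers": int(col.sum()),
            "beta": np.nan,
            "se": np.nan,
            "wald_z": np.nan,
            "p_value": np.nan,
            "odds_ratio": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "fdr_q": np.nan,
            "converged": False,
            "estimable": True,
        }
        if col.min() == col.max():
            rec["estimable"] = False
            rows.append(rec)
            continue
        design = np.column_stack([np.ones_like(y), col, cov_block])
        fit = fit_logistic(y, design)
        rec["converged"] = bool(fit.converged)
        if fit.converged and np.isfinite(fit.se[1]) and fit.se[1] > 0:
            b, s = float(fit.beta[1]), float(fit.se[1])
            odds, lo, hi = odds_ratio_ci(b, s)
            rec.update(
                beta=b,
                se=s,
                wald_z=b / s,
                p_value=wald_test(b, s),
                odds_ratio=odds,
                ci_low=lo,
                ci_high=hi,
            )
        rows.append(rec)

    results = pd.DataFrame(
        rows,
        columns=[
            "region_id",
            "chrom",
            "length_bp",
            "n_snps",
            "n_carriers",
            "beta",
            "se",
            "wald_z",
            "p_value",
            "odds_ratio",
            "ci_low",
            "ci_high",
            "fdr_q",
            "converged",
            "estimable",
        ],
    )
    if len(results):
        ok = results["converged"] & results["p_value"].notna()
        if ok.any():
            results.loc[ok, "fdr_q"] = bh_fdr(results.loc[ok, "p_value"].to_numpy())
    return results
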