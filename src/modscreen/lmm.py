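"""Single-marker association under a linear mixed model.

The model is ``y = alpha + x beta + u + eps`` with ``u ~ MVN(0, lambda/tau K)``
and ``eps ~ MVN(0, I/tau)``: ``K`` is the centered relatedness matrix,
``lambda`` the ratio of the polygenic to the residual variance component and
``1/tau`` the residual variance.  After one eigendecomposition ``K = U D Uᵀ``
the rotated model has diagonal covariance ``(lambda d_i + 1)/tau``, so the
likelihood profiles over ``(alpha, tau)`` in closed form and ``lambda`` is a
one-dimensional search.  Per-marker tests reuse the null ``lambda`` (the
standard approximate scheme) or re-optimise it per marker (exact mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from modscreen.containers import GenotypePanel, KinshipMatrix

logger = logging.getLogger(__name__)

LOG10_LAMBDA_RANGE = (-5.0, 5.0)
_GRID_POINTS = 50


class FitError(RuntimeError):
    pass


@dataclass
class LMMNullFit:
    """Null-model (no marker) variance-component fit.

    ``lambda_hat`` is the ratio of the between-strain to the residual variance
    component; ``tau_hat`` the inverse residual variance; the eigen-cache of K
    is kept so per-marker tests rotate vectors instead of solving dense
    systems.
    """

    lambda_hat: float
    tau_hat: float
    alpha_hat: float
    loglik: float
    method: str
    eigvals: np.ndarray
    eigvecs: np.ndarray
    y_rot: np.ndarray
    ones_rot: np.ndarray
    lambda_unidentifiable: bool = False

    @property
    def n(self) -> int:
        return len(self.y_rot)


def _profile_loglik(
    log10_lam: float,
    d: np.ndarray,
    X_rot: np.ndarray,
    y_rot: np.ndarray,
    method: str,
) -> float:
    """Log-likelihood at a given lambda, profiled over fixed effects and tau."""
    lam = 10.0**log10_lam
    n, p = X_rot.shape
    v = lam * d + 1.0
    w = 1.0 / v
    XtWX = (X_rot * w[:, None]).T @ X_rot
    XtWy = (X_rot * w[:, None]).T @ y_rot
    try:
        coef = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return -np.inf
    resid = y_rot - X_rot @ coef
    rss = float(np.sum(w * resid**2))
    if rss <= 0:
        return -np.inf
    logdet_v = float(np.sum(np.log(v)))
    if method == "ml":
        sigma2 = rss / n
        return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet_v + n)
    # REML: penalise by the log-determinant of the weighted information
    sigma2 = rss / (n - p)
    sign, logdet_i = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    return -0.5 * (
        (n - p) * np.log(2 * np.pi * sigma2) + logdet_v + logdet_i + (n - p)
    )


def _optimize_lambda(
    d: np.ndarray, X_rot: np.ndarray, y_rot: np.ndarray, method: str
) -> tuple[float, float]:
    """Grid scan then Brent refinement of the profile likelihood in log10 lambda."""
    lo, hi = LOG10_LAMBDA_RANGE
    grid = np.linspace(lo, hi, _GRID_POINTS)
    vals = np.array([_profile_loglik(g, d, X_rot, y_rot, method) for g in grid])
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    if a == b:
        return grid[i], vals[i]
    res = optimize.minimize_scalar(
        lambda g: -_profile_loglik(g, d, X_rot, y_rot, method),
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if -res.fun >= vals[i]:
        return float(res.x), float(-res.fun)
    return float(grid[i]), float(vals[i])


def fit_null(
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    method: str = "reml",
    psd_tol: float = 1e-8,
) -> LMMNullFit:
    """Fit the intercept-only mixed model by maximising the profile likelihood.

    Eigendecomposes K once, scans 50 grid points of log10(lambda) on
    [-5, 5] and refines with bounded Brent.  ``method`` selects the REML
    (default) or ML criterion.  REML is the default because with a centered
    relatedness matrix the ones vector is an exact null eigenvector of K, and
    the ML profile likelihood then diverges like (1/2) log lambda as
    lambda -> infinity; the REML determinant penalty cancels that divergence
    and leaves an interior optimum.
    """
    y = np.asarray(y, dtype=float)
    Kmat = K.K if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    n = len(y)
    if Kmat.shape != (n, n):
        raise ValueError(f"K shape {Kmat.shape} does not match phenotype length {n}")
    if np.ptp(y) == 0:
        raise FitError("phenotype is constant; variance components unidentifiable")
    if method not in ("ml", "reml"):
        raise ValueError("method must be 'ml' or 'reml'")

    d, U = np.linalg.eigh(Kmat)
    scale = max(1.0, float(d[-1]))
    if d[0] < -psd_tol * scale:
        raise ValueError(f"K is not positive semi-definite (min eigenvalue {d[0]:.3g})")
    d = np.clip(d, 0.0, None)

    y_rot = U.T @ y
    ones_rot = U.T @ np.ones(n)
    X_rot = ones_rot[:, None]

    unidentifiable = bool(d[-1] <= psd_tol)
    if unidentifiable:
        log10_lam, ll = LOG10_LAMBDA_RANGE[0], _profile_loglik(
            LOG10_LAMBDA_RANGE[0], d, X_rot, y_rot, method
        )
        logger.warning("K is (numerically) zero; lambda fixed at its lower bound")
    else:
        log10_lam, ll = _optimize_lambda(d, X_rot, y_rot, method)

    lam = 10.0**log10_lam
    v = lam * d + 1.0
    w = 1.0 / v
    alpha = float(np.sum(w * ones_rot * y_rot) / np.sum(w * ones_rot**2))
    resid = y_rot - alpha * ones_rot
    rss = float(np.sum(w * resid**2))
    sigma2 = rss / n if method == "ml" else rss / (n - 1)
    return LMMNullFit(
        lambda_hat=lam,
        tau_hat=1.0 / sigma2,
        alpha_hat=alpha,
        loglik=ll,
        method=method,
        eigvals=d,
        eigvecs=U,
        y_rot=y_rot,
        ones_rot=ones_rot,
        lambda_unidentifiable=unidentifiable,
    )


@dataclass
class AssocResult:
    variant_id: str
    beta: float
    se_beta: float
    wald_stat: float
    p_value: float
    maf: float
    skipped: bool = False
    reason: str = ""


def _gls_single(
    y_rot: np.ndarray,
    ones_rot: np.ndarray,
    x_rot: np.ndarray,
    lam: float,
    d: np.ndarray,
    reference: str,
) -> tuple[float, float, float, float]:
    """Weighted (GLS) regression of y on [1, x] in the eigenbasis."""
    n = len(y_rot)
    w = 1.0 / (lam * d + 1.0)
    a11 = np.sum(w * ones_rot**2)
    a12 = np.sum(w * ones_rot * x_rot)
    a22 = np.sum(w * x_rot**2)
    b1 = np.sum(w * ones_rot * y_rot)
    b2 = np.sum(w * x_rot * y_rot)
    det = a11 * a22 - a12**2
    if det <= 0:
        raise FitError("design matrix is singular")
    beta = (a11 * b2 - a12 * b1) / det
    alpha = (a22 * b1 - a12 * b2) / det
    rss = np.sum(w * y_rot**2) - alpha * b1 - beta * b2
    sigma2 = max(rss, 0.0) / (n - 2)
    var_beta = sigma2 * a11 / det
    se = float(np.sqrt(var_beta))
    wald = float(beta**2 / var_beta) if var_beta > 0 else np.inf
    p = _wald_p(wald, n, reference)
    return float(beta), se, wald, p


def _wald_p(wald: float | np.ndarray, n: int, reference: str) -> float | np.ndarray:
    if reference == "chisq":
        p = stats.chi2.sf(wald, 1)
    elif reference == "t":
        p = 2.0 * stats.t.sf(np.sqrt(wald), n - 2)
    else:
        raise ValueError("reference must be 'chisq' or 't'")
    # keep p strictly positive so -log10 p and BH stay finite
    return np.maximum(p, np.finfo(float).tiny)


def test_variant(
    y: np.ndarray,
    x: np.ndarray,
    null_fit: LMMNullFit,
    reference: str = "chisq",
    mode: str = "emmax",
    method: str | None = None,
) -> AssocResult:
    """Wald test of a single marker under the fitted mixed model.

    Missing genotypes are mean-imputed; monomorphic markers are skipped with
    a reason code.  In ``emmax`` mode the null-model lambda is reused; in
    ``exact`` mode lambda is re-optimised with the marker in the design.
    """
    x = np.asarray(x, dtype=float).copy()
    if np.any(np.isnan(x)):
        m = np.nanmean(x)
        x[np.isnan(x)] = m
    uniq = np.unique(x)
    freq = float(np.mean(x))
    maf = min(freq, 1 - freq)
    if len(uniq) < 2:
        return AssocResult("", np.nan, np.nan, np.nan, np.nan, maf, True, "monomorphic")
    U = null_fit.eigvecs
    x_rot = U.T @ x
    lam = null_fit.lambda_hat
    if mode == "exact":
        X_rot = np.column_stack([null_fit.ones_rot, x_rot])
        log10_lam, _ = _optimize_lambda(
            null_fit.eigvals, X_rot, null_fit.y_rot, method or null_fit.method
        )
        lam = 10.0**log10_lam
    beta, se, wald, p = _gls_single(
        null_fit.y_rot, null_fit.ones_rot, x_rot, lam, null_fit.eigvals, reference
    )
    return AssocResult("", beta, se, wald, float(p), maf)


def run_gwa(
    panel: GenotypePanel,
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray | None,
    mode: str = "emmax",
    method: str = "reml",
    reference: str = "chisq",
    p_threshold: float = 1e-5,
) -> pd.DataFrame:
    """Genome-wide single-marker scan.

    Modes: ``emmax`` (default) estimates lambda once on the null model and
    reuses it for every marker, vectorised; ``exact`` re-optimises lambda per
    marker; ``ols`` ignores K entirely (lambda = 0), for inflation
    comparisons.  Returns a table sorted by p-value with Bonferroni and
    Benjamini-Hochberg columns and a ``hit`` flag at ``p_threshold``.
    """
    y = np.asarray(y, dtype=float)
    n, m = panel.n_strains, panel.n_variants
    if mode == "ols":
        Kmat = np.zeros((n, n))
        fit = fit_null(y, Kmat, method=method)
    else:
        if K is None:
            raise ValueError("K is required unless mode='ols'")
        fit = fit_null(y, K, method=method)
    lam = 0.0 if mode == "ols" else fit.lambda_hat

    G = panel.imputed()
    freq = G.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    poly = np.array([len(np.unique(G[:, j])) > 1 for j in range(m)])

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    wald = np.full(m, np.nan)
    pval = np.full(m, np.nan)

    if mode == "exact":
        for j in np.where(poly)[0]:
            r = test_variant(y, G[:, j], fit, reference=reference, mode="exact", method=method)
            beta[j], se[j], wald[j], pval[j] = r.beta, r.se_beta, r.wald_stat, r.p_value
    else:
        U, d = fit.eigvecs, fit.eigvals
        w = 1.0 / (lam * d + 1.0)
        Xr = U.T @ G
        o, yr = fit.ones_rot, fit.y_rot
        a11 = float(np.sum(w * o**2))
        b1 = float(np.sum(w * o * yr))
        yy = float(np.sum(w * yr**2))
        a12 = (w * o) @ Xr
        a22 = w @ (Xr**2)
        b2 = (w * yr) @ Xr
        det = a11 * a22 - a12**2
        ok = poly & (det > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            b_hat = (a11 * b2 - a12 * b1) / det
            a_hat = (a22 * b1 - a12 * b2) / det
            rss = np.maximum(yy - a_hat * b1 - b_hat * b2, 0.0)
            sigma2 = rss / (n - 2)
            var_b = sigma2 * a11 / det
            beta[ok] = b_hat[ok]
            se[ok] = np.sqrt(var_b[ok])
            wald[ok] = b_hat[ok] ** 2 / var_b[ok]
        pval[ok] = _wald_p(wald[ok], n, reference)

    out = panel.variants.copy()
    out["maf"] = maf
    out["beta"] = beta
    out["se_beta"] = se
    out["wald_stat"] = wald
    out["p_value"] = pval
    out["skipped"] = ~poly
    out["reason"] = np.where(poly, "", "monomorphic")

    tested = out["p_value"].notna()
    n_tested = int(tested.sum())
    out["p_bonferroni"] = np.minimum(out["p_value"] * n_tested, 1.0)
    from modscreen.enrichment import bh_qvalues

    q = np.full(m, np.nan)
    if n_tested:
        q[tested.to_numpy()] = bh_qvalues(out.loc[tested, "p_value"].to_numpy())
    out["p_bh"] = q
    out["hit"] = out["p_value"] < p_threshold
    out = out.sort_values("p_value", kind="mergesort", na_position="last").reset_index(drop=True)
    logger.info(
        "GWA: %d/%d variants tested, %d below p < %.3g", n_tested, m, int(out["hit"].sum()), p_threshold
    )
    return out


def genomic_inflation(pvalues_or_stats: np.ndarray, from_p: bool = False) -> float:
    """Genomic-control inflation factor: median chi-square over its null median."""
    x = np.asarray(pvalues_or_stats, dtype=float)
    x = x[~np.isnan(x)]
    if from_p:
        x = stats.chi2.isf(x, 1)
    return float(np.median(x) / stats.chi2.ppf(0.5, 1))
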