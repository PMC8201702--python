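"""Single-marker linear mixed-model association with genomic control.

Model per marker: y = 1*mu + x*beta + u + e with u ~ N(0, A * lambda *
tau^-1) and e ~ N(0, I * tau^-1); A is the pedigree numerator
relationship matrix, lambda the additive-to-residual variance ratio.
lambda is estimated once per trait on the null (intercept-only) model
by REML (ML selectable) using a single eigen-decomposition of A, then
fixed across markers: each marker is scored by generalized least
squares in the rotated (diagonalized) coordinates, with a 1-df Wald
chi-square on beta.  A per-marker lambda refit is available behind a
flag for cross-checking.

Genomic control: the inflation factor is the through-origin regression
slope of the sorted observed chi-squares on the chi-square(1 df)
theoretical quantiles (a median-based estimator is selectable);
corrected statistics are chi2 / inflation_factor with p-values
recomputed from chi-square(1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix
from .pedigree import RelationshipMatrix

logger = logging.getLogger(__name__)

LAMBDA_BOUNDS = (1e-5, 1e5)


class AssocError(ValueError):
    pass


@dataclass
class LambdaFit:
    """Null-model variance-ratio fit, carrying the reusable rotation."""

    lambda_: float
    resid_var: float  # tau^-1
    loglik: float
    method: str
    boundary: bool
    eigvals: np.ndarray  # eigenvalues of A
    rot_y: np.ndarray  # U' y
    rot_ones: np.ndarray  # U' 1
    rot: np.ndarray  # U'
    ids: list[str]


def _neg_loglik(log_lam: float, s: np.ndarray, ry: np.ndarray, rw: np.ndarray, reml: bool):
    lam = np.exp(log_lam)
    d = lam * s + 1.0
    w = 1.0 / d
    # weighted OLS of rotated y on rotated intercept
    xtx = np.sum(w * rw * rw)
    alpha = np.sum(w * rw * ry) / xtx
    resid = ry - alpha * rw
    rss = np.sum(w * resid * resid)
    n = len(ry)
    if reml:
        df = n - 1
        ll = -0.5 * (
            df * np.log(2 * np.pi * rss / df) + df
            + np.sum(np.log(d)) + np.log(xtx)
        )
    else:
        df = n
        ll = -0.5 * (n * np.log(2 * np.pi * rss / n) + n + np.sum(np.log(d)))
    if not np.isfinite(ll):
        raise AssocError(f"non-finite likelihood at lambda={lam:.3g}")
    return -ll, rss / df


def fit_null_lambda(
    y: np.ndarray | pd.Series,
    a_matrix: RelationshipMatrix,
    method: str = "reml",
) -> LambdaFit:
    """Estimate the variance ratio lambda on the intercept-only model.

    Uses the eigen-decomposition of A (computed once and reused for all
    markers of the trait).  With an unstructured A (identity), the
    likelihood is flat in lambda: the boundary solution is returned and
    flagged.
    """
    ids = list(y.index.astype(str)) if isinstance(y, pd.Series) else [str(i) for i in range(len(y))]
    yv = np.asarray(y, dtype=float)
    if len(yv) < 10:
        raise AssocError(f"n={len(yv)} too small for variance-component estimation")
    if np.std(yv) == 0:
        raise AssocError("phenotype has zero variance")
    if a_matrix.values.shape[0] != len(yv):
        raise AssocError("A matrix does not match phenotype length")
    reml = method.lower() == "reml"
    s, u = np.linalg.eigh((a_matrix.values + a_matrix.values.T) / 2.0)
    s = np.clip(s, 0.0, None)
    ry = u.T @ yv
    rw = u.T @ np.ones(len(yv))
    lo, hi = np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1])
    res = optimize.minimize_scalar(
        lambda t: _neg_loglik(t, s, ry, rw, reml)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    boundary = bool(res.x < lo + 1e-3 or res.x > hi - 1e-3)
    # a flat profile (e.g. A = I) leaves lambda unidentifiable
    nll_lo = _neg_loglik(lo, s, ry, rw, reml)[0]
    nll_hi = _neg_loglik(hi, s, ry, rw, reml)[0]
    if max(nll_lo, nll_hi) - res.fun < 1e-6:
        boundary = True
        lam = LAMBDA_BOUNDS[0]
        res.x = lo
    if boundary:
        logger.warning("lambda estimate at boundary (%.3g); flat or degenerate likelihood", lam)
    nll, sigma2 = _neg_loglik(res.x, s, ry, rw, reml)
    return LambdaFit(
        lambda_=lam, resid_var=float(sigma2), loglik=-float(nll), method=method,
        boundary=bool(boundary), eigvals=s, rot_y=ry, rot_ones=rw, rot=u.T, ids=ids,
    )


def score_markers(
    y: pd.Series,
    genotypes: GenotypeMatrix,
    fit: LambdaFit,
    refit_lambda_per_marker: bool = False,
) -> pd.DataFrame:
    """Wald chi-square association scan of all markers against one trait.

    ``y`` must be indexed by animal id and aligned with the ids used in
    ``fit``; marker dosages are taken from ``genotypes`` in that order.
    Missing dosages are mean-imputed per marker.  Monomorphic markers
    (zero dosage variance in the subset) are skipped and logged.
    Returns a tidy DataFrame with beta, se, chi2_raw, p, neg_log10_p
    (genomic control is applied separately).
    """
    ids = [str(i) for i in y.index]
    if ids != fit.ids:
        raise AssocError("phenotype ids differ from the ids used for the null fit")
    gindex = {i: k for k, i in enumerate(genotypes.ids)}
    try:
        rows = [gindex[i] for i in ids]
    except KeyError as e:
        raise AssocError(f"no genotypes for animal {e.args[0]!r}") from None
    x = genotypes.values[rows, :].astype(float)
    # mean-impute per-marker missing dosages
    if np.isnan(x).any():
        col_mean = np.nanmean(x, axis=0)
        nan_r, nan_c = np.where(np.isnan(x))
        x[nan_r, nan_c] = col_mean[nan_c]

    if refit_lambda_per_marker:
        return _score_refit(y, x, genotypes, fit)

    # GLS of y on (1, x) in the eigenbasis of A: V^-1 is diagonal there,
    # but the rotated intercept U'1 is a general vector, so solve the
    # two-regressor normal equations explicitly (vectorized over markers)
    w = 1.0 / (fit.lambda_ * fit.eigvals + 1.0)
    rx = fit.rot @ x  # rotated markers, (n, m)
    ry, rw = fit.rot_y, fit.rot_ones
    n = len(ry)
    a11 = float(np.sum(w * rw * rw))
    b1 = float(np.sum(w * rw * ry))
    syy = float(np.sum(w * ry * ry))
    a12 = (w * rw) @ rx
    a22 = w @ (rx * rx)
    b2 = (w * ry) @ rx
    det = a11 * a22 - a12 * a12
    sxx_c = a22 - a12 * a12 / a11  # marker variance net of the intercept
    mono = sxx_c <= 1e-12 * np.maximum(a22, 1.0)
    n_mono = int(mono.sum())
    if n_mono:
        logger.info("skipping %d monomorphic markers", n_mono)
        if n_mono > 0.5 * len(mono):
            logger.warning(
                "more than half of the markers are monomorphic in this subset; "
                "check the analysis subset"
            )
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (a11 * b2 - a12 * b1) / det
        alpha = (a22 * b1 - a12 * b2) / det
        rss = syy - (alpha * b1 + beta * b2)
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 * a11 / det)
        chi2 = (beta / se) ** 2
    beta[mono] = np.nan
    se[mono] = np.nan
    chi2[mono] = np.nan
    p = stats.chi2.sf(chi2, df=1)
    res = genotypes.snp_map[["snp_id", "chrom", "pos_bp"]].copy()
    res["beta"] = beta
    res["se"] = se
    res["chi2_raw"] = chi2
    res["p"] = p
    with np.errstate(divide="ignore"):
        res["neg_log10_p"] = -np.log10(p)
    return res


def _marker_gls(w, rw, rx, ry):
    """Weighted two-regressor GLS pieces for one marker in rotated space."""
    a11 = float(np.sum(w * rw * rw))
    a12 = float(np.sum(w * rw * rx))
    a22 = float(np.sum(w * rx * rx))
    b1 = float(np.sum(w * rw * ry))
    b2 = float(np.sum(w * rx * ry))
    syy = float(np.sum(w * ry * ry))
    det = a11 * a22 - a12 * a12
    beta = (a11 * b2 - a12 * b1) / det
    alpha = (a22 * b1 - a12 * b2) / det
    rss = syy - (alpha * b1 + beta * b2)
    return beta, rss, a11 / det


def _score_refit(y, x, genotypes, fit):
    """Per-marker lambda refit under the alternative model (the exact
    per-marker algorithm of the reference implementation), using the
    shared eigen-rotation of A."""
    s, rw, ry, rot = fit.eigvals, fit.rot_ones, fit.rot_y, fit.rot
    n = len(ry)
    lo, hi = np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1])
    out = []
    for j in range(x.shape[1]):
        xj = x[:, j]
        if np.var(xj) <= 1e-12:
            out.append((np.nan, np.nan, np.nan, np.nan))
            continue
        rx = rot @ xj

        def nll(log_lam):
            d = np.exp(log_lam) * s + 1.0
            w = 1.0 / d
            _, rss, _ = _marker_gls(w, rw, rx, ry)
            df = n - 2
            return 0.5 * (df * np.log(rss / df) + np.sum(np.log(d)))

        res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-6})
        w = 1.0 / (np.exp(res.x) * s + 1.0)
        beta, rss, covfac = _marker_gls(w, rw, rx, ry)
        sigma2 = rss / (n - 2)
        se = float(np.sqrt(sigma2 * covfac))
        chi2 = (beta / se) ** 2
        out.append((beta, se, chi2, float(stats.chi2.sf(chi2, df=1))))
    res = genotypes.snp_map[["snp_id", "chrom", "pos_bp"]].copy()
    res[["beta", "se", "chi2_raw", "p"]] = np.array(out)
    with np.errstate(divide="ignore"):
        res["neg_log10_p"] = -np.log10(res["p"])
    return res


def genomic_control(
    chi2_raw: np.ndarray | pd.Series,
    estimator: str = "regression",
    floor_at_one: bool = False,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Genomic-control inflation factor and corrected statistics.

    Returns (inflation_factor, chi2_gc, p_gc).  ``regression`` fits a
    through-origin line of the sorted observed chi-squares on the
    chi-square(1) theoretical quantiles; ``median`` divides the
    observed median by 0.4549 (the chi-square(1) median).
    """
    chi2 = np.asarray(chi2_raw, dtype=float)
    ok = np.isfinite(chi2)
    vals = chi2[ok]
    if len(vals) < 100:
        raise AssocError(f"genomic control needs >= 100 markers, got {len(vals)}")
    if estimator == "regression":
        obs = np.sort(vals)
        mquant = len(vals)
        expq = stats.chi2.ppf((np.arange(1, mquant + 1) - 0.5) / mquant, df=1)
        factor = float(np.sum(obs * expq) / np.sum(expq * expq))
    elif estimator == "median":
        factor = float(np.median(vals) / stats.chi2.ppf(0.5, df=1))
    else:
        raise AssocError(f"unknown estimator {estimator!r}")
    if floor_at_one:
        factor = max(factor, 1.0)
    chi2_gc = chi2 / factor
    p_gc = stats.chi2.sf(chi2_gc, df=1)
    return factor, chi2_gc, p_gc


def apply_genomic_control(res: pd.DataFrame, **kwargs) -> tuple[pd.DataFrame, float]:
    """Attach chi2_gc / corrected p / mlog10p columns to a scan result."""
    factor, chi2_gc, p_gc = genomic_control(res["chi2_raw"], **kwargs)
    out = res.copy()
    out["chi2_gc"] = chi2_gc
    out["p"] = p_gc
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(p_gc)
    return out, factor


def qq_data(p_values: np.ndarray | pd.Series) -> pd.DataFrame:
    """Expected vs observed -log10 p quantile pairs for a Q-Q plot."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if np.any((p <= 0) | (p > 1)):
        raise AssocError("p-values must lie in (0, 1]")
    obs = np.sort(-np.log10(p))[::-1]
    mquant = len(p)
    expd = -np.log10((np.arange(1, mquant + 1) - 0.5) / mquant)
    return pd.DataFrame({"expected": expd, "observed": obs})
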