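"""Kinship-corrected genome-wide association of a binary phenotype.

The phenotype (presence/absence of any functional copy of a duplicated
gene) is treated as quantitative and fitted with a linear mixed model

    y = mu + g + e,   g ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I),

where K is a VanRaden-style genomic kinship matrix. Variance components
are estimated once on the null model by REML after a spectral decomposition
of K (the likelihood is one-dimensional in delta = sigma_e^2 / sigma_g^2),
and each marker is then tested by generalized least squares in the rotated
eigenspace with those components held fixed (the EMMAX approximation).
Significance uses a Bonferroni threshold, reported as -log10(alpha / m).

Marker QC follows the usual panel filters: minor allele frequency > 0.05
and missing rate < 0.1, with remaining missing dosages imputed to the
marker mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "filter_and_impute",
    "compute_kinship",
    "NullModelFit",
    "fit_null_mlm",
    "association_scan",
    "bonferroni_threshold",
    "genomic_control_lambda",
]

log = logging.getLogger(__name__)


def filter_and_impute(
    raw: pd.DataFrame, maf_min: float = 0.05, miss_max: float = 0.1
) -> pd.DataFrame:
    """Filter a dosage panel (accessions x markers, 0/1/2 with NaN missing)
    and mean-impute surviving missing entries."""
    g = raw.astype(float)
    miss = g.isna().mean(axis=0)
    freq = g.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = (maf > maf_min) & (miss < miss_max)
    if not keep.any():
        raise ValueError("no markers survive the MAF/missing-rate filters")
    g = g.loc[:, keep]
    return g.fillna(g.mean(axis=0))


def compute_kinship(panel: pd.DataFrame) -> pd.DataFrame:
    """VanRaden genomic relationship matrix.

    Centered dosages Z = G - 2p, K = Z Z' / sum(2 p (1-p)); the diagonal
    averages about 1 for an unstructured panel.
    """
    g = panel.to_numpy(dtype=float)
    if np.isnan(g).any():
        raise ValueError("panel contains missing values; impute first")
    p = g.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("panel is entirely monomorphic")
    g = g[:, poly]
    p = p[poly]
    z = g - 2.0 * p
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    k = z @ z.T / denom
    return pd.DataFrame(k, index=panel.index, columns=panel.index)


@dataclass
class NullModelFit:
    """REML variance components of the intercept-only mixed model."""

    sigma_g2: float
    sigma_e2: float
    delta: float  # sigma_e2 / sigma_g2
    loglik: float  # restricted log-likelihood
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def heritability(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


def _reml_loglik(log_delta: float, lam: np.ndarray, y_r: np.ndarray, x_r: np.ndarray) -> float:
    delta = 10.0 ** log_delta
    v = lam + delta
    w = 1.0 / v
    xtwx = (x_r * w[:, None]).T @ x_r
    beta = np.linalg.solve(xtwx, (x_r * w[:, None]).T @ y_r)
    r = y_r - x_r @ beta
    n, q = x_r.shape
    rss = float(np.sum(w * r * r))
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    _, logdet_xtx = np.linalg.slogdet(x_r.T @ x_r)
    nq = n - q
    return 0.5 * (
        nq * np.log(nq / (2 * np.pi))
        - nq
        - nq * np.log(rss)
        - float(np.sum(np.log(v)))
        - logdet_xtwx
        + logdet_xtx
    )


def fit_null_mlm(
    phenotype: np.ndarray | pd.Series,
    kinship: pd.DataFrame | np.ndarray,
    psd_tol: float = 1e-6,
) -> NullModelFit:
    """REML fit of the intercept-only mixed model.

    delta is profiled on a log10 grid over [1e-5, 1e5] and refined by
    bounded scalar minimization (tolerance 1e-8 on log10 delta).
    """
    y = np.asarray(phenotype, dtype=float)
    k = np.asarray(kinship, dtype=float)
    lam, u = np.linalg.eigh((k + k.T) / 2.0)
    if lam.min() < -psd_tol * max(1.0, lam.max()):
        raise ValueError(
            f"kinship is not PSD within tolerance (min eigenvalue {lam.min():.3g})"
        )
    lam = np.clip(lam, 0.0, None)
    y_r = u.T @ y
    x_r = u.T @ np.ones((len(y), 1))

    grid = np.linspace(-5.0, 5.0, 61)
    vals = [-_reml_loglik(g, lam, y_r, x_r) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_reml_loglik(g, lam, y_r, x_r),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    log_delta = float(res.x)
    delta = 10.0 ** log_delta
    v = lam + delta
    w = 1.0 / v
    xtwx = (x_r * w[:, None]).T @ x_r
    beta = np.linalg.solve(xtwx, (x_r * w[:, None]).T @ y_r)
    r = y_r - x_r @ beta
    n, q = x_r.shape
    sigma_g2 = float(np.sum(w * r * r) / (n - q))
    return NullModelFit(
        sigma_g2=sigma_g2,
        sigma_e2=delta * sigma_g2,
        delta=delta,
        loglik=float(_reml_loglik(log_delta, lam, y_r, x_r)),
        eigenvalues=lam,
        eigenvectors=u,
    )


def association_scan(
    panel: pd.DataFrame,
    phenotype: np.ndarray | pd.Series,
    kinship: pd.DataFrame | np.ndarray | None = None,
    null: NullModelFit | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-marker mixed-model association (EMMAX-style single fit).

    With the null variance components fixed, each marker is regressed by
    weighted least squares in the eigenspace of K; the Wald p-value uses a
    t reference with n - 2 degrees of freedom, so an identity kinship
    reproduces ordinary least squares exactly. Markers that are constant
    after imputation get p = 1 (logged).

    Returns a DataFrame (marker, beta, se, p, neglog10p) plus a Bonferroni
    ``threshold`` attribute in ``.attrs``.
    """
    y = np.asarray(phenotype, dtype=float)
    g = panel.to_numpy(dtype=float)
    n, m = g.shape
    if null is None:
        if kinship is None:
            raise ValueError("provide a kinship matrix or a null fit")
        null = fit_null_mlm(y, kinship)
    u, lam, delta = null.eigenvectors, null.eigenvalues, null.delta
    w = 1.0 / (lam + delta)
    y_r = u.T @ y
    g_r = u.T @ g
    one_r = u.T @ np.ones(n)

    s11 = float(np.sum(w * one_r * one_r))
    s1y = float(np.sum(w * one_r * y_r))
    syy = float(np.sum(w * y_r * y_r))
    s1g = (w * one_r) @ g_r
    sgy = (w * y_r) @ g_r
    sgg = np.einsum("i,ij,ij->j", w, g_r, g_r)

    det = s11 * sgg - s1g**2
    const = det <= 1e-12 * np.maximum(s11 * sgg, 1e-300)
    if const.any():
        log.info("association_scan: %d constant markers set to p = 1", const.sum())
    det_safe = np.where(const, 1.0, det)
    beta = (s11 * sgy - s1g * s1y) / det_safe
    beta0 = (s1y - beta * s1g) / s11
    rss = syy - beta0 * s1y - beta * sgy
    dof = n - 2
    sigma2 = np.clip(rss, 0.0, None) / dof
    se = np.sqrt(np.clip(sigma2 * s11 / det_safe, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p = np.where(const, 1.0, p)
    beta = np.where(const, 0.0, beta)
    se = np.where(const, np.nan, se)

    out = pd.DataFrame(
        {
            "marker": panel.columns,
            "beta": beta,
            "se": se,
            "p": p,
            "neglog10p": -np.log10(np.clip(p, 1e-300, None)),
        }
    )
    out.attrs["threshold"] = bonferroni_threshold(alpha, m)
    out.attrs["sigma_g2"] = null.sigma_g2
    out.attrs["sigma_e2"] = null.sigma_e2
    return out


def bonferroni_threshold(alpha: float, marker_count: int) -> float:
    """-log10 of the Bonferroni-corrected per-marker significance level."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if marker_count < 1:
        raise ValueError("marker_count must be >= 1")
    return float(-np.log10(alpha / marker_count))


def genomic_control_lambda(pvalues: np.ndarray) -> float:
    """Median-based genomic-control inflation factor."""
    chi = stats.chi2.isf(np.asarray(pvalues, dtype=float), 1)
    return float(np.median(chi) / stats.chi2.isf(0.5, 1))
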