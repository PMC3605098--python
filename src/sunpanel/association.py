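"""Mixed-linear-model association scans with an effective-number-of-tests
significance threshold.

The model is ``y = X beta + u + e`` with ``u ~ N(0, sigma2_g * 2K)`` for a
relative-kinship matrix K (the factor 2 converts kinship to the numerator
relationship scale) and ``e ~ N(0, sigma2_e * I)``.  Variance components
are estimated once by REML on the null (no-marker) model via a 1-D search
over the variance ratio after a single eigendecomposition of 2K, then
held fixed while every marker is tested by generalized least squares
(the population-parameters-previously-determined shortcut).  Supported
fixed-effect designs: intercept only (models "naive" — which also drops
the kinship term — and "k"), intercept + principal-component scores
("pk") or intercept + admixture membership fractions ("qk").

Marker significance uses a two-sided Wald t-test on the dosage
coefficient.  The scan-wide threshold is alpha divided by the effective
number of independent tests: per linkage group, the smallest number of
top eigenvalues of the marker correlation matrix whose sum reaches a
fraction C (default 0.995) of the total, summed over groups.  q-q
diagnostics report -log10 observed vs expected uniform quantiles and the
genomic-control inflation factor lambda (median chi-square ratio).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panel_io import GeneticMap, GenotypeMatrix
from .structure import KinshipMatrix

logger = logging.getLogger(__name__)

MODELS = ("naive", "k", "pk", "qk")


@dataclass
class MLMFit:
    """Null-model REML fit, cached for per-marker GLS scans."""

    accessions: list[str]
    y: np.ndarray
    x: np.ndarray                 # fixed-effect design (intercept + covars)
    eigvals: np.ndarray           # eigenvalues of 2K
    eigvecs: np.ndarray
    sigma2_g: float
    sigma2_e: float
    delta: float                  # sigma2_e / sigma2_g
    at_bound: bool
    reml_loglik: float
    model: str = "k"

    @property
    def heritability_ratio(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


def _reml_neg_loglik(
    log_delta: float, s: np.ndarray, yt: np.ndarray, xt: np.ndarray
) -> float:
    """Negative REML log-likelihood profiled over sigma2_g at fixed
    delta = sigma2_e/sigma2_g, in the eigenbasis of 2K."""
    delta = np.exp(log_delta)
    w = 1.0 / (s + delta)
    n, p = xt.shape
    xtwx = xt.T @ (w[:, None] * xt)
    xtwy = xt.T @ (w * yt)
    try:
        beta = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(xtwx, xtwy, rcond=None)[0]
    resid = yt - xt @ beta
    rss = float(resid @ (w * resid))
    if rss <= 0:
        return np.inf
    df = n - p
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return np.inf
    ll = -0.5 * (
        df * np.log(2.0 * np.pi * rss / df) + df
        + np.sum(np.log(s + delta))
        + logdet_xtwx
    )
    return -ll


def fit_null_mlm(
    y: pd.Series,
    kinship: KinshipMatrix | None,
    covariates: pd.DataFrame | None = None,
    model: str | None = None,
) -> MLMFit:
    """REML fit of the null mixed model for one trait.

    ``y`` is indexed by accession; accessions with missing phenotype are
    dropped.  ``kinship=None`` (or the "naive" model) collapses to
    ordinary least squares with sigma2_g = 0.  Covariates (P or Q) are
    aligned by accession and enter as fixed effects next to the intercept.
    """
    y = y.dropna()
    if y.std() == 0:
        raise ValueError("constant phenotype: variance components undefined")
    accessions = list(y.index)
    n = len(accessions)

    cols = [np.ones(n)]
    if covariates is not None:
        cov = covariates.loc[accessions]
        cols.extend(cov.to_numpy(dtype=float).T)
    x = np.column_stack(cols)

    if model is None:
        model = "naive" if kinship is None else (
            "k" if covariates is None else "pk")

    def _ols_fit() -> MLMFit:
        yt, xt = y.to_numpy(dtype=float), x
        beta = np.linalg.pinv(xt) @ yt
        resid = yt - xt @ beta
        sigma_e = float(resid @ resid) / max(n - x.shape[1], 1)
        return MLMFit(accessions, yt, x, np.zeros(n), np.eye(n),
                      0.0, sigma_e, np.inf, at_bound=True,
                      reml_loglik=np.nan, model=model or "naive")

    if kinship is None or model == "naive":
        return _ols_fit()

    a = 2.0 * kinship.aligned(accessions)
    a = 0.5 * (a + a.T)
    if np.abs(a).max() < 1e-12:
        # fully unrelated panel after truncation: the genetic component is
        # unidentifiable and the model collapses to OLS
        return _ols_fit()
    s, u = np.linalg.eigh(a)
    # truncating negative kinship estimates routinely leaves the matrix
    # slightly indefinite; bend small negative eigenvalues to 0 and only
    # reject a spectrum that is substantially negative
    if s.min() < -0.05 * max(abs(s.max()), 1.0):
        raise ValueError(
            f"kinship matrix far from PSD (min eigenvalue {s.min():.3g} "
            f"vs max {s.max():.3g}); check the estimator or input matrix"
        )
    if s.min() < 0:
        logger.info("bent %d negative kinship eigenvalues (min %.3g) to 0",
                    int((s < 0).sum()), s.min())
    s = np.maximum(s, 0.0)
    yt = u.T @ y.to_numpy(dtype=float)
    xt = u.T @ x

    grid = np.linspace(-12.0, 12.0, 49)
    vals = np.array([_reml_neg_loglik(g_, s, yt, xt) for g_ in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(s, yt, xt), method="bounded"
    )
    log_delta = float(res.x)
    at_bound = log_delta <= grid[0] + 0.5 or log_delta >= grid[-1] - 0.5
    delta = np.exp(log_delta)
    w = 1.0 / (s + delta)
    xtwx = xt.T @ (w[:, None] * xt)
    beta = np.linalg.solve(xtwx, xt.T @ (w * yt))
    resid = yt - xt @ beta
    df = n - x.shape[1]
    sigma_g = float(resid @ (w * resid)) / df
    sigma_e = sigma_g * delta
    if at_bound:
        logger.info("variance ratio at search bound (log delta = %.1f)",
                    log_delta)
    return MLMFit(accessions, y.to_numpy(dtype=float), x, s, u,
                  sigma_g, sigma_e, delta, at_bound,
                  reml_loglik=-float(res.fun), model=model)


def scan_association(
    g: GenotypeMatrix,
    fit: MLMFit,
    model: str | None = None,
    gmap: GeneticMap | None = None,
) -> tuple[pd.DataFrame, float]:
    """Single-marker GLS scan under the null-fitted covariance.

    Each marker enters as a fixed dosage covariate; missing dosages are
    mean-imputed per marker.  Markers collinear with the fixed-effect
    design are reported NA with a reason.  Returns the per-marker table
    (effect, se, p) and the genomic-control lambda of the scan.
    """
    model = model or fit.model
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    gmap = gmap if gmap is not None else g.gmap
    sub = g.take_accessions(fit.accessions)
    x = sub.dosage_float()
    mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), mean[None, :], x)

    n, p = fit.x.shape
    w = 1.0 / (fit.sigma2_g * fit.eigvals + fit.sigma2_e)
    sw = np.sqrt(w)
    yt = sw * (fit.eigvecs.T @ fit.y)
    xt = sw[:, None] * (fit.eigvecs.T @ fit.x)
    gt = sw[:, None] * (fit.eigvecs.T @ x)

    # project out the fixed-effect design
    q, _ = np.linalg.qr(xt)
    y_r = yt - q @ (q.T @ yt)
    g_r = gt - q @ (q.T @ gt)

    gg = (g_r * g_r).sum(axis=0)
    gy = g_r.T @ y_r
    yy = float(y_r @ y_r)
    df = n - p - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = gy / gg
        rss = yy - beta * gy
        se2 = rss / df / gg
        tstat = beta / np.sqrt(se2)
    tol = 1e-10 * max(float(np.nanmax(gg)), 1.0)
    collinear = gg <= tol
    beta = np.where(collinear, np.nan, beta)
    tstat = np.where(collinear, np.nan, tstat)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals = np.where(collinear, np.nan, pvals)

    out = pd.DataFrame(
        {
            "marker_id": sub.marker_ids,
            "effect": beta,
            "se": np.where(collinear, np.nan, np.sqrt(se2)),
            "p": pvals,
            "note": np.where(collinear, "collinear", ""),
        }
    )
    if gmap is not None:
        out.insert(1, "lg", gmap.groups(sub.marker_ids))
        out.insert(2, "position_cM", gmap.positions(sub.marker_ids))
    lam = genomic_lambda(out["p"].dropna().to_numpy())
    return out, lam


@dataclass
class SignificanceThreshold:
    """Effective-number-of-tests threshold p* = alpha / Meff_total."""

    alpha: float
    c: float
    meff_per_group: dict[int, int]
    meff_total: int
    p_star: float


def simpleM_threshold(
    g: GenotypeMatrix,
    gmap: GeneticMap | None = None,
    alpha: float = 0.05,
    c: float = 0.995,
) -> SignificanceThreshold:
    """Effective number of independent tests from per-linkage-group
    eigenvalue sums of the marker dosage-correlation matrix.

    Meff per group is the smallest k such that the top-k eigenvalues
    account for at least fraction ``c`` of their sum; a single-marker (or
    all-constant) group contributes 1.  p* = alpha / sum(Meff).
    """
    if not 0 < c <= 1:
        raise ValueError("C must be in (0, 1]")
    gmap = gmap if gmap is not None else g.gmap
    if gmap is None:
        raise ValueError("a genetic map is required")
    x = g.dosage_float()
    mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), mean[None, :], x)
    lg = gmap.groups(g.marker_ids)
    meff: dict[int, int] = {}
    for group in sorted(set(lg.tolist())):
        cols = np.flatnonzero(lg == group)
        block = x[:, cols]
        sd = block.std(axis=0)
        block = block[:, sd > 0]
        if block.shape[1] <= 1:
            meff[group] = 1
            continue
        corr = np.corrcoef(block, rowvar=False)
        evals = np.linalg.eigvalsh(corr)[::-1]
        evals = np.maximum(evals, 0.0)
        frac = np.cumsum(evals) / evals.sum()
        meff[group] = int(np.searchsorted(frac, c) + 1)
    total = int(sum(meff.values()))
    return SignificanceThreshold(alpha, c, meff, total, alpha / total)


def genomic_lambda(pvals: np.ndarray) -> float:
    """Genomic-control inflation factor: median observed 1-df chi-square
    quantile divided by its null median (0.4549...)."""
    pvals = np.asarray(pvals, dtype=float)
    pvals = pvals[~np.isnan(pvals)]
    if pvals.size == 0:
        return np.nan
    chi = stats.chi2.isf(pvals, df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))


def qq_data(pvals: np.ndarray) -> tuple[pd.DataFrame, float]:
    """Observed vs expected -log10 p quantiles plus lambda.

    Expected quantiles are uniform order statistics i/(m+1).  P-values
    must lie in (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    obs = np.sort(p)
    m = p.size
    expected = np.arange(1, m + 1) / (m + 1.0)
    frame = pd.DataFrame({
        "expected_neglog10": -np.log10(expected),
        "observed_neglog10": -np.log10(obs),
    })
    return frame, genomic_lambda(p)
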