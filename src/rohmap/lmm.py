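"""Univariate linear-mixed-model association scan with a GRM random effect.

Model: y = W alpha + x beta + g + e, with g ~ N(0, lambda tau^-1 G) and
e ~ N(0, tau^-1 I); the case/control status is analyzed as a quantitative
0/1 trait. The variance ratio lambda is estimated once by REML under the
null (no SNP) using the eigendecomposition of G, then each SNP's effect is
the GLS estimate in the rotated (eigen) basis, with a two-sided Wald test
against F(1, n - c - 1).

The restricted log-likelihood for a given lambda is, up to a constant,
l_R = -1/2 [ log|V| + log|X' V^-1 X| + (n - c) log(y' P y) ] with
V = lambda G + I; it is maximized by a coarse grid on log10(lambda) in
[-5, 5] followed by bounded Brent refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import MISSING, GenotypeMatrix
from .qc import allele_frequencies


@dataclass
class ScanFilterParams:
    """Pre-scan SNP filters (emulating the common mixed-model tool defaults)."""

    maf_min: float = 0.01
    max_missing: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min <= 1 and 0 <= self.max_missing <= 1):
            raise ValueError("scan filter parameters must be in [0, 1]")


def grm_eigen(G: np.ndarray, tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the GRM; raises if meaningfully non-PSD."""
    G = np.asarray(G, dtype=float)
    s, U = np.linalg.eigh(G)
    if s.min() < -tol * max(1.0, s.max()):
        raise ValueError("GRM is not positive semidefinite beyond tolerance; "
                         "consider adding a small diagonal jitter")
    return np.clip(s, 0.0, None), U


def _reml_loglik(log10_lam: float, s: np.ndarray, Wt: np.ndarray,
                 yt: np.ndarray) -> float:
    lam = 10.0 ** log10_lam
    d = lam * s + 1.0
    n, c = Wt.shape
    Wd = Wt / d[:, None]
    XtVX = Wt.T @ Wd
    XtVy = Wd.T @ yt
    beta = np.linalg.solve(XtVX, XtVy)
    ypy = float(yt @ (yt / d) - XtVy @ beta)
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    if sign <= 0 or ypy <= 0:
        return -np.inf
    return -0.5 * (np.log(d).sum() + logdet_xvx + (n - c) * np.log(ypy))


def reml_lambda(y: np.ndarray, covariates: np.ndarray | None,
                grm_eigenpair: tuple[np.ndarray, np.ndarray],
                grid_points: int = 21,
                log10_bounds: tuple[float, float] = (-5.0, 5.0),
                ) -> float:
    """REML estimate of the genetic-to-residual variance ratio lambda.

    ``covariates`` defaults to an intercept. The returned value may sit at a
    search bound when the data carry no (or overwhelming) genetic signal.
    """
    s, U = grm_eigenpair
    y = np.asarray(y, dtype=float)
    n = len(y)
    W = np.ones((n, 1)) if covariates is None else np.asarray(covariates, float)
    yt = U.T @ y
    Wt = U.T @ W
    grid = np.linspace(log10_bounds[0], log10_bounds[1], grid_points)
    ll = np.array([_reml_loglik(g, s, Wt, yt) for g in grid])
    # ties within numerical noise resolve toward the smallest lambda, so a
    # flat profile (no genetic variance) lands on the lower search bound
    tol = 1e-8 * max(1.0, abs(float(ll.max())))
    k = int(np.flatnonzero(ll >= ll.max() - tol)[0])
    lo = grid[max(0, k - 1)]
    hi = grid[min(len(grid) - 1, k + 1)]
    if lo == hi:
        return float(10.0 ** grid[k])
    res = optimize.minimize_scalar(lambda g: -_reml_loglik(g, s, Wt, yt),
                                   bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-6})
    best = res.x if -res.fun > ll[k] + tol else grid[k]
    return float(10.0 ** best)


def restricted_loglik(lam: float, y: np.ndarray, covariates: np.ndarray | None,
                      grm_eigenpair: tuple[np.ndarray, np.ndarray]) -> float:
    """Restricted log-likelihood at a given lambda (for optimality audits)."""
    s, U = grm_eigenpair
    y = np.asarray(y, dtype=float)
    W = np.ones((len(y), 1)) if covariates is None else np.asarray(covariates, float)
    return _reml_loglik(np.log10(lam), s, U.T @ W, U.T @ y)


def scan_filter_mask(gm: GenotypeMatrix, params: ScanFilterParams,
                     ) -> np.ndarray:
    miss = (gm.dosage == MISSING).mean(axis=0)
    p = allele_frequencies(gm.dosage)
    maf = np.where(np.isnan(p), 0.0, np.minimum(p, 1 - p))
    return (maf >= params.maf_min) & (miss <= params.max_missing)


def lmm_scan(gm: GenotypeMatrix, status: np.ndarray | None = None,
             grm: np.ndarray | None = None,
             scan_filter: ScanFilterParams | None = None,
             covariates: np.ndarray | None = None,
             lambda_override: float | None = None,
             per_snp_lambda: bool = False) -> pd.DataFrame:
    """Mixed-model association scan over every SNP passing the scan filter.

    ``status`` defaults to the 0/1 affection coding from the sample metadata
    (samples with unknown status or flagged excluded are dropped). Returns a
    table with chrom, pos, ref, alt, maf, beta, se, wald_stat, p_value,
    minus_log10_p, lambda_hat, and a ``flag`` column marking degenerate SNPs
    (zero variance after rotation; reported with p = 1).
    """
    if scan_filter is None:
        scan_filter = ScanFilterParams()
    if status is None:
        known = gm.samples["status"].isin(["affected", "unaffected"]).to_numpy()
        keep = known & ~gm.samples["excluded"].to_numpy()
        gm = gm.subset(sample_mask=keep)
        status = (gm.samples["status"] == "affected").to_numpy(dtype=float)
    y = np.asarray(status, dtype=float)
    n = gm.n_samples
    if grm is None:
        from .qc import grm_standardized
        grm = grm_standardized(gm)
    s, U = grm_eigen(grm)

    vmask = scan_filter_mask(gm, scan_filter)
    W = np.ones((n, 1)) if covariates is None else np.asarray(covariates, float)
    c = W.shape[1]
    if lambda_override is not None:
        lam = float(lambda_override)
    else:
        lam = reml_lambda(y, W, (s, U))

    # mean-impute missing dosages, rotate everything once
    d = gm.dosage[:, vmask].astype(float)
    obs = gm.dosage[:, vmask] != MISSING
    mean = np.where(obs, d, 0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    d = np.where(obs, d, mean[None, :])
    p = allele_frequencies(gm.dosage[:, vmask])
    maf = np.minimum(p, 1 - p)

    yt = U.T @ y
    Wt = U.T @ W
    Xt = U.T @ d

    if per_snp_lambda:
        lam_vec = np.empty(Xt.shape[1])
        for j in range(Xt.shape[1]):
            lam_vec[j] = reml_lambda(y, np.column_stack([W, d[:, j]]), (s, U))
    else:
        lam_vec = None

    beta = np.empty(Xt.shape[1])
    se = np.empty(Xt.shape[1])
    flag = np.zeros(Xt.shape[1], dtype=bool)
    df2 = n - c - 1
    if c == 1:  # vectorized closed form for the intercept-only design
        lams = lam_vec if per_snp_lambda else np.full(Xt.shape[1], lam)
        for start in range(0, Xt.shape[1], 2048):
            sl = slice(start, min(start + 2048, Xt.shape[1]))
            dvec = lams[sl][None, :] * s[:, None] + 1.0
            wt = Wt[:, 0][:, None] / dvec
            a11 = (Wt[:, 0][:, None] * wt).sum(axis=0)
            a12 = (Xt[:, sl] * wt).sum(axis=0)
            a22 = (Xt[:, sl] ** 2 / dvec).sum(axis=0)
            b1 = (yt[:, None] * wt).sum(axis=0)
            b2 = (Xt[:, sl] * yt[:, None] / dvec).sum(axis=0)
            yy = (yt[:, None] ** 2 / dvec).sum(axis=0)
            det = a11 * a22 - a12 ** 2
            bad = det <= np.finfo(float).eps * a11 * np.maximum(a22, 1.0)
            det_safe = np.where(bad, 1.0, det)
            b_int = (a22 * b1 - a12 * b2) / det_safe
            b_snp = (a11 * b2 - a12 * b1) / det_safe
            rss = np.clip(yy - b_int * b1 - b_snp * b2, 0.0, None)
            sigma2 = rss / df2
            var = sigma2 * a11 / det_safe
            beta[sl] = np.where(bad, 0.0, b_snp)
            se[sl] = np.where(bad | (var <= 0), np.nan, np.sqrt(var))
            flag[sl] = bad | (var <= 0)
    else:
        for j in range(Xt.shape[1]):
            lj = lam_vec[j] if per_snp_lambda else lam
            dvec = lj * s + 1.0
            X = np.column_stack([Wt, Xt[:, j]])
            Xd = X / dvec[:, None]
            A = X.T @ Xd
            b = Xd.T @ yt
            try:
                coef = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                beta[j], se[j], flag[j] = 0.0, np.nan, True
                continue
            rss = max(float(yt @ (yt / dvec) - b @ coef), 0.0)
            Ainv = np.linalg.inv(A)
            var = rss / df2 * Ainv[-1, -1]
            beta[j] = coef[-1]
            se[j] = np.sqrt(var) if var > 0 else np.nan
            flag[j] = var <= 0

    wald = np.where(flag, 0.0, (beta / np.where(flag, 1.0, se)) ** 2)
    pval = np.where(flag, 1.0, stats.f.sf(wald, 1, df2))
    out = gm.variants.loc[vmask, ["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    out["maf"] = maf
    out["beta"] = beta
    out["se"] = se
    out["wald_stat"] = wald
    out["p_value"] = pval
    out["minus_log10_p"] = -np.log10(np.clip(pval, 1e-300, None))
    out["lambda_hat"] = lam_vec if per_snp_lambda else lam
    out["flag"] = flag
    out.attrs["n_snps_discarded"] = int((~vmask).sum())
    out.attrs["lambda_hat"] = None if per_snp_lambda else lam
    return out


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Genome-wide significance threshold on the -log10 scale: -log10(alpha/m)."""
    if not 0 < alpha < 1 and alpha != 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(-np.log10(alpha / m))


def qq_data(p_values: np.ndarray) -> tuple[pd.DataFrame, float]:
    """Observed vs expected -log10(p) quantiles plus the genomic inflation factor.

    The inflation factor is the median of the chi-square(1) quantiles implied
    by the p-values divided by the theoretical null median 0.4549.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    obs = np.sort(p)
    n = len(obs)
    expected = (np.arange(1, n + 1) - 0.5) / n
    chi = stats.chi2.isf(obs, df=1)
    gif = float(np.median(chi) / stats.chi2.ppf(0.5, df=1))
    frame = pd.DataFrame({"expected_minus_log10": -np.log10(expected),
                          "observed_minus_log10": -np.log10(obs)})
    return frame, gif
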