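"""Genotype QC, homozygote-excess inbreeding, PCA, and the standardized GRM.

QC mirrors the usual array workflow for a small case/control cohort: drop
variants with minor allele frequency at or below 0.05 or with a per-variant
missing-call rate above 0.1, then drop samples with a per-individual missing
rate above 0.1. The inbreeding coefficient is the method-of-moments
homozygote excess F = (O - E) / (m - E), with the expected homozygous count
per sample computed from cohort allele frequencies using the small-sample
correction n/(n-1). PCA and the standardized genomic relationship matrix
operate on mean-imputed, variance-standardized dosages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class QCParams:
    maf_min: float = 0.05               # keep MAF strictly greater
    max_variant_missing: float = 0.1
    max_sample_missing: float = 0.1

    def __post_init__(self) -> None:
        for name in ("maf_min", "max_variant_missing", "max_sample_missing"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def allele_frequencies(dosage: np.ndarray) -> np.ndarray:
    """Alternative-allele frequency per variant from non-missing calls."""
    obs = dosage != MISSING
    n = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(obs, dosage, 0).sum(axis=0) / np.maximum(2 * n, 1)
    p[n == 0] = np.nan
    return p


def qc_filter(gm: GenotypeMatrix, params: QCParams | None = None,
              ) -> tuple[GenotypeMatrix, dict]:
    """Apply variant-level then sample-level QC; returns (filtered, report)."""
    if params is None:
        params = QCParams()
    if gm.n_variants == 0:
        raise ValueError("empty genotype matrix")
    obs = gm.dosage != MISSING
    vmiss = 1.0 - obs.mean(axis=0)
    p = allele_frequencies(gm.dosage)
    maf = np.minimum(p, 1 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)

    maf_fail = maf <= params.maf_min
    miss_fail = vmiss > params.max_variant_missing
    vkeep = ~(maf_fail | miss_fail)
    report = {
        "variants_in": gm.n_variants,
        "removed_maf": int((maf_fail & ~miss_fail).sum()),
        "removed_variant_missing": int(miss_fail.sum()),
        "variants_out": int(vkeep.sum()),
    }
    if not vkeep.any():
        err = ValueError("all variants removed by QC")
        err.report = report  # type: ignore[attr-defined]
        raise err

    d2 = gm.dosage[:, vkeep]
    smiss = 1.0 - (d2 != MISSING).mean(axis=1)
    skeep = smiss <= params.max_sample_missing
    report["samples_in"] = gm.n_samples
    report["removed_sample_missing"] = int((~skeep).sum())
    report["samples_out"] = int(skeep.sum())
    return gm.subset(sample_mask=skeep, variant_mask=vkeep), report


# ---------------------------------------------------------------------------
# inbreeding
# ---------------------------------------------------------------------------

def inbreeding_f(gm: GenotypeMatrix, freq_samples: np.ndarray | None = None,
                 ) -> pd.DataFrame:
    """Homozygote-excess inbreeding coefficient per sample.

    For each sample, over its non-missing variants i (with at least two
    genotyped samples): E = sum_i [1 - 2 p_i (1 - p_i) n_i / (n_i - 1)],
    O = observed homozygous count, F = (O - E) / (m_used - E). Allele
    frequencies come from the whole cohort unless ``freq_samples`` restricts
    the rows used (e.g. controls only).

    Returns a DataFrame with sample_id, observed_hom, expected_hom, m_used, F.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples to estimate allele frequencies")
    dref = gm.dosage if freq_samples is None else gm.dosage[freq_samples]
    obs_ref = dref != MISSING
    n_i = obs_ref.sum(axis=0)
    p = allele_frequencies(dref)
    with np.errstate(invalid="ignore", divide="ignore"):
        exp_hom_i = 1.0 - 2.0 * p * (1 - p) * n_i / (n_i - 1)
    usable = n_i >= 2

    obs = gm.dosage != MISSING
    use = obs & usable[None, :]
    hom = (gm.dosage == 0) | (gm.dosage == 2)
    O = (hom & use).sum(axis=1).astype(float)
    E = np.where(use, exp_hom_i[None, :], 0.0).sum(axis=1)
    m_used = use.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (O - E) / (m_used - E)
    return pd.DataFrame({
        "sample_id": gm.sample_ids,
        "observed_hom": O.astype(int),
        "expected_hom": E,
        "m_used": m_used.astype(int),
        "F": F,
    })


def compare_group_f(f_table: pd.DataFrame, samples: pd.DataFrame) -> dict:
    """Welch two-sample comparison of F between affected and unaffected.

    Convenience wrapper around standard statistics (mirrors the usual report
    of higher inbreeding in affected animals); not a contribution.
    """
    merged = f_table.merge(samples, on="sample_id")
    merged = merged[~merged["excluded"]]
    a = merged.loc[merged["status"] == "affected", "F"].to_numpy()
    u = merged.loc[merged["status"] == "unaffected", "F"].to_numpy()
    t, p = stats.ttest_ind(a, u, equal_var=False)
    return {"mean_f_affected": float(np.mean(a)), "mean_f_unaffected": float(np.mean(u)),
            "welch_t": float(t), "welch_p": float(p)}


# ---------------------------------------------------------------------------
# PCA and GRM
# ---------------------------------------------------------------------------

def _standardized(dosage: np.ndarray, min_var: float = 1e-12,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute MISSING, center, scale to unit variance; returns (Z, kept)."""
    d = dosage.astype(float)
    obs = dosage != MISSING
    mean = np.where(obs, d, 0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    d = np.where(obs, d, mean[None, :])
    d -= mean[None, :]
    sd = d.std(axis=0)
    kept = sd > min_var
    return d[:, kept] / sd[kept][None, :], kept


def pca_scores(gm: GenotypeMatrix, k: int = 2) -> pd.DataFrame:
    """Sample scores on the top-k principal axes of standardized dosages.

    Computed by SVD of the standardized matrix (numerically equivalent to an
    eigendecomposition of the sample covariance). The sign of each axis is
    fixed by making its largest-magnitude variant loading positive.
    """
    Z, _ = _standardized(gm.dosage)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int((s > s[0] * 1e-9).sum()) if len(s) else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank}")
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            U[:, j] *= -1
            Vt[j] *= -1
    scores = U[:, :k] * s[:k]
    return pd.DataFrame(scores, columns=[f"PC{j+1}" for j in range(k)],
                        index=pd.Index(gm.sample_ids, name="sample_id")).reset_index()


def grm_standardized(gm: GenotypeMatrix) -> np.ndarray:
    """Standardized genomic relationship matrix.

    G = (1/m) sum_i (x_i - 2 p_i)(x_i - 2 p_i)^T / (2 p_i (1 - p_i)), with
    MISSING imputed to 2 p_i. Monomorphic variants cannot be standardized and
    are skipped with a warning.
    """
    p = allele_frequencies(gm.dosage)
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if (~poly).any():
        warnings.warn(f"skipping {int((~poly).sum())} monomorphic variants "
                      "in GRM", stacklevel=2)
    if not poly.any():
        raise ValueError("no polymorphic variants for GRM")
    d = gm.dosage[:, poly].astype(float)
    pp = p[poly]
    obs = gm.dosage[:, poly] != MISSING
    d = np.where(obs, d, 2 * pp[None, :])
    X = (d - 2 * pp[None, :]) / np.sqrt(2 * pp * (1 - pp))[None, :]
    return X @ X.T / X.shape[1]
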