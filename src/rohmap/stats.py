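"""Genotype-by-status contingency statistics for validation cohorts.

Given genotype classes AA (homozygous alternative), AR (heterozygous) and
RR (homozygous reference) crossed with affection status, this module
computes relative risks between genotype classes (with a Yates-corrected
chi-square p-value on the corresponding 2x2 subtable), Pearson/Yates
chi-square tests, exact tests (hypergeometric for 2x2; Freeman–Halton full
enumeration over fixed margins for R x C, with a seeded Monte Carlo fallback
for tables too large to enumerate), allele frequencies from genotype counts,
and the headline cohort percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .genotype_io import MISSING

GENOTYPE_CLASSES = ("AA", "AR", "RR")
_DOSAGE_CLASS = {2: "AA", 1: "AR", 0: "RR"}


@dataclass(frozen=True)
class RiskEstimate:
    rr: float
    exposed_genotype: str
    reference_genotype: str
    p_value: float
    test_name: str
    ci_low: float | None = None
    ci_high: float | None = None


def genotype_status_table(dosages: np.ndarray, status: np.ndarray,
                          ) -> pd.DataFrame:
    """3x2 genotype-class by affection-status counts; MISSING calls dropped."""
    d = np.asarray(dosages)
    st = np.asarray(status)
    keep = (d != MISSING) & np.isin(st, ["affected", "unaffected"])
    if not keep.any():
        raise ValueError("no usable genotype/status pairs")
    table = pd.DataFrame(0, index=list(GENOTYPE_CLASSES),
                         columns=["affected", "unaffected"])
    for dose, s in zip(d[keep], st[keep]):
        table.loc[_DOSAGE_CLASS[int(dose)], s] += 1
    return table


def chi2_test(table, yates: bool = True) -> tuple[float, float]:
    """Pearson chi-square test of independence; Yates correction on 2x2.

    The 2x2 Yates statistic is n (|ad - bc| - n/2)^2 / (r1 r2 c1 c2),
    clamped at zero when |ad - bc| < n/2.
    """
    t = np.asarray(table, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero marginal")
    correction = bool(yates) and t.shape == (2, 2)
    stat, p, _, _ = sps.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


def relative_risk(table: pd.DataFrame, exposed: str = "AA",
                  reference: str = "RR", with_ci: bool = False,
                  ) -> RiskEstimate:
    """Relative risk of affection between two genotype classes.

    rr = [a / (a + b)] / [c / (c + d)] for exposed row (a, b) and reference
    row (c, d); the p-value is the Yates-corrected chi-square on that 2x2.
    """
    a, b = float(table.loc[exposed, "affected"]), float(table.loc[exposed, "unaffected"])
    c, d = float(table.loc[reference, "affected"]), float(table.loc[reference, "unaffected"])
    if a + b == 0:
        raise ValueError("exposed row is empty")
    if c + d == 0:
        raise ValueError("reference row is empty")
    if c == 0:
        rr = float("inf")
    else:
        rr = (a / (a + b)) / (c / (c + d))
    try:
        _, p = chi2_test([[a, b], [c, d]], yates=True)
    except ValueError:
        p = float("nan")
    ci_low = ci_high = None
    if with_ci and 0 < rr < np.inf and a > 0 and c > 0:
        se = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
        ci_low = float(rr * np.exp(-1.959963984540054 * se))
        ci_high = float(rr * np.exp(1.959963984540054 * se))
    return RiskEstimate(rr, exposed, reference, p, "chi2_yates", ci_low, ci_high)


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

def _log_table_prob(t: np.ndarray, row: np.ndarray, col: np.ndarray,
                    n: float) -> float:
    return (gammaln(row + 1).sum() + gammaln(col + 1).sum()
            - gammaln(n + 1) - gammaln(t + 1).sum())


def _enumerate_exact(observed: np.ndarray, max_tables: float) -> float:
    """Freeman–Halton two-sided exact p by full enumeration over fixed margins."""
    obs = np.asarray(observed, dtype=np.int64)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    R, C = obs.shape
    # crude bound on the enumeration size
    est = 1.0
    for i in range(R - 1):
        for j in range(C - 1):
            est *= min(row[i], col[j]) + 1
    if est > max_tables:
        raise ValueError(f"enumeration would visit ~{est:.2g} tables "
                         f"(> {max_tables:.2g}); use monte_carlo=True")
    log_p_obs = _log_table_prob(obs, row, col, n)
    total = 0.0

    cells = np.zeros((R, C), dtype=np.int64)

    def fill(i: int, j: int, row_rem: np.ndarray, col_rem: np.ndarray) -> None:
        nonlocal total
        if i == R - 1:
            # last row forced by column margins
            if (col_rem < 0).any():
                return
            cells[i] = col_rem
            lp = _log_table_prob(cells, row, col, n)
            if lp <= log_p_obs + 1e-7:
                total += np.exp(lp)
            return
        if j == C - 1:
            if row_rem[i] > col_rem[j]:
                return
            cells[i, j] = row_rem[i]
            nc = col_rem.copy()
            nc[j] -= row_rem[i]
            fill(i + 1, 0, row_rem, nc)
            return
        hi = min(row_rem[i], col_rem[j])
        for v in range(hi + 1):
            cells[i, j] = v
            nr = row_rem.copy()
            nr[i] -= v
            nc = col_rem.copy()
            nc[j] -= v
            fill(i, j + 1, nr, nc)

    fill(0, 0, row.copy(), col.copy())
    return min(1.0, float(total))


def _monte_carlo_exact(observed: np.ndarray, n_draws: int,
                       seed: int) -> float:
    """Seeded Monte Carlo estimate of the Freeman–Halton p-value."""
    obs = np.asarray(observed, dtype=np.int64)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = int(obs.sum())
    log_p_obs = _log_table_prob(obs, row, col, n)
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(col)), col)
    starts = np.concatenate([[0], np.cumsum(row)])
    hits = 0
    for _ in range(n_draws):
        rng.shuffle(labels)
        t = np.stack([np.bincount(labels[starts[i]:starts[i + 1]],
                                  minlength=len(col))
                      for i in range(len(row))])
        if _log_table_prob(t, row, col, n) <= log_p_obs + 1e-7:
            hits += 1
    return (hits + 1) / (n_draws + 1)


def fisher_exact(table, max_tables: float = 1e7, monte_carlo: bool = False,
                 n_draws: int = 100_000, seed: int = 0) -> float:
    """Two-sided exact test of independence for an R x C table.

    2x2 tables use the hypergeometric test; larger tables use Freeman–Halton
    full enumeration (probability-at-most-observed rule) when the number of
    tables over the fixed margins is tractable, otherwise a seeded Monte
    Carlo estimate when ``monte_carlo`` is set.
    """
    t = np.asarray(table, dtype=np.int64)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.shape == (2, 2):
        return float(sps.fisher_exact(t, alternative="two-sided")[1])
    if monte_carlo:
        return _monte_carlo_exact(t, n_draws, seed)
    return _enumerate_exact(t, max_tables)


def freeman_halton(table, max_tables: float = 1e7) -> float:
    """Freeman–Halton enumeration path exposed for any R x C (including 2x2)."""
    return _enumerate_exact(np.asarray(table, dtype=np.int64), max_tables)


# ---------------------------------------------------------------------------
# frequencies and percentages
# ---------------------------------------------------------------------------

def allele_freq_from_counts(hom_alt: int, het: int, hom_ref: int) -> float:
    """Alternative-allele frequency from genotype counts."""
    total = hom_alt + het + hom_ref
    if total < 1:
        raise ValueError("genotype counts sum to zero")
    return (2 * hom_alt + het) / (2 * total)


def cohort_percentages(table: pd.DataFrame) -> dict:
    """Headline proportions from a 3x2 genotype-by-status table.

    Returns the fraction of cases homozygous-alternative, the fraction of
    homozygous-alternative individuals affected, and the fraction of
    controls homozygous-alternative, each raw and at integer percent
    (None/flagged when a denominator is zero).
    """
    a_aa = float(table.loc["AA", "affected"])
    u_aa = float(table.loc["AA", "unaffected"])
    n_cases = float(table["affected"].sum())
    n_controls = float(table["unaffected"].sum())
    n_hom = a_aa + u_aa

    def frac(num, den):
        return None if den == 0 else num / den

    out = {
        "cases_homozygous": frac(a_aa, n_cases),
        "homozygotes_affected": frac(a_aa, n_hom),
        "controls_homozygous": frac(u_aa, n_controls),
    }
    out.update({f"{k}_pct": (None if v is None else round(100 * v))
                for k, v in list(out.items())})
    return out
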