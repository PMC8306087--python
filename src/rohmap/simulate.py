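"""Gene-drop simulation of an inbred pedigree with a planted recessive variant.

The generator emulates the data situation of a recessive-disease mapping
study in a heavily inbred dog population: a *case line* founded by a single
pair and propagated by full-sib matings (pedigree inbreeding reaches 0.5
after four generations), into which one founder haplotype carries a novel
causal allele, and a *control line* of crossed founders without recent
inbreeding. Line allele frequencies drift from a shared ancestral frequency
under a Balding–Nichols model, which reproduces the breed-level homozygote
excess (F on the 0.5 scale when measured against cohort frequencies) without
creating long recent-IBD segments in controls.

Affected individuals are the homozygous carriers of the causal allele
(configurable penetrance and phenocopy rate). The module emits an
array-density panel, a WGS-density panel, and a variant annotation table
with pathogenicity scores and reference-panel genotype counts, including
common "decoy" variants that segregate perfectly with the causal one but are
frequent in the reference panel, and therefore must be removed by the
allele-frequency filter rather than by segregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SiteQuality, VariantKey, \
    make_variants_frame

__all__ = [
    "SimConfig", "Individual", "Pedigree", "ConfigError",
    "simulate_pedigree", "pedigree_inbreeding", "gene_drop",
    "assign_phenotypes", "emit_panels", "simulate_dataset", "SimResult",
    "transmission_audit",
]


class ConfigError(ValueError):
    """Invalid or infeasible simulation configuration."""


# causal-variant annotation constants (deleterious consensus across tools)
_CAUSAL_SCORES = dict(sift=0.0, provean=-6.775, panther_psep=0.89, polyphen2=0.999)
# linked missense with a discordant score profile (deleterious by SIFT only)
_BENIGN_MISSENSE_SCORES = dict(sift=0.0, provean=-1.901, panther_psep=0.27,
                               polyphen2=0.337)


@dataclass
class SimConfig:
    """Parameters of the synthetic study population.

    The defaults define the reference study conditions: a one-chromosome
    genome of 50 Mb at 1 cM/Mb, a case line of full-sib matings for four
    generations (pedigree F = 0.5), a recessive causal variant at 8 Mb
    carried by one founder haplotype with full penetrance, ~20 sampled cases
    and 20 controls, a 2,500-SNP array panel and a 5,000-variant WGS panel.
    """

    # pedigree
    n_founders: int = 2                 # case-line founders (pairs)
    n_generations: int = 4              # case-line inbred generations
    mating_scheme: str = "full_sib"     # full_sib | half_sib | small_sire_pool
    sire_pool_k: int = 2
    branch_factor: int = 3              # sib pairs formed per litter
    litter_size: int = 6
    control_founders: int = 4
    control_generations: int = 2
    control_litter: int = 8
    # genome
    chromosome: str = "chr17"
    chromosome_length_bp: int = 50_000_000
    cm_per_mb: float = 1.0
    n_array_snps: int = 2_500
    n_wgs_variants: int = 5_000
    # causal variant and phenotype model
    causal_position: int = 8_000_000
    causal_founder_copies: int = 1
    penetrance: float = 1.0
    phenocopy_rate: float = 0.0
    # founder allele frequencies
    founder_maf_low: float = 0.05
    founder_maf_high: float = 0.5
    line_fst: float = 0.5               # Balding–Nichols drift per line
    # annotation decoys / linked variants
    n_decoys: int = 5                   # common-in-panel, case-private
    n_linked_rare: int = 3              # rare intronic hitchhikers
    n_svs: int = 3
    panel_size: int = 722               # reference-panel dog count
    # panels and cohort; a few controls are unaffected relatives from the
    # case line (real cohorts include them, and they break the otherwise
    # perfect confounding of status with population structure)
    array_missing_rate: float = 0.01
    n_cases: int = 20
    n_controls: int = 20
    n_related_controls: int = 5
    # ascertainment: a mapping study exists only where the disease segregates,
    # so gene drops are redrawn (deterministically) until enough affected
    # final-generation individuals exist
    min_cases: int = 5
    max_ascertainment_attempts: int = 30
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.penetrance <= 1 and 0 <= self.phenocopy_rate <= 1):
            raise ConfigError("penetrance and phenocopy_rate must be in [0, 1]")
        if not (1 <= self.causal_position <= self.chromosome_length_bp):
            raise ConfigError("causal_position outside chromosome")
        if self.n_array_snps > self.n_wgs_variants:
            raise ConfigError("n_array_snps exceeds n_wgs_variants")
        if self.mating_scheme not in ("full_sib", "half_sib", "small_sire_pool"):
            raise ConfigError(f"unknown mating scheme {self.mating_scheme!r}")
        if self.mating_scheme == "full_sib" and self.n_founders < 2:
            raise ConfigError("full-sib scheme needs at least 2 founders")
        if self.litter_size < 2 * self.branch_factor:
            raise ConfigError("litter_size must be >= 2 * branch_factor")
        if not (0 <= self.founder_maf_low <= self.founder_maf_high <= 0.5):
            raise ConfigError("founder MAF bounds must satisfy 0 <= low <= high <= 0.5")
        if self.causal_founder_copies < 1 or \
                self.causal_founder_copies > self.n_founders * 2:
            raise ConfigError("causal_founder_copies outside founder haplotype count")
        if self.cm_per_mb < 0:
            raise ConfigError("cm_per_mb must be non-negative")


@dataclass(frozen=True)
class Individual:
    id: str
    sire: str | None
    dam: str | None
    generation: int
    line: str  # "case" or "control"

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None


@dataclass
class Pedigree:
    individuals: list[Individual]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ind in self.individuals:
            for p in (ind.sire, ind.dam):
                if p is not None and p not in seen:
                    raise ValueError(f"parent {p} of {ind.id} not defined earlier")
            if ind.id in seen:
                raise ValueError(f"duplicate individual id {ind.id}")
            seen.add(ind.id)

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def ids(self) -> list[str]:
        return [i.id for i in self.individuals]

    def index(self) -> dict[str, int]:
        return {ind.id: k for k, ind in enumerate(self.individuals)}

    def founders(self) -> list[Individual]:
        return [i for i in self.individuals if i.is_founder]

    def finals(self, line: str | None = None) -> list[Individual]:
        pool = [i for i in self.individuals if line is None or i.line == line]
        gmax = max(i.generation for i in pool)
        return [i for i in pool if i.generation == gmax]


def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None,
                      ) -> Pedigree:
    """Build the two-line study pedigree for the configured mating scheme."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng([config.seed, 11])
    inds: list[Individual] = []
    counter = [0]

    def new(sire, dam, gen, line) -> Individual:
        counter[0] += 1
        ind = Individual(f"{line[0].upper()}{counter[0]:04d}", sire, dam, gen, line)
        inds.append(ind)
        return ind

    # --- case line ---------------------------------------------------------
    founders = [new(None, None, 0, "case") for _ in range(config.n_founders)]
    pairs = [(founders[i].id, founders[i + 1].id)
             for i in range(0, config.n_founders - 1, 2)]
    for gen in range(1, config.n_generations + 1):
        litters: list[list[Individual]] = []
        for sire, dam in pairs:
            litters.append([new(sire, dam, gen, "case")
                            for _ in range(config.litter_size)])
        if gen == config.n_generations:
            break
        pairs = _form_pairs(config, litters, rng)
        if not pairs:
            raise ConfigError("mating scheme produced no pairs; "
                              "check litter_size/branch_factor")

    # --- control line: founder pairs, then crosses between litters ---------
    cfounders = [new(None, None, 0, "control")
                 for _ in range(config.control_founders)]
    litters = []
    for i in range(0, config.control_founders - 1, 2):
        litters.append([new(cfounders[i].id, cfounders[i + 1].id, 1, "control")
                        for _ in range(config.control_litter)])
    for gen in range(2, config.control_generations + 1):
        nxt: list[list[Individual]] = []
        k = len(litters)
        for a in range(k):
            b = (a + 1) % k  # cross litters so mates are unrelated when k > 1
            for j in range(2):
                sire = litters[a][2 * j].id
                dam = litters[b][2 * j + 1].id
                nxt.append([new(sire, dam, gen, "control")
                            for _ in range(config.control_litter)])
        litters = nxt
    return Pedigree(inds)


def _form_pairs(config: SimConfig, litters: list[list[Individual]],
                rng: np.random.Generator) -> list[tuple[str, str]]:
    scheme = config.mating_scheme
    pairs: list[tuple[str, str]] = []
    if scheme == "full_sib":
        for litter in litters:
            for b in range(config.branch_factor):
                pairs.append((litter[2 * b].id, litter[2 * b + 1].id))
    elif scheme == "half_sib":
        for litter in litters:
            sire = litter[0]
            for dam in litter[1:1 + config.branch_factor]:
                pairs.append((sire.id, dam.id))
    else:  # small_sire_pool
        flat = [i for litter in litters for i in litter]
        sires = list(rng.choice([i.id for i in flat],
                                size=min(config.sire_pool_k, len(flat)),
                                replace=False))
        dams = [i.id for i in flat if i.id not in sires]
        n_pairs = min(len(dams), config.branch_factor * len(litters))
        for dam in dams[:n_pairs]:
            pairs.append((str(rng.choice(sires)), dam))
    return pairs


def pedigree_inbreeding(ped: Pedigree) -> dict[str, float]:
    """Pedigree-expected inbreeding coefficients by the tabular method.

    Builds the additive relationship matrix A (parents before offspring) and
    returns F_i = A_ii - 1. Serves as the classical oracle for the realized
    autozygosity of gene-drop output: under repeated full-sib mating it
    follows F_t = 1/4 (1 + 2 F_{t-1} + F_{t-2}).
    """
    n = len(ped)
    idx = ped.index()
    A = np.zeros((n, n))
    for i, ind in enumerate(ped.individuals):
        if ind.is_founder:
            A[i, i] = 1.0
            continue
        s, d = idx[ind.sire], idx[ind.dam]
        A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
        A[:i, i] = A[i, :i]
        A[i, i] = 1.0 + 0.5 * A[s, d]
    return {ind.id: A[i, i] - 1.0 for i, ind in enumerate(ped.individuals)}


# ---------------------------------------------------------------------------
# gene drop
# ---------------------------------------------------------------------------

def _meiosis(parent: np.ndarray, positions: np.ndarray, length_bp: int,
             cm_per_mb: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete: crossovers as a Poisson process (Haldane, no interference)."""
    morgans = length_bp / 1e6 * cm_per_mb / 100.0
    k = rng.poisson(morgans) if morgans > 0 else 0
    start = int(rng.integers(2))
    if k == 0:
        return parent[start].copy()
    xos = np.sort(rng.uniform(0, length_bp, size=k))
    phase = (start + np.searchsorted(xos, positions)) % 2
    return np.where(phase == 0, parent[0], parent[1])


def gene_drop(pedigree: Pedigree, founder_haplotypes: np.ndarray,
              positions: np.ndarray, length_bp: int, cm_per_mb: float,
              rng: np.random.Generator) -> np.ndarray:
    """Drop founder haplotypes through the pedigree with recombination.

    ``founder_haplotypes`` has shape (2 * n_founders, n_variants); founders
    consume rows in pedigree order. Returns diploid haplotypes with shape
    (n_individuals, 2, n_variants).
    """
    idx = pedigree.index()
    m = founder_haplotypes.shape[1]
    out = np.zeros((len(pedigree), 2, m), dtype=np.int8)
    f = 0
    for i, ind in enumerate(pedigree.individuals):
        if ind.is_founder:
            out[i, 0] = founder_haplotypes[2 * f]
            out[i, 1] = founder_haplotypes[2 * f + 1]
            f += 1
        else:
            out[i, 0] = _meiosis(out[idx[ind.sire]], positions, length_bp,
                                 cm_per_mb, rng)
            out[i, 1] = _meiosis(out[idx[ind.dam]], positions, length_bp,
                                 cm_per_mb, rng)
    return out


def transmission_audit(pedigree: Pedigree, haps: np.ndarray) -> bool:
    """Check Mendelian consistency: each transmitted allele exists in the parent."""
    idx = pedigree.index()
    for i, ind in enumerate(pedigree.individuals):
        if ind.is_founder:
            continue
        for h, parent in ((0, ind.sire), (1, ind.dam)):
            p = haps[idx[parent]]
            ok = (haps[i, h] == p[0]) | (haps[i, h] == p[1])
            if not ok.all():
                return False
    return True


def assign_phenotypes(dosage_at_causal: np.ndarray, penetrance: float,
                      phenocopy_rate: float, rng: np.random.Generator,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Affection status from causal dosage under a recessive model.

    Homozygous-alternative individuals are affected with probability
    ``penetrance``; everyone else with probability ``phenocopy_rate``.
    Returns (status array of affected/unaffected, phenocopy mask).
    """
    d = np.asarray(dosage_at_causal)
    u = rng.random(d.shape)
    affected = np.where(d == 2, u < penetrance, u < phenocopy_rate)
    status = np.where(affected, "affected", "unaffected")
    phenocopy = affected & (d != 2)
    return status, phenocopy


# ---------------------------------------------------------------------------
# variant layout, annotation, panels
# ---------------------------------------------------------------------------

_NUCS = np.array(list("ACGT"))


@dataclass
class _VariantLayout:
    variants: pd.DataFrame          # sorted, includes SVs
    causal_idx: int
    decoy_idx: np.ndarray
    linked_rare_idx: np.ndarray
    benign_missense_idx: int
    sv_idx: np.ndarray              # all SV rows
    sv_private_idx: np.ndarray      # case-private SVs
    ancestral_p: np.ndarray


def _draw_positions(config: SimConfig, rng: np.random.Generator) -> _VariantLayout:
    L = config.chromosome_length_bp
    n_extra = config.n_svs
    pool = rng.choice(L, size=config.n_wgs_variants + n_extra + 50,
                      replace=False) + 1
    pool = pool[pool != config.causal_position]
    snv_pos = np.sort(pool[:config.n_wgs_variants - 1])
    # private SVs must sit inside the shared case haplotype around the
    # causal position; one extra SV is an ordinary polymorphism elsewhere
    n_priv_sv = max(0, n_extra - 1)
    lo = max(1, config.causal_position - 2_000_000)
    hi = min(L, config.causal_position + 2_000_000)
    sv_near = rng.choice(np.arange(lo, hi), size=n_priv_sv, replace=False)
    sv_far = pool[config.n_wgs_variants - 1:
                  config.n_wgs_variants - 1 + (n_extra - n_priv_sv)]
    sv_priv_pos = np.setdiff1d(sv_near, snv_pos)
    sv_pos = np.sort(np.concatenate([sv_priv_pos, sv_far]))

    positions = np.sort(np.concatenate([snv_pos, [config.causal_position], sv_pos]))
    m = len(positions)
    is_sv = np.isin(positions, sv_pos)
    causal_idx = int(np.searchsorted(positions, config.causal_position))

    refs = _NUCS[rng.integers(0, 4, size=m)]
    alts = np.array([_NUCS[(np.flatnonzero(_NUCS != r))[rng.integers(3)]]
                     for r in refs])
    sv_types = rng.choice(["<DEL>", "<INS>"], size=m)
    refs = np.where(is_sv, "N", refs)
    alts = np.where(is_sv, sv_types, alts)
    variants = make_variants_frame(config.chromosome, positions, refs, alts)

    # linked specials sit on the causal founder haplotype within +-1.5 Mb
    near = np.flatnonzero((np.abs(positions - config.causal_position) < 1_500_000)
                          & ~is_sv & (np.arange(m) != causal_idx))
    need = config.n_decoys + config.n_linked_rare + 1
    if len(near) < need:
        raise ConfigError("too few variants near the causal position; "
                          "increase n_wgs_variants")
    picked = rng.choice(near, size=need, replace=False)
    decoy_idx = np.sort(picked[:config.n_decoys])
    linked_rare_idx = np.sort(picked[config.n_decoys:config.n_decoys
                                     + config.n_linked_rare])
    benign_missense_idx = int(picked[-1])

    sv_idx = np.flatnonzero(is_sv)
    sv_private_idx = sv_idx[np.isin(positions[sv_idx], sv_priv_pos)]

    p_anc = rng.uniform(config.founder_maf_low, config.founder_maf_high, size=m)
    return _VariantLayout(variants, causal_idx, decoy_idx, linked_rare_idx,
                          benign_missense_idx, sv_idx, sv_private_idx, p_anc)


def _balding_nichols(p: np.ndarray, fst: float, rng: np.random.Generator,
                     ) -> np.ndarray:
    if fst <= 0:
        return p.copy()
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    return rng.beta(a, b)


def draw_founder_haplotypes(config: SimConfig, layout: _VariantLayout,
                            n_case_founders: int, n_control_founders: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Founder haplotypes: Balding–Nichols line frequencies around the
    ancestral frequency, with the causal allele and its linked specials
    placed on designated case-line founder haplotypes."""
    m = len(layout.ancestral_p)
    p_case = _balding_nichols(layout.ancestral_p, config.line_fst, rng)
    p_ctrl = _balding_nichols(layout.ancestral_p, config.line_fst, rng)
    hc = (rng.random((2 * n_case_founders, m)) < p_case).astype(np.int8)
    hk = (rng.random((2 * n_control_founders, m)) < p_ctrl).astype(np.int8)

    special = np.concatenate([[layout.causal_idx], layout.decoy_idx,
                              layout.linked_rare_idx,
                              [layout.benign_missense_idx],
                              layout.sv_private_idx]).astype(int)
    hc[:, special] = 0
    hk[:, special] = 0
    # the causal founder haplotype (row 0) carries every linked special allele
    hc[0, special] = 1
    for extra in range(1, config.causal_founder_copies):
        hc[extra, layout.causal_idx] = 1
    # non-private SVs are ordinary polymorphisms in both lines
    other_sv = np.setdiff1d(layout.sv_idx, layout.sv_private_idx)
    for j in other_sv:
        hc[:, j] = rng.random(hc.shape[0]) < 0.2
        hk[:, j] = rng.random(hk.shape[0]) < 0.2
    return np.vstack([hc, hk])


def _panel_counts(af: float, n: int, rng: np.random.Generator) -> tuple[int, int, int]:
    probs = [af ** 2, 2 * af * (1 - af), (1 - af) ** 2]
    hom_alt, het, hom_ref = rng.multinomial(n, probs)
    return int(hom_alt), int(het), int(hom_ref)


def _build_annotation(config: SimConfig, layout: _VariantLayout,
                      rng: np.random.Generator) -> pd.DataFrame:
    v = layout.variants
    m = len(v)
    consequence = np.array(rng.choice(
        ["intergenic", "intronic", "synonymous", "missense"], size=m,
        p=[0.55, 0.30, 0.08, 0.07]), dtype=object)
    gene = np.array([f"G{int(p // 3_500_000):02d}" for p in v["pos"]],
                    dtype=object)
    gene[consequence == "intergenic"] = None
    aa = np.array([None] * m, dtype=object)
    sift = np.full(m, np.nan)
    provean = np.full(m, np.nan)
    panther = np.full(m, np.nan)
    polyphen = np.full(m, np.nan)

    mis = np.flatnonzero(consequence == "missense")
    sift[mis] = rng.uniform(0.2, 1.0, size=len(mis))
    provean[mis] = rng.uniform(-1.5, 2.0, size=len(mis))
    panther[mis] = rng.uniform(0.0, 0.4, size=len(mis))
    polyphen[mis] = rng.uniform(0.0, 0.4, size=len(mis))
    for i in mis:
        aa[i] = f"{int(v['pos'].iat[i]) % 997}A>T"

    panel = np.empty((m, 3), dtype=float)
    for i in range(m):
        panel[i] = _panel_counts(float(layout.ancestral_p[i]),
                                 config.panel_size, rng)

    ci = layout.causal_idx
    consequence[ci], gene[ci], aa[ci] = "missense", "TPO", "686F>V"
    sift[ci] = _CAUSAL_SCORES["sift"]
    provean[ci] = _CAUSAL_SCORES["provean"]
    panther[ci] = _CAUSAL_SCORES["panther_psep"]
    polyphen[ci] = _CAUSAL_SCORES["polyphen2"]
    panel[ci] = np.nan  # novel: absent from the reference panel

    bi = layout.benign_missense_idx
    consequence[bi], gene[bi], aa[bi] = "missense", "SNTG2", "360F>S"
    sift[bi] = _BENIGN_MISSENSE_SCORES["sift"]
    provean[bi] = _BENIGN_MISSENSE_SCORES["provean"]
    panther[bi] = _BENIGN_MISSENSE_SCORES["panther_psep"]
    polyphen[bi] = _BENIGN_MISSENSE_SCORES["polyphen2"]
    panel[bi] = _panel_counts(float(rng.uniform(0.01, 0.02)),
                              config.panel_size, rng)

    for i in layout.decoy_idx:
        consequence[i], gene[i] = "intronic", "EIPR1"
        panel[i] = _panel_counts(float(rng.uniform(0.10, 0.30)),
                                 config.panel_size, rng)
    for i in layout.linked_rare_idx:
        consequence[i], gene[i] = "intronic", "TPO"
        panel[i] = _panel_counts(float(rng.uniform(0.005, 0.03)),
                                 config.panel_size, rng)
    for i in layout.sv_idx:
        consequence[i] = ("SV-deletion" if v["alt"].iat[i] == "<DEL>"
                          else "SV-insertion")
        gene[i] = None
        panel[i] = np.nan

    return pd.DataFrame({
        "chrom": v["chrom"], "pos": v["pos"], "ref": v["ref"], "alt": v["alt"],
        "gene": gene, "consequence": consequence, "aa_change": aa,
        "sift": sift, "provean": provean, "panther_psep": panther,
        "polyphen2": polyphen,
        "panel_hom_alt": panel[:, 0], "panel_het": panel[:, 1],
        "panel_hom_ref": panel[:, 2],
    })


def emit_panels(cohort_dosage: np.ndarray, samples: pd.DataFrame,
                layout: _VariantLayout, config: SimConfig,
                rng: np.random.Generator,
                ) -> tuple[GenotypeMatrix, GenotypeMatrix, list[SiteQuality]]:
    """Build array-density and WGS-density GenotypeMatrix panels for the cohort.

    The array panel is an evenly spaced subsample of the SNVs (excluding the
    novel causal variant and SVs, which a genotyping array would not carry)
    with uniform missingness; the WGS panel carries every simulated variant
    plus per-site depth/quality.
    """
    m = cohort_dosage.shape[1]
    snv_pool = np.setdiff1d(np.arange(m),
                            np.concatenate([[layout.causal_idx], layout.sv_idx]))
    take = np.unique(np.round(np.linspace(0, len(snv_pool) - 1,
                                          config.n_array_snps)).astype(int))
    array_idx = snv_pool[take]

    array_dos = cohort_dosage[:, array_idx].copy()
    miss = rng.random(array_dos.shape) < config.array_missing_rate
    array_dos[miss] = MISSING
    array_gm = GenotypeMatrix(array_dos,
                              layout.variants.iloc[array_idx].copy(),
                              samples.copy())

    wgs_gm = GenotypeMatrix(cohort_dosage.copy(), layout.variants.copy(),
                            samples.copy())
    depth = rng.poisson(18, size=m).astype(int)
    qual = rng.uniform(25, 900, size=m)
    protected = np.concatenate([[layout.causal_idx], layout.decoy_idx,
                                layout.linked_rare_idx,
                                [layout.benign_missense_idx]]).astype(int)
    depth[protected] = np.maximum(depth[protected], 30)
    qual[protected] = 999.0
    quality = [SiteQuality(int(d), float(q)) for d, q in zip(depth, qual)]
    return array_gm, wgs_gm, quality


# ---------------------------------------------------------------------------
# top-level driver
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    pedigree: Pedigree
    population: pd.DataFrame        # id, line, generation, pedigree_f, causal
    haplotypes: np.ndarray          # (n_individuals, 2, m) whole population
    positions: np.ndarray
    array_gm: GenotypeMatrix
    wgs_gm: GenotypeMatrix
    wgs_quality: list[SiteQuality]
    annotation: pd.DataFrame
    causal: VariantKey
    decoys: list[VariantKey]

    @property
    def sample_sheet(self) -> pd.DataFrame:
        return self.array_gm.samples[["sample_id", "status", "excluded"]].copy()

    @property
    def phenocopy_ids(self) -> list[str]:
        # internal label: affected without the causal genotype; never emitted
        pop = self.population
        return pop.loc[pop["is_phenocopy"], "id"].tolist()


def simulate_dataset(config: SimConfig) -> SimResult:
    """Run the full generator: pedigree, gene drop, phenotypes, panels.

    The gene drop is redrawn with deterministic sub-seeds until at least
    ``min_cases`` affected individuals exist in the final generation
    (ascertainment: the study population is one where the recessive disease
    actually segregates). Fully deterministic under ``seed``.
    """
    config.validate()
    ped = simulate_pedigree(config, np.random.default_rng([config.seed, 11]))
    layout = _draw_positions(config, np.random.default_rng([config.seed, 1]))
    founders = ped.founders()
    n_case_f = sum(1 for f in founders if f.line == "case")
    n_ctrl_f = len(founders) - n_case_f
    final_ids = {i.id for i in ped.finals("case")} \
        | {i.id for i in ped.finals("control")}
    final_rows = [k for k, ind in enumerate(ped.individuals)
                  if ind.id in final_ids]
    positions = layout.variants["pos"].to_numpy()

    haps = None
    for attempt in range(config.max_ascertainment_attempts):
        rng_a = np.random.default_rng([config.seed, 2, attempt])
        fh = draw_founder_haplotypes(config, layout, n_case_f, n_ctrl_f, rng_a)
        haps_try = gene_drop(ped, fh, positions, config.chromosome_length_bp,
                             config.cm_per_mb, rng_a)
        causal_try = haps_try[:, :, layout.causal_idx].sum(axis=1)
        st_try, pc_try = assign_phenotypes(causal_try, config.penetrance,
                                           config.phenocopy_rate, rng_a)
        n_aff_finals = int((st_try[final_rows] == "affected").sum())
        if n_aff_finals >= config.min_cases:
            haps = haps_try
            status, phenocopy = st_try, pc_try
            break
    if haps is None:
        raise ConfigError(
            f"no gene drop with >= {config.min_cases} affected finals in "
            f"{config.max_ascertainment_attempts} attempts; the causal "
            "allele keeps being lost to drift under this configuration")

    rng = np.random.default_rng([config.seed, 3])
    dosage_all = haps.sum(axis=1, dtype=np.int8)
    causal_dos = dosage_all[:, layout.causal_idx]
    pedF = pedigree_inbreeding(ped)
    pop = pd.DataFrame({
        "id": ped.ids,
        "line": [i.line for i in ped.individuals],
        "generation": [i.generation for i in ped.individuals],
        "pedigree_f": [pedF[i] for i in ped.ids],
        "causal_dosage": causal_dos,
        "status": status,
        "is_phenocopy": phenocopy,
    })

    # cohort ascertainment: affected finals as cases, unaffected control-line
    # finals as controls (the study sampled by affection status)
    finals = {i.id for i in ped.finals("case")} | {i.id for i in ped.finals("control")}
    aff_pool = pop.loc[pop["id"].isin(finals) & (pop["status"] == "affected"),
                       "id"].tolist()
    ctrl_finals = {i.id for i in ped.finals("control")}
    case_finals = {i.id for i in ped.finals("case")}
    una_pool = pop.loc[pop["id"].isin(ctrl_finals)
                       & (pop["status"] == "unaffected"), "id"].tolist()
    rel_pool = pop.loc[pop["id"].isin(case_finals)
                       & (pop["status"] == "unaffected"), "id"].tolist()
    if not aff_pool:
        raise ConfigError("no affected individuals produced; check causal "
                          "configuration and penetrance")
    cases = sorted(rng.choice(aff_pool, size=min(config.n_cases, len(aff_pool)),
                              replace=False).tolist())
    n_rel = min(config.n_related_controls, len(rel_pool), config.n_controls)
    related = sorted(rng.choice(rel_pool, size=n_rel, replace=False).tolist())
    n_unrel = min(config.n_controls - n_rel, len(una_pool))
    controls = sorted(rng.choice(una_pool, size=n_unrel,
                                 replace=False).tolist()) + related
    cohort = cases + controls
    idx = ped.index()
    rows = [idx[s] for s in cohort]
    samples = pd.DataFrame({
        "sample_id": cohort,
        "status": ["affected"] * len(cases) + ["unaffected"] * len(controls),
        "excluded": [False] * len(cohort),
    })
    pop["in_cohort"] = pop["id"].isin(cohort)

    annotation = _build_annotation(config, layout, rng)
    array_gm, wgs_gm, quality = emit_panels(dosage_all[rows], samples, layout,
                                            config, rng)
    vk = layout.variants
    causal = VariantKey(config.chromosome, int(vk["pos"].iat[layout.causal_idx]),
                        str(vk["ref"].iat[layout.causal_idx]),
                        str(vk["alt"].iat[layout.causal_idx]))
    decoys = [VariantKey(config.chromosome, int(vk["pos"].iat[i]),
                         str(vk["ref"].iat[i]), str(vk["alt"].iat[i]))
              for i in layout.decoy_idx]
    return SimResult(config, ped, pop, haps, layout.variants["pos"].to_numpy(),
                     array_gm, wgs_gm, quality, annotation, causal, decoys)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
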