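"""Genotype containers and file I/O.

The central data structure is :class:`GenotypeMatrix`, a samples x variants
dosage matrix (0 = homozygous reference, 1 = heterozygous, 2 = homozygous
alternative, ``MISSING`` = no call) with variant and sample metadata attached.
Genotypes enter as VCF (via cyvcf2) or as PED/MAP text and every downstream
stage — QC, the mixed-model scan, ROH detection, segregation filtering —
operates on this one container.

Coordinates are 1-based and inclusive throughout (VCF convention).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

#: Sentinel for a missing genotype call.
MISSING: int = -1

STATUSES = ("affected", "unaffected", "unknown")


class FormatError(ValueError):
    """Malformed input file (bad header, mismatched PED/MAP lines, ...)."""


class VariantKey(NamedTuple):
    """Identity of one bi-allelic variant: (chromosome, 1-based bp, ref, alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None


@dataclass
class SiteQuality:
    """Per-site sequencing quality: read depth and phred-like calling quality."""

    depth: int
    qual: float

    def __post_init__(self) -> None:
        if self.depth < 0 or self.qual < 0:
            raise ValueError("depth and qual must be non-negative")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with metadata.

    Attributes
    ----------
    dosage:
        ``(n_samples, n_variants)`` int8 array with entries in
        ``{0, 1, 2, MISSING}``.
    variants:
        DataFrame with columns ``chrom, pos, ref, alt, id`` sorted by
        (chrom, pos), positions strictly increasing within a chromosome.
    samples:
        DataFrame with columns ``sample_id, status, excluded`` (and
        optionally ``sex``); ``status`` in {affected, unaffected, unknown}.
    """

    dosage: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_s, n_v = self.dosage.shape
        if len(self.samples) != n_s or len(self.variants) != n_v:
            raise ValueError("metadata shape does not match dosage matrix")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be in {0,1,2,MISSING}")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        keys = list(zip(self.variants["chrom"], self.variants["pos"],
                        self.variants["ref"], self.variants["alt"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate variant keys")
        for _, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            # non-decreasing: split multi-allelic records share a position
            if np.any(np.diff(pos) < 0):
                raise ValueError("positions not sorted within chromosome")
        if (self.variants["pos"] < 1).any():
            raise ValueError("positions must be >= 1")
        if (self.variants["ref"] == self.variants["alt"]).any():
            raise ValueError("ref and alt alleles must differ")
        bad_status = ~self.samples["status"].isin(STATUSES)
        if bad_status.any():
            raise ValueError(f"unknown status values: "
                             f"{sorted(self.samples.loc[bad_status, 'status'].unique())}")

    # -- conveniences -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    def variant_keys(self) -> list[VariantKey]:
        ids = self.variants["id"] if "id" in self.variants else [None] * self.n_variants
        return [VariantKey(c, int(p), r, a, i if isinstance(i, str) else None)
                for c, p, r, a, i in zip(self.variants["chrom"], self.variants["pos"],
                                         self.variants["ref"], self.variants["alt"], ids)]

    def subset(self, sample_mask: np.ndarray | None = None,
               variant_mask: np.ndarray | None = None) -> "GenotypeMatrix":
        d = self.dosage
        s = self.samples
        v = self.variants
        if sample_mask is not None:
            d = d[np.asarray(sample_mask)]
            s = s.loc[np.asarray(sample_mask)]
        if variant_mask is not None:
            d = d[:, np.asarray(variant_mask)]
            v = v.loc[np.asarray(variant_mask)]
        return GenotypeMatrix(d.copy(), v.copy(), s.copy())

    def status_mask(self, status: str) -> np.ndarray:
        return (self.samples["status"] == status).to_numpy() \
            & ~self.samples["excluded"].to_numpy()

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (np.array_equal(self.dosage, other.dosage)
                and self.sample_ids == other.sample_ids
                and self.variant_keys() == other.variant_keys())


def _empty_samples(ids: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame({"sample_id": list(ids),
                         "status": ["unknown"] * len(ids),
                         "excluded": [False] * len(ids)})


def make_variants_frame(chrom, pos, ref, alt, ids=None) -> pd.DataFrame:
    n = len(pos)
    return pd.DataFrame({
        "chrom": list(chrom) if not isinstance(chrom, str) else [chrom] * n,
        "pos": np.asarray(pos, dtype=np.int64),
        "ref": list(ref), "alt": list(alt),
        "id": list(ids) if ids is not None else [None] * n,
    })


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV with columns sample_id, status, excluded."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "status", "excluded"}
    if not required.issubset(df.columns):
        raise FormatError(f"sample sheet must have columns {sorted(required)}")
    df["excluded"] = df["excluded"].astype(bool)
    bad = ~df["status"].isin(STATUSES)
    if bad.any():
        raise FormatError(f"bad status values in sample sheet: "
                          f"{sorted(df.loc[bad, 'status'].unique())}")
    return df[["sample_id", "status", "excluded"]]


def write_sample_sheet(samples: pd.DataFrame, path: str | os.PathLike) -> None:
    samples[["sample_id", "status", "excluded"]].to_csv(path, sep="\t", index=False)


def apply_sample_sheet(gm_samples: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Attach status/excluded from a sample sheet; error on sheet ids not present."""
    present = set(gm_samples["sample_id"])
    missing = [s for s in sheet["sample_id"] if s not in present]
    if missing:
        raise FormatError(f"sample sheet ids absent from genotype data: {missing}")
    merged = gm_samples[["sample_id"]].merge(sheet, on="sample_id", how="left")
    merged["status"] = merged["status"].fillna("unknown")
    merged["excluded"] = merged["excluded"].map(lambda v: bool(v) if v == v
                                                else False).astype(bool)
    return merged


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike, sample_sheet: pd.DataFrame | None = None,
             split_multiallelic: bool = True,
             ) -> tuple[GenotypeMatrix, list[SiteQuality]]:
    """Read a VCF 4.x file into a GenotypeMatrix plus per-site quality.

    Dosage counts alternative alleles in the GT field. Half calls and
    non-diploid records become MISSING. Multi-allelic records are split into
    one record per alternative allele when ``split_multiallelic`` (the
    default) and skipped otherwise. Site depth is taken from INFO/DP (0 when
    absent) and calling quality from the QUAL column (0 when absent).
    """
    try:
        vcf = VCF(str(path))
        vcf_samples = list(vcf.samples)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    vids: list[str | None] = []
    rows: list[np.ndarray] = []
    quals: list[SiteQuality] = []

    for rec in vcf:
        alt_list = rec.ALT
        if len(alt_list) != 1 and not split_multiallelic:
            continue
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        depth = rec.INFO.get("DP")
        sq = SiteQuality(int(depth) if depth is not None else 0,
                         float(rec.QUAL) if rec.QUAL is not None else 0.0)
        for k, alt in enumerate(alt_list, start=1):
            dos = np.full(len(vcf_samples), MISSING, dtype=np.int8)
            for j, g in enumerate(gts):
                alleles = g[:-1]
                if len(alleles) != 2 or any(a < 0 for a in alleles):
                    continue  # half call / non-diploid / no call -> MISSING
                dos[j] = sum(1 for a in alleles if a == k)
            chroms.append(rec.CHROM)
            positions.append(rec.POS)
            refs.append(rec.REF)
            alts.append(alt)
            vids.append(rec.ID)
            rows.append(dos)
            quals.append(sq)
    vcf.close()

    dosage = (np.stack(rows).T if rows
              else np.zeros((len(vcf_samples), 0), dtype=np.int8))
    samples = _empty_samples(vcf_samples)
    if sample_sheet is not None:
        samples = apply_sample_sheet(samples, sample_sheet)
    variants = make_variants_frame(chroms, positions, refs, alts, vids)
    return GenotypeMatrix(dosage, variants, samples), quals


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike,
              site_quality: Sequence[SiteQuality] | None = None,
              chrom_lengths: Mapping[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 text file."""
    if chrom_lengths is None:
        chrom_lengths = {}
        for c, grp in gm.variants.groupby("chrom", sort=False):
            chrom_lengths[c] = int(grp["pos"].max())
    lines = ["##fileformat=VCFv4.2", "##source=rohmap"]
    for c in dict.fromkeys(gm.variants["chrom"]):
        lines.append(f"##contig=<ID={c},length={chrom_lengths.get(c, 0)}>")
    lines.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids))
    for i in range(gm.n_variants):
        v = gm.variants.iloc[i]
        if site_quality is not None:
            sq = site_quality[i]
            qual, info = f"{sq.qual:g}", f"DP={sq.depth}"
        else:
            qual, info = ".", "."
        gts = "\t".join(_GT_STR[int(d)] for d in gm.dosage[:, i])
        vid = v["id"] if isinstance(v["id"], str) else "."
        lines.append(f"{v['chrom']}\t{v['pos']}\t{vid}\t{v['ref']}\t{v['alt']}\t"
                     f"{qual}\tPASS\t{info}\tGT\t{gts}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PED / MAP
# ---------------------------------------------------------------------------

_PED_STATUS = {"1": "unaffected", "2": "affected", "0": "unknown", "-9": "unknown"}
_STATUS_PED = {"unaffected": "1", "affected": "2", "unknown": "0"}


def write_ped_map(gm: GenotypeMatrix, ped_path: str | os.PathLike,
                  map_path: str | os.PathLike, cm_per_mb: float = 1.0) -> None:
    """Write PED (6 leading columns + allele pairs) and MAP text files.

    MISSING becomes "0 0"; affection status uses the 1=unaffected /
    2=affected / 0=unknown dialect.
    """
    with open(map_path, "w") as fh:
        for i in range(gm.n_variants):
            v = gm.variants.iloc[i]
            vid = v["id"] if isinstance(v["id"], str) else f"var{i+1}"
            cm = v["pos"] / 1e6 * cm_per_mb
            fh.write(f"{v['chrom']}\t{vid}\t{cm:.6f}\t{v['pos']}\n")
    ref = gm.variants["ref"].to_numpy()
    alt = gm.variants["alt"].to_numpy()
    with open(ped_path, "w") as fh:
        for j in range(gm.n_samples):
            s = gm.samples.iloc[j]
            cols = ["FAM", s["sample_id"], "0", "0", "0",
                    _STATUS_PED[s["status"]]]
            for i, d in enumerate(gm.dosage[j]):
                if d == MISSING:
                    cols += ["0", "0"]
                elif d == 0:
                    cols += [ref[i], ref[i]]
                elif d == 1:
                    cols += [ref[i], alt[i]]
                else:
                    cols += [alt[i], alt[i]]
            fh.write(" ".join(map(str, cols)) + "\n")


def read_ped_map(ped_path: str | os.PathLike, map_path: str | os.PathLike,
                 ref_alleles: Sequence[tuple[str, str]] | None = None,
                 ) -> GenotypeMatrix:
    """Read PED/MAP text files into a GenotypeMatrix.

    Without a reference-allele table the reference at each variant is the
    majority allele across samples, ties broken lexicographically (smaller
    allele is reference); with ``ref_alleles`` (one (ref, alt) pair per MAP
    line) dosage counts the given alt allele.
    """
    variants_raw = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{map_path}:{ln}: expected 4 MAP columns")
            variants_raw.append((parts[0], parts[1], int(parts[3])))
    m = len(variants_raw)

    ids, statuses, geno_pairs = [], [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}:{ln}: expected {6 + 2*m} fields "
                    f"({m} variants), found {len(parts)}")
            ids.append(parts[1])
            statuses.append(_PED_STATUS.get(parts[5], "unknown"))
            geno_pairs.append(parts[6:])

    n = len(ids)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    refs, alts = [], []
    for i in range(m):
        a1 = [geno_pairs[j][2 * i] for j in range(n)]
        a2 = [geno_pairs[j][2 * i + 1] for j in range(n)]
        observed = [a for a in a1 + a2 if a != "0"]
        if ref_alleles is not None:
            ref, alt = ref_alleles[i]
        else:
            uniq = sorted(set(observed))
            if not uniq:
                ref, alt = "N", "A"  # fully missing column
            elif len(uniq) == 1:
                ref, alt = uniq[0], "N" if uniq[0] != "N" else "A"
            else:
                counts = {u: observed.count(u) for u in uniq}
                # majority allele is reference; ties -> lexicographically smaller
                ref = sorted(uniq, key=lambda u: (-counts[u], u))[0]
                alt = sorted(u for u in uniq if u != ref)[0]
        refs.append(ref)
        alts.append(alt)
        for j in range(n):
            x, y = geno_pairs[j][2 * i], geno_pairs[j][2 * i + 1]
            if x == "0" or y == "0":
                continue
            dosage[j, i] = (x == alt) + (y == alt)

    variants = make_variants_frame([v[0] for v in variants_raw],
                                   [v[2] for v in variants_raw],
                                   refs, alts, [v[1] for v in variants_raw])
    samples = pd.DataFrame({"sample_id": ids, "status": statuses,
                            "excluded": [False] * n})
    return GenotypeMatrix(dosage, variants, samples)


# ---------------------------------------------------------------------------
# panel intersection and site-quality filtering
# ---------------------------------------------------------------------------

def intersect_panels(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix) -> GenotypeMatrix:
    """Merge two genotype panels on shared variants.

    Returns the union of samples (sample sets must be disjoint) restricted to
    variants present in both panels, matched on (chrom, pos, ref, alt).
    A site present with swapped alleles (chrom, pos, alt, ref) is accepted by
    complementing the second panel's dosages (0 <-> 2).
    """
    if set(gm_a.sample_ids) & set(gm_b.sample_ids):
        raise ValueError("panels must have disjoint sample sets")
    key_b = {(c, p, r, a): i for i, (c, p, r, a) in enumerate(
        zip(gm_b.variants["chrom"], gm_b.variants["pos"],
            gm_b.variants["ref"], gm_b.variants["alt"]))}
    idx_a, idx_b, flipped = [], [], []
    for i, (c, p, r, a) in enumerate(zip(gm_a.variants["chrom"], gm_a.variants["pos"],
                                         gm_a.variants["ref"], gm_a.variants["alt"])):
        j = key_b.get((c, p, r, a))
        if j is not None:
            idx_a.append(i); idx_b.append(j); flipped.append(False)
            continue
        j = key_b.get((c, p, a, r))
        if j is not None:
            idx_a.append(i); idx_b.append(j); flipped.append(True)
    if not idx_a:
        raise ValueError("panels share no variants")

    dos_b = gm_b.dosage[:, idx_b].copy()
    flip = np.asarray(flipped)
    if flip.any():
        col = dos_b[:, flip]
        swapped = col.copy()
        swapped[col == 0] = 2
        swapped[col == 2] = 0
        dos_b[:, flip] = swapped
    dosage = np.vstack([gm_a.dosage[:, idx_a], dos_b])
    samples = pd.concat([gm_a.samples, gm_b.samples], ignore_index=True)
    variants = gm_a.variants.iloc[idx_a].copy()
    return GenotypeMatrix(dosage, variants, samples)


def site_quality_filter(records: Sequence[SiteQuality], min_depth: int = 4,
                        min_qual: float = 20.0, missing_fails: bool = True,
                        ) -> tuple[np.ndarray, dict[str, int]]:
    """Keep sites with depth >= min_depth and qual >= min_qual.

    Returns a boolean keep mask aligned with ``records`` and counts of sites
    failing each criterion. ``records`` may contain None entries (no quality
    information); those fail by default (``missing_fails``).
    """
    keep = np.ones(len(records), dtype=bool)
    removed = {"low_depth": 0, "low_qual": 0, "no_quality": 0}
    for i, sq in enumerate(records):
        if sq is None:
            if missing_fails:
                keep[i] = False
                removed["no_quality"] += 1
            continue
        if sq.depth < min_depth:
            keep[i] = False
            removed["low_depth"] += 1
        if sq.qual < min_qual:
            if keep[i]:
                keep[i] = False
            removed["low_qual"] += 1
    return keep, removed
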