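"""Runs-of-homozygosity detection and case/control autozygosity contrast.

The caller is the classical scanning-window algorithm: a window of
``window_snps`` consecutive SNPs slides one SNP at a time along each
sample's chromosome; a window is *homozygous* when it contains at most
``window_het_allow`` heterozygous and ``window_missing_allow`` missing
calls; each SNP's hit rate is the fraction of windows containing it that
are homozygous. SNPs with hit rate >= ``window_hit_rate`` whose own call is
homozygous (or missing) form candidate runs, which are split at inter-SNP
gaps above ``max_gap_bp`` and then kept only if they satisfy the segment
criteria: at least ``min_seg_snps`` SNPs, at least ``min_length_bp`` long,
and an inverse density of at most ``max_kb_per_snp`` kilobases per SNP.

For a recessive disease in an inbred population, affected individuals are
expected to be autozygous across the causal locus: the per-position fraction
of each group covered by an ROH (the autozygosity track) localizes the
candidate region as the interval where case autozygosity is high and
control autozygosity low.

All coordinates are 1-based inclusive; segments run from the first to the
last SNP of the run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class ROHParams:
    window_snps: int = 15
    min_length_bp: int = 1_000_000
    max_kb_per_snp: float = 100.0
    max_gap_bp: int = 1_000_000
    window_hit_rate: float = 0.05
    window_het_allow: int = 0
    window_missing_allow: int = 1
    min_seg_snps: int | None = None     # defaults to window_snps

    def __post_init__(self) -> None:
        if self.window_snps < 2:
            raise ValueError("window_snps must be >= 2")
        if not 0 < self.window_hit_rate <= 1:
            raise ValueError("window_hit_rate must be in (0, 1]")
        if self.min_length_bp <= 0 or self.max_gap_bp <= 0 or self.max_kb_per_snp <= 0:
            raise ValueError("lengths must be positive")

    @property
    def seg_snps(self) -> int:
        return self.window_snps if self.min_seg_snps is None else self.min_seg_snps


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start_bp: int
    end_bp: int
    mean_case_autozygosity: float
    mean_control_autozygosity: float


def call_roh(gm: GenotypeMatrix, params: ROHParams | None = None,
             ) -> list[ROHSegment]:
    """Detect ROH segments for every sample (see module docstring for rules)."""
    if params is None:
        params = ROHParams()
    w = params.window_snps
    segments: list[ROHSegment] = []
    for chrom, grp in gm.variants.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        n = len(cols)
        if n < w:
            warnings.warn(f"chromosome {chrom} has {n} SNPs, fewer than the "
                          f"{w}-SNP window; no calls", stacklevel=2)
            continue
        d = gm.dosage[:, cols]
        het = (d == 1)
        mis = (d == MISSING)

        def winsum(a: np.ndarray) -> np.ndarray:
            cs = np.zeros((a.shape[0], n + 1), dtype=np.int32)
            np.cumsum(a, axis=1, out=cs[:, 1:])
            return cs[:, w:] - cs[:, :-w]          # (S, n - w + 1)

        hom_win = ((winsum(het) <= params.window_het_allow)
                   & (winsum(mis) <= params.window_missing_allow))
        K = n - w + 1
        hw = np.zeros((gm.n_samples, K + 1), dtype=np.int32)
        np.cumsum(hom_win, axis=1, out=hw[:, 1:])
        i = np.arange(n)
        lo = np.maximum(0, i - w + 1)
        hi = np.minimum(i, K - 1)
        n_win = (hi - lo + 1).astype(float)         # windows fully on-chromosome
        hits = hw[:, hi + 1] - hw[:, lo]
        rate = hits / n_win[None, :]
        # own call homozygous or missing, i.e. anything but a het
        eligible = (rate >= params.window_hit_rate) & ~het

        # candidate runs, vectorized across samples: insert permanent break
        # columns at inter-SNP gaps above max_gap_bp plus one separator per
        # row, then find maximal True runs on the flattened matrix
        gap_break = np.flatnonzero(np.diff(pos) > params.max_gap_bp)
        n_ext = n + len(gap_break) + 1
        col_map = np.zeros(n, dtype=np.int64)
        ext = np.zeros((gm.n_samples, n_ext), dtype=bool)
        shift = np.zeros(n, dtype=np.int64)
        for k, g in enumerate(gap_break):       # columns after g shift right
            shift[g + 1:] += 1
        col_map = np.arange(n) + shift
        ext[:, col_map] = eligible
        flat = ext.ravel()
        edges = np.diff(flat.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1)
        if flat[0]:
            starts = np.concatenate([[0], starts])
        if flat[-1]:
            ends = np.concatenate([ends, [flat.size - 1]])
        rows = starts // n_ext
        back = np.full(n_ext, -1, dtype=np.int64)
        back[col_map] = np.arange(n)
        c0 = back[starts - rows * n_ext]
        c1 = back[ends - rows * n_ext]
        n_snps = c1 - c0 + 1
        length = pos[c1] - pos[c0] + 1
        ok = ((n_snps >= params.seg_snps)
              & (length >= params.min_length_bp)
              & (length / n_snps <= params.max_kb_per_snp * 1000))
        ids = gm.sample_ids
        for r, a, b, k in zip(rows[ok], pos[c0[ok]], pos[c1[ok]],
                              n_snps[ok]):
            segments.append(ROHSegment(ids[r], str(chrom), int(a), int(b),
                                       int(k)))
    return segments


def autozygosity_track(segments: Sequence[ROHSegment],
                       variants: pd.DataFrame,
                       sample_groups: Mapping[str, Sequence[str]],
                       ) -> pd.DataFrame:
    """Per-position fraction of each group's samples covered by an ROH.

    Returns a DataFrame with chrom, pos, and one ``frac_<group>`` column per
    group in ``sample_groups`` (values in [0, 1]).
    """
    for name, ids in sample_groups.items():
        if len(ids) == 0:
            raise ValueError(f"empty sample group {name!r}")
    by_sample: dict[tuple[str, str], list[ROHSegment]] = {}
    for seg in segments:
        by_sample.setdefault((seg.sample_id, seg.chrom), []).append(seg)

    frames = []
    for chrom, grp in variants.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        out = {"chrom": chrom, "pos": pos}
        for name, ids in sample_groups.items():
            counts = np.zeros(len(pos))
            for sid in ids:
                cov = np.zeros(len(pos) + 1, dtype=np.int32)
                for seg in by_sample.get((sid, str(chrom)), ()):
                    lo = np.searchsorted(pos, seg.start_bp, side="left")
                    hi = np.searchsorted(pos, seg.end_bp, side="right")
                    cov[lo] += 1
                    cov[hi] -= 1
                counts += np.cumsum(cov[:-1]) > 0
            out[f"frac_{name}"] = counts / len(ids)
        frames.append(pd.DataFrame(out))
    return pd.concat(frames, ignore_index=True)


def contrast_candidate_regions(track: pd.DataFrame, case_min: float = 0.7,
                               control_max: float = 0.2, pad_bp: int = 0,
                               max_gap_bp: int = 1_000_000,
                               chrom_lengths: Mapping[str, int] | None = None,
                               case_col: str = "frac_affected",
                               control_col: str = "frac_unaffected",
                               ) -> list[CandidateRegion]:
    """Maximal intervals where case autozygosity is high and control low.

    At every SNP of a region, ``case >= case_min`` and
    ``control <= control_max``. Intervals separated by less than
    ``max_gap_bp`` are merged; the result is padded by ``pad_bp`` and
    clipped to chromosome bounds.
    """
    regions: list[CandidateRegion] = []
    for chrom, grp in track.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        case = grp[case_col].to_numpy()
        ctrl = grp[control_col].to_numpy()
        mask = (case >= case_min) & (ctrl <= control_max)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        brk = np.flatnonzero(np.diff(idx) > 1)
        raw: list[np.ndarray] = list(np.split(idx, brk + 1))
        # merge intervals separated by < max_gap_bp
        merged: list[np.ndarray] = [raw[0]]
        for run in raw[1:]:
            if pos[run[0]] - pos[merged[-1][-1]] < max_gap_bp:
                merged[-1] = np.concatenate([merged[-1], run])
            else:
                merged.append(run)
        limit = (chrom_lengths or {}).get(str(chrom), int(pos[-1]))
        for run in merged:
            start = max(1, int(pos[run[0]]) - pad_bp)
            end = min(limit, int(pos[run[-1]]) + pad_bp)
            regions.append(CandidateRegion(
                str(chrom), start, end,
                float(case[run].mean()), float(ctrl[run].mean())))
    return regions


def roh_burden(segments: Sequence[ROHSegment], min_len_bp: int = 2_000_000,
               sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-sample count and summed length of segments >= ``min_len_bp``."""
    ids = list(sample_ids) if sample_ids is not None else \
        sorted({s.sample_id for s in segments})
    count = {s: 0 for s in ids}
    total = {s: 0 for s in ids}
    for seg in segments:
        if seg.length >= min_len_bp and seg.sample_id in count:
            count[seg.sample_id] += 1
            total[seg.sample_id] += seg.length
    return pd.DataFrame({"sample_id": ids,
                         "n_segments": [count[s] for s in ids],
                         "total_length_bp": [total[s] for s in ids]})


# ---------------------------------------------------------------------------
# export helpers
# ---------------------------------------------------------------------------

def segments_to_frame(segments: Sequence[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": s.sample_id, "chrom": s.chrom, "start_bp": s.start_bp,
        "end_bp": s.end_bp, "n_snps": s.n_snps, "length_bp": s.length,
    } for s in segments])


def regions_to_bed(regions: Sequence[CandidateRegion], path) -> None:
    """Write regions as BED (0-based half-open, converted from 1-based closed)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t"
                     f"case={r.mean_case_autozygosity:.3f};"
                     f"control={r.mean_control_autozygosity:.3f}\n")
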