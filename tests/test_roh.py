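"""ROH caller tests against an independent brute-force oracle, plus
autozygosity track, candidate-region contrast and burden summaries."""

import numpy as np
import pandas as pd
import pytest

import rohmap
from rohmap import (MISSING, CandidateRegion, ROHParams, autozygosity_track,
                    call_roh, contrast_candidate_regions, roh_burden)

from conftest import make_gm


# ---------------------------------------------------------------------------
# independent brute-force implementation of the five segment criteria
# ---------------------------------------------------------------------------

def roh_oracle(dosages, positions, p: ROHParams):
    """Plain-loop reimplementation of the scanning-window rules."""
    n = len(positions)
    w = p.window_snps
    if n < w:
        return []
    windows = [(s, s + w) for s in range(n - w + 1)]
    hom_win = []
    for s, e in windows:
        hets = sum(1 for i in range(s, e) if dosages[i] == 1)
        miss = sum(1 for i in range(s, e) if dosages[i] == MISSING)
        hom_win.append(hets <= p.window_het_allow
                       and miss <= p.window_missing_allow)
    eligible = []
    for i in range(n):
        covering = [k for k, (s, e) in enumerate(windows) if s <= i < e]
        rate = sum(hom_win[k] for k in covering) / len(covering)
        eligible.append(rate >= p.window_hit_rate and dosages[i] != 1)

    segs = []

    def flush(run):
        pieces = [[run[0]]]
        for a, b in zip(run, run[1:]):
            if positions[b] - positions[a] > p.max_gap_bp:
                pieces.append([])
            pieces[-1].append(b)
        for piece in pieces:
            length = positions[piece[-1]] - positions[piece[0]] + 1
            if (len(piece) >= p.seg_snps and length >= p.min_length_bp
                    and length / len(piece) <= p.max_kb_per_snp * 1000):
                segs.append((int(positions[piece[0]]),
                             int(positions[piece[-1]]), len(piece)))

    run = []
    for i in range(n):
        if eligible[i]:
            run.append(i)
        elif run:
            flush(run)
            run = []
    if run:
        flush(run)
    return segs


def caller_segments(dosages, positions, p):
    gm = make_gm(np.asarray([dosages], dtype=np.int8), positions=positions)
    return [(s.start_bp, s.end_bp, s.n_snps) for s in call_roh(gm, p)]


def check_segment_criteria(seg, positions, dosages, p: ROHParams):
    """Independent validity checker for one emitted segment."""
    pos = np.asarray(positions)
    inside = np.flatnonzero((pos >= seg.start_bp) & (pos <= seg.end_bp))
    assert seg.n_snps >= p.seg_snps
    assert seg.length >= p.min_length_bp
    assert seg.length / seg.n_snps <= p.max_kb_per_snp * 1000
    gaps = np.diff(pos[inside])
    assert (gaps <= p.max_gap_bp).all()
    assert not any(dosages[i] == 1 for i in inside)


class TestCallRoh:
    def test_fully_heterozygous_sample_has_no_segments(self):
        gm = make_gm(np.ones((1, 40), dtype=np.int8),
                     positions=np.arange(40) * 100_000 + 1)
        assert call_roh(gm, ROHParams()) == []

    def test_forced_single_segment(self):
        # 20 contiguous homozygous SNPs spanning 1.2 Mb flanked by hets
        pos = np.concatenate([[1, 50_000],
                              np.linspace(2e6, 3.2e6, 20).astype(int),
                              [4_000_000, 4_050_000]])
        dosages = np.array([1, 1] + [0] * 10 + [2] * 10 + [1, 1])
        p = ROHParams(window_snps=15, window_hit_rate=0.05)
        segs = caller_segments(dosages, pos, p)
        assert segs == [(2_000_000, 3_200_000, 20)]

    def test_too_few_snps_no_segment(self):
        # 14 homozygous SNPs over 1.5 Mb fail the minimum SNP count of 15
        pos = np.concatenate([[1], np.linspace(2e6, 3.5e6, 14).astype(int),
                              [5_000_000]])
        dosages = np.array([1] + [0] * 14 + [1])
        assert caller_segments(dosages, pos, ROHParams()) == []

    def test_gap_splits_run(self):
        # 30 hom SNPs with a 2 Mb hole in the middle -> two 15-SNP halves
        pos = np.concatenate([np.linspace(1e6, 2.4e6, 15),
                              np.linspace(4.5e6, 5.9e6, 15)]).astype(int)
        dosages = np.zeros(30, dtype=int)
        p = ROHParams(window_snps=15, max_gap_bp=1_000_000)
        segs = caller_segments(dosages, pos, p)
        assert len(segs) == 2
        assert segs[0][2] == 15 and segs[1][2] == 15

    def test_density_criterion(self):
        # 15 SNPs spread over 3 Mb: 200 kb per SNP exceeds the 100 kb cap
        pos = np.linspace(1e6, 4e6, 15).astype(int)
        dosages = np.zeros(15, dtype=int)
        assert caller_segments(dosages, pos, ROHParams()) == []

    def test_short_chromosome_warns(self):
        gm = make_gm(np.zeros((1, 5), dtype=np.int8))
        with pytest.warns(UserWarning, match="fewer than"):
            assert call_roh(gm, ROHParams()) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_on_random_toys(self, seed):
        rng = np.random.default_rng(seed)
        n = 300
        pos = np.sort(rng.choice(30_000_000, size=n, replace=False)) + 1
        dosages = rng.choice([0, 1, 2, MISSING], size=n,
                             p=[0.42, 0.08, 0.42, 0.08])
        p = ROHParams(window_snps=int(rng.integers(3, 20)),
                      min_length_bp=int(rng.integers(1, 15) * 100_000),
                      max_kb_per_snp=float(rng.integers(50, 300)),
                      max_gap_bp=int(rng.integers(2, 15) * 100_000),
                      window_hit_rate=float(rng.uniform(0.03, 0.6)),
                      window_het_allow=int(rng.integers(0, 2)),
                      window_missing_allow=int(rng.integers(0, 3)))
        assert caller_segments(dosages, pos, p) == roh_oracle(dosages, pos, p)

    def test_emitted_segments_satisfy_all_criteria(self, default_sim):
        gm, _ = rohmap.qc_filter(default_sim.array_gm)
        p = ROHParams()
        segs = call_roh(gm, p)
        assert segs, "inbred simulation should produce ROH"
        pos = gm.variants["pos"].to_numpy()
        ids = gm.sample_ids
        for seg in segs:
            row = ids.index(seg.sample_id)
            check_segment_criteria(seg, pos, gm.dosage[row], p)

    def test_min_length_monotonicity(self, default_sim):
        gm, _ = rohmap.qc_filter(default_sim.array_gm)
        counts = [len(call_roh(gm, ROHParams(min_length_bp=L)))
                  for L in (500_000, 1_000_000, 2_000_000, 4_000_000)]
        assert counts == sorted(counts, reverse=True)


class TestAutozygosityTrack:
    def _variants(self, n=20):
        return pd.DataFrame({"chrom": ["chr1"] * n,
                             "pos": np.arange(1, n + 1) * 100_000})

    def test_no_segments_all_zero(self):
        track = autozygosity_track([], self._variants(),
                                   {"affected": ["a"], "unaffected": ["b"]})
        assert (track["frac_affected"] == 0).all()
        assert (track["frac_unaffected"] == 0).all()

    def test_shared_segment_is_one_inside_zero_outside(self):
        from rohmap.roh import ROHSegment
        segs = [ROHSegment(s, "chr1", 500_000, 1_000_000, 6)
                for s in ("a", "b", "c")]
        track = autozygosity_track(segs, self._variants(),
                                   {"affected": ["a", "b", "c"]})
        inside = (track["pos"] >= 500_000) & (track["pos"] <= 1_000_000)
        assert (track.loc[inside, "frac_affected"] == 1).all()
        assert (track.loc[~inside, "frac_affected"] == 0).all()

    def test_matches_bruteforce_interval_stabbing(self):
        from rohmap.roh import ROHSegment
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(8)]
        segs = []
        for sid in ids:
            for _ in range(rng.integers(0, 4)):
                a = int(rng.integers(1, 1_900_000))
                b = a + int(rng.integers(1, 500_000))
                segs.append(ROHSegment(sid, "chr1", a, b, 5))
        variants = self._variants()
        track = autozygosity_track(segs, variants, {"affected": ids})
        for _, row in track.iterrows():
            covered = sum(
                1 for sid in ids
                if any(s.sample_id == sid and s.start_bp <= row["pos"]
                       <= s.end_bp for s in segs))
            assert row["frac_affected"] == pytest.approx(covered / len(ids))

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="empty"):
            autozygosity_track([], self._variants(), {"affected": []})


class TestContrast:
    def _track(self, case, control, n=None):
        n = n or len(case)
        return pd.DataFrame({"chrom": ["chr1"] * n,
                             "pos": np.arange(1, n + 1) * 100_000,
                             "frac_affected": case,
                             "frac_unaffected": control})

    def test_region_ends_at_autozygosity_drop(self):
        # case autozygosity 0.86 over the first 47 SNPs then drops to 0.3;
        # control stays at 0.14 -> one region ending at the last high SNP
        case = [0.86] * 47 + [0.3] * 13
        control = [0.14] * 60
        regions = contrast_candidate_regions(self._track(case, control))
        assert len(regions) == 1
        assert regions[0].start_bp == 100_000
        assert regions[0].end_bp == 47 * 100_000

    def test_trivial_thresholds_cover_chromosome(self):
        case = np.linspace(0, 1, 30)
        control = np.linspace(1, 0, 30)
        regions = contrast_candidate_regions(self._track(case, control),
                                             case_min=0.0, control_max=1.0)
        assert len(regions) == 1
        assert regions[0].start_bp == 100_000
        assert regions[0].end_bp == 3_000_000

    def test_padding_and_clipping(self):
        case = [0.0] * 5 + [0.9] * 5 + [0.0] * 5
        control = [0.0] * 15
        regions = contrast_candidate_regions(
            self._track(case, control), pad_bp=10_000_000,
            chrom_lengths={"chr1": 2_000_000})
        assert regions[0].start_bp == 1 and regions[0].end_bp == 2_000_000

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        case = rng.random(n).round(2)
        control = rng.random(n).round(2)
        track = self._track(case, control, n)
        regions = contrast_candidate_regions(track, case_min=0.6,
                                             control_max=0.3,
                                             max_gap_bp=150_000)
        pos = track["pos"].to_numpy()
        mask = (case >= 0.6) & (control <= 0.3)
        # brute force: maximal runs, then merge across gaps < 150 kb
        runs = []
        for i in range(n):
            if mask[i]:
                if runs and runs[-1][-1] == i - 1:
                    runs[-1].append(i)
                else:
                    runs.append([i])
        merged = []
        for r in runs:
            if merged and pos[r[0]] - pos[merged[-1][-1]] < 150_000:
                merged[-1].extend(r)
            else:
                merged.append(list(r))
        expected = [(int(pos[r[0]]), int(pos[r[-1]])) for r in merged]
        assert [(r.start_bp, r.end_bp) for r in regions] == expected

    def test_contains_planted_locus(self, default_sim):
        gm, _ = rohmap.qc_filter(default_sim.array_gm)
        segs = call_roh(gm)
        groups = {
            "affected": [s for s, st in zip(gm.sample_ids,
                                            gm.samples["status"])
                         if st == "affected"],
            "unaffected": [s for s, st in zip(gm.sample_ids,
                                              gm.samples["status"])
                           if st == "unaffected"]}
        track = autozygosity_track(segs, gm.variants, groups)
        regions = contrast_candidate_regions(track)
        assert any(r.start_bp <= default_sim.causal.pos <= r.end_bp
                   for r in regions)


class TestBurden:
    def test_empty(self):
        out = roh_burden([], sample_ids=["a"])
        assert out.loc[0, "n_segments"] == 0
        assert out.loc[0, "total_length_bp"] == 0

    def test_threshold(self):
        from rohmap.roh import ROHSegment
        segs = [ROHSegment("a", "chr1", 1, 1_500_000, 20),
                ROHSegment("a", "chr1", 3_000_000, 5_499_999, 30)]
        out = roh_burden(segs, min_len_bp=2_000_000)
        assert out.loc[0, "n_segments"] == 1
        assert out.loc[0, "total_length_bp"] == 2_500_000

    def test_cases_carry_more_long_roh(self, default_sim):
        gm, _ = rohmap.qc_filter(default_sim.array_gm)
        segs = call_roh(gm)
        burden = roh_burden(segs, sample_ids=gm.sample_ids)
        merged = burden.merge(gm.samples, on="sample_id")
        case_mean = merged.loc[merged["status"] == "affected",
                               "n_segments"].mean()
        ctrl_mean = merged.loc[merged["status"] == "unaffected",
                               "n_segments"].mean()
        assert case_mean > ctrl_mean
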