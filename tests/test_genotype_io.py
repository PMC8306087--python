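"""Genotype container and file-format round-trip tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rohmap
from rohmap import (MISSING, FormatError, GenotypeMatrix, SiteQuality,
                    intersect_panels, read_ped_map, read_vcf,
                    site_quality_filter, write_ped_map, write_vcf)

from conftest import make_gm


VCF_TEXT = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tdogA\tdogB
chr1\t100\t.\tA\tG\t50\tPASS\tDP=30\tGT\t0/0\t0/0
chr1\t200\t.\tC\tT\t60\tPASS\tDP=25\tGT\t0/1\t./.
chr1\t300\t.\tG\tA\t70\tPASS\tDP=12\tGT\t1/1\t0/.
chr1\t400\t.\tT\tA,C\t80\tPASS\tDP=9\tGT\t1/2\t0/1
"""


@pytest.fixture
def vcf_file(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(VCF_TEXT)
    return p


class TestReadVcf:
    def test_dosage_codes_and_missing(self, vcf_file):
        gm, quals = read_vcf(vcf_file)
        assert gm.sample_ids == ["dogA", "dogB"]
        # bi-allelic records: 0/0 -> 0, 0/1 -> 1, 1/1 -> 2, ./. and half
        # calls -> MISSING
        assert gm.dosage[0, 0] == 0 and gm.dosage[1, 0] == 0
        assert gm.dosage[0, 1] == 1 and gm.dosage[1, 1] == MISSING
        assert gm.dosage[0, 2] == 2 and gm.dosage[1, 2] == MISSING

    def test_multiallelic_split(self, vcf_file):
        gm, _ = read_vcf(vcf_file, split_multiallelic=True)
        # the A,C record becomes two bi-allelic variants at pos 400
        sub = gm.variants[gm.variants["pos"] == 400]
        assert list(sub["alt"]) == ["A", "C"]
        col_a = sub.index[0]
        col_c = sub.index[1]
        assert gm.dosage[0, col_a] == 1  # GT 1/2 counts one copy of each alt
        assert gm.dosage[0, col_c] == 1
        assert gm.dosage[1, col_a] == 1 and gm.dosage[1, col_c] == 0

    def test_multiallelic_skip(self, vcf_file):
        gm, _ = read_vcf(vcf_file, split_multiallelic=False)
        assert 400 not in set(gm.variants["pos"])

    def test_site_quality_captured(self, vcf_file):
        _, quals = read_vcf(vcf_file)
        assert quals[0].depth == 30 and quals[0].qual == 50

    def test_sample_sheet_applied_and_missing_ids_error(self, vcf_file):
        sheet = pd.DataFrame({"sample_id": ["dogA"], "status": ["affected"],
                              "excluded": [False]})
        gm, _ = read_vcf(vcf_file, sheet)
        assert gm.samples.loc[0, "status"] == "affected"
        assert gm.samples.loc[1, "status"] == "unknown"
        bad = pd.DataFrame({"sample_id": ["nope"], "status": ["affected"],
                            "excluded": [False]})
        with pytest.raises(FormatError, match="nope"):
            read_vcf(vcf_file, bad)

    def test_malformed_vcf(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("not a vcf at all\n")
        with pytest.raises(FormatError):
            read_vcf(p)


class TestWriteVcf:
    def test_empty_matrix_header_only(self, tmp_path):
        gm = make_gm(np.zeros((2, 0), dtype=np.int8))
        path = tmp_path / "empty.vcf"
        write_vcf(gm, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "##fileformat=VCFv4.2"
        assert all(l.startswith("#") for l in lines)

    def test_missing_cell_rendered(self, tmp_path):
        gm = make_gm([[MISSING], [1]])
        path = tmp_path / "m.vcf"
        write_vcf(gm, path)
        data = [l for l in path.read_text().splitlines()
                if not l.startswith("#")]
        assert data[0].split("\t")[-2:] == ["./.", "0/1"]

    def test_roundtrip_simulated(self, small_sim, tmp_path):
        path = tmp_path / "rt.vcf"
        write_vcf(small_sim.wgs_gm, path, small_sim.wgs_quality)
        gm2, _ = read_vcf(path)
        assert gm2.equals(small_sim.wgs_gm)


class TestPedMap:
    def test_codes(self, tmp_path):
        gm = make_gm([[0, MISSING, 2], [1, 1, 0]],
                     status=["unaffected", "affected"],
                     ref=list("AAA"), alt=list("GGG"))
        write_ped_map(gm, tmp_path / "t.ped", tmp_path / "t.map")
        ped = (tmp_path / "t.ped").read_text().splitlines()
        assert ped[0].split()[5] == "1" and ped[1].split()[5] == "2"
        assert ped[0].split()[8:10] == ["0", "0"]  # MISSING -> "0 0"
        gm2 = read_ped_map(tmp_path / "t.ped", tmp_path / "t.map",
                           ref_alleles=[("A", "G")] * 3)
        assert np.array_equal(gm2.dosage, gm.dosage)
        assert list(gm2.samples["status"]) == ["unaffected", "affected"]

    def test_majority_reference_with_tiebreak(self, tmp_path):
        # G is the majority allele at the first variant -> reference;
        # at the second, G and A tie 2:2 -> lexicographically smaller A wins
        gm = make_gm([[0, 0], [0, 2]], ref=list("GG"), alt=list("AA"))
        write_ped_map(gm, tmp_path / "t.ped", tmp_path / "t.map")
        gm2 = read_ped_map(tmp_path / "t.ped", tmp_path / "t.map")
        assert gm2.variants["ref"].iloc[0] == "G"
        assert np.array_equal(gm2.dosage[:, 0], gm.dosage[:, 0])
        assert gm2.variants["ref"].iloc[1] == "A"
        # with A as reference, the all-G sample is homozygous alternative
        assert list(gm2.dosage[:, 1]) == [2, 0]

    def test_length_mismatch_names_line(self, tmp_path):
        (tmp_path / "t.map").write_text("chr1\tv1\t0.001\t1000\n")
        (tmp_path / "t.ped").write_text("FAM s1 0 0 0 1 A A G\n")
        with pytest.raises(FormatError, match=":1"):
            read_ped_map(tmp_path / "t.ped", tmp_path / "t.map")

    def test_roundtrip_simulated(self, small_sim, tmp_path):
        gm = small_sim.array_gm
        write_ped_map(gm, tmp_path / "a.ped", tmp_path / "a.map")
        refs = list(zip(gm.variants["ref"], gm.variants["alt"]))
        gm2 = read_ped_map(tmp_path / "a.ped", tmp_path / "a.map",
                           ref_alleles=refs)
        assert np.array_equal(gm2.dosage, gm.dosage)
        assert gm2.sample_ids == gm.sample_ids


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.integers(0, 10**6))
def test_roundtrip_property_random_matrices(seed):
    """read(write(x)) == x for both formats, MISSING cells included."""
    import tempfile
    from pathlib import Path

    rng = np.random.default_rng(seed)
    n, m = rng.integers(1, 6), rng.integers(1, 15)
    dosage = rng.choice([0, 1, 2, MISSING], size=(n, m),
                        p=[0.4, 0.25, 0.25, 0.1]).astype(np.int8)
    pos = np.sort(rng.choice(10**6, size=m, replace=False)) + 1
    refs = rng.choice(list("ACGT"), size=m)
    alts = [rng.choice([b for b in "ACGT" if b != r]) for r in refs]
    gm = make_gm(dosage, positions=pos, ref=refs, alt=alts)
    with tempfile.TemporaryDirectory() as tmp:
        d = Path(tmp)
        write_vcf(gm, d / "x.vcf")
        gm_v, _ = read_vcf(d / "x.vcf")
        assert gm_v.equals(gm)
        write_ped_map(gm, d / "x.ped", d / "x.map")
        gm_p = read_ped_map(d / "x.ped", d / "x.map",
                            ref_alleles=list(zip(refs, alts)))
        assert np.array_equal(gm_p.dosage, gm.dosage)


class TestIntersectPanels:
    def _two(self):
        a = make_gm([[0, 1, 2, 0, 1]], ref=list("AACGT"), alt=list("GGTAC"))
        b = make_gm([[2, 0, 1, 1, 0]], ref=list("AACGT"), alt=list("GGTAC"))
        b.samples["sample_id"] = ["other"]
        return a, b

    def test_identical_panels_keep_all(self):
        a, b = self._two()
        out = intersect_panels(a, b)
        assert out.n_variants == 5 and out.n_samples == 2

    def test_partial_overlap(self):
        a, b = self._two()
        b.variants.loc[3, "pos"] = 99_999
        b.variants.loc[4, "pos"] = 99_998
        b = GenotypeMatrix(b.dosage, b.variants.sort_values("pos"),
                           b.samples)
        out = intersect_panels(a, b)
        assert out.n_variants == 3

    def test_allele_swap_complements_dosage(self):
        a, b = self._two()
        # swap ref/alt at the first site in panel b
        b.variants.loc[0, ["ref", "alt"]] = ["G", "A"]
        out = intersect_panels(a, b)
        col = out.variants.index[out.variants["pos"] == 1000][0]
        assert out.dosage[1, col] == 0  # b had 2, complemented to 0
        assert out.dosage[0, col] == 0  # a unchanged

    def test_symmetry_of_variant_content(self):
        a, b = self._two()
        b.variants.loc[4, "pos"] = 77_777
        b = GenotypeMatrix(b.dosage, b.variants.sort_values("pos"), b.samples)
        ab = intersect_panels(a, b)
        ba = intersect_panels(b, a)
        keys = lambda gm: set(zip(gm.variants["chrom"], gm.variants["pos"]))
        assert keys(ab) == keys(ba)

    def test_errors(self):
        a, _ = self._two()
        with pytest.raises(ValueError, match="disjoint"):
            intersect_panels(a, a)
        a2, b = self._two()
        b.variants["pos"] = b.variants["pos"] + 10**7
        with pytest.raises(ValueError, match="share no variants"):
            intersect_panels(a2, b)


class TestSiteQualityFilter:
    def test_boundaries_inclusive(self):
        keep, removed = site_quality_filter(
            [SiteQuality(4, 20.0), SiteQuality(3, 99.0),
             SiteQuality(100, 19.9)])
        assert list(keep) == [True, False, False]
        assert removed["low_depth"] == 1 and removed["low_qual"] == 1

    def test_missing_quality_fails_by_default(self):
        keep, removed = site_quality_filter([None, SiteQuality(10, 30)])
        assert list(keep) == [False, True]
        keep2, _ = site_quality_filter([None], missing_fails=False)
        assert list(keep2) == [True]

    def test_matches_bruteforce_and_idempotent(self):
        rng = np.random.default_rng(0)
        recs = [SiteQuality(int(d), float(q)) for d, q in
                zip(rng.integers(0, 10, 1000), rng.uniform(0, 40, 1000))]
        keep, _ = site_quality_filter(recs)
        expected = [r.depth >= 4 and r.qual >= 20 for r in recs]
        assert list(keep) == expected
        kept_records = [r for r, k in zip(recs, keep) if k]
        keep2, removed2 = site_quality_filter(kept_records)
        assert keep2.all() and sum(removed2.values()) == 0
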