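"""End-to-end orchestration: simulate -> QC -> GWAS -> ROH -> filter -> validate.

A single YAML/dict configuration drives the whole analysis; every stage
writes its outputs (plain text: TSV, BED, VCF, JSON) under the configured
output directory and the run finishes with a machine-readable
``report.json`` capturing parameters, per-stage summaries, the candidate
regions, the filter funnel and the validation statistics. Reruns with the
same seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genotype_io as gio
from . import lmm, qc, roh, segfilter, stats
from .simulate import SimConfig, simulate_dataset

log = logging.getLogger("rohmap")


class ConfigValidationError(ValueError):
    pass


_KNOWN_SECTIONS = {"output_dir", "seed", "simulate", "inputs", "qc", "roh",
                   "scan_filter", "filter", "thresholds"}


@dataclass
class RunConfig:
    output_dir: str
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    inputs: dict | None = None
    qc: dict = field(default_factory=dict)
    roh: dict = field(default_factory=dict)
    scan_filter: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigValidationError("config must be a mapping")
        unknown = set(raw) - _KNOWN_SECTIONS
        if unknown:
            raise ConfigValidationError(f"unknown config fields: {sorted(unknown)}")
        if "output_dir" not in raw or not raw["output_dir"]:
            raise ConfigValidationError("missing required field 'output_dir'")
        cfg = cls(**raw)
        sim_fields = {f.name for f in dc_fields(SimConfig)}
        bad = set(cfg.simulate) - sim_fields
        if bad:
            raise ConfigValidationError(f"unknown simulate fields: {sorted(bad)}")
        for section, allowed in (("qc", {"maf_min", "max_variant_missing",
                                         "max_sample_missing"}),
                                 ("scan_filter", {"maf_min", "max_missing"}),
                                 ("thresholds", {"alpha", "case_min",
                                                 "control_max", "pad_bp"}),
                                 ("filter", {"region", "excluded_cases",
                                             "af_max", "consensus_rule"})):
            bad = set(getattr(cfg, section)) - allowed
            if bad:
                raise ConfigValidationError(
                    f"unknown {section} fields: {sorted(bad)}")
        roh_fields = {f.name for f in dc_fields(roh.ROHParams)}
        bad = set(cfg.roh) - roh_fields
        if bad:
            raise ConfigValidationError(f"unknown roh fields: {sorted(bad)}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log", mode="w")
    log.addHandler(fh)
    report: dict = {"seed": config.seed, "parameters": {
        "qc": config.qc, "roh": config.roh, "scan_filter": config.scan_filter,
        "filter": {k: v for k, v in config.filter.items()},
        "thresholds": config.thresholds, "simulate": config.simulate,
    }}
    try:
        # ---- stage 1: data ------------------------------------------------
        causal = None
        if config.inputs:
            ins = config.inputs
            sheet = gio.read_sample_sheet(ins["sample_sheet"])
            if "vcf" in ins:
                wgs_gm, quality = gio.read_vcf(ins["vcf"], sheet)
            else:
                wgs_gm, quality = None, None
            if "ped" in ins and "map" in ins:
                array_gm = gio.read_ped_map(ins["ped"], ins["map"])
                array_gm.samples = gio.apply_sample_sheet(
                    array_gm.samples[["sample_id"]], sheet)
            else:
                array_gm = wgs_gm
            annotation = (pd.read_csv(ins["annotation"], sep="\t")
                          if "annotation" in ins else None)
        else:
            sim_cfg = SimConfig(**{**config.simulate, "seed": config.seed})
            sim = simulate_dataset(sim_cfg)
            array_gm, wgs_gm, quality = sim.array_gm, sim.wgs_gm, sim.wgs_quality
            annotation = sim.annotation
            causal = sim.causal
            gio.write_ped_map(array_gm, out / "array.ped", out / "array.map")
            gio.write_vcf(wgs_gm, out / "wgs.vcf", quality,
                          {sim_cfg.chromosome: sim_cfg.chromosome_length_bp})
            gio.write_sample_sheet(array_gm.samples, out / "samples.tsv")
            annotation.to_csv(out / "annotation.tsv", sep="\t", index=False,
                              float_format="%.6g")
            report["simulated_causal"] = {
                "chrom": causal.chrom, "pos": causal.pos,
                "ref": causal.ref, "alt": causal.alt}
        log.info("data stage complete: %d samples, %d array variants",
                 array_gm.n_samples, array_gm.n_variants)

        # ---- stage 2: QC, inbreeding, PCA ---------------------------------
        qcp = qc.QCParams(**config.qc)
        gm_qc, qc_report = qc.qc_filter(array_gm, qcp)
        f_table = qc.inbreeding_f(gm_qc)
        f_table.to_csv(out / "inbreeding.tsv", sep="\t", index=False,
                       float_format="%.6g")
        f_groups = qc.compare_group_f(f_table, gm_qc.samples)
        pca = qc.pca_scores(gm_qc, k=2)
        pca.to_csv(out / "pca.tsv", sep="\t", index=False, float_format="%.6g")
        report["qc"] = qc_report
        report["inbreeding"] = f_groups
        with open(out / "qc_report.json", "w") as jfh:
            json.dump(_jsonable(qc_report), jfh, indent=2, sort_keys=True)

        # ---- stage 3: mixed-model scan ------------------------------------
        sf = lmm.ScanFilterParams(**config.scan_filter)
        scan = lmm.lmm_scan(gm_qc, scan_filter=sf)
        scan.to_csv(out / "gwas.tsv", sep="\t", index=False,
                    float_format="%.6g")
        alpha = float(config.thresholds.get("alpha", 0.05))
        m_tested = int(len(scan))
        thr = lmm.bonferroni_threshold(alpha, max(m_tested, 1))
        qq, gif = lmm.qq_data(scan["p_value"].to_numpy())
        qq.to_csv(out / "qq.tsv", sep="\t", index=False, float_format="%.6g")
        top = scan.sort_values("p_value").iloc[0]
        report["gwas"] = {
            "n_snps_tested": m_tested,
            "n_snps_discarded": scan.attrs["n_snps_discarded"],
            "lambda_hat": scan.attrs["lambda_hat"],
            "bonferroni_minus_log10": thr,
            "genomic_inflation": gif,
            "n_above_threshold": int((scan["minus_log10_p"] >= thr).sum()),
            "top_snp": {"chrom": str(top["chrom"]), "pos": int(top["pos"]),
                        "p_value": float(top["p_value"])},
        }

        # ---- stage 4: ROH and autozygosity contrast -----------------------
        rohp = roh.ROHParams(**config.roh)
        segments = roh.call_roh(gm_qc, rohp)
        roh.segments_to_frame(segments).to_csv(out / "roh_segments.tsv",
                                               sep="\t", index=False)
        groups = {
            "affected": [s for s in gm_qc.sample_ids
                         if gm_qc.samples.set_index("sample_id")
                         .loc[s, "status"] == "affected"],
            "unaffected": [s for s in gm_qc.sample_ids
                           if gm_qc.samples.set_index("sample_id")
                           .loc[s, "status"] == "unaffected"],
        }
        track = roh.autozygosity_track(segments, gm_qc.variants, groups)
        track.to_csv(out / "autozygosity.tsv", sep="\t", index=False,
                     float_format="%.6g")
        th = config.thresholds
        regions = roh.contrast_candidate_regions(
            track, case_min=float(th.get("case_min", 0.7)),
            control_max=float(th.get("control_max", 0.2)),
            pad_bp=int(th.get("pad_bp", 0)), max_gap_bp=rohp.max_gap_bp)
        roh.regions_to_bed(regions, out / "candidate_regions.bed")
        burden = roh.roh_burden(segments, sample_ids=gm_qc.sample_ids)
        burden.to_csv(out / "roh_burden.tsv", sep="\t", index=False)
        report["roh"] = {
            "n_segments": len(segments),
            "regions": [{"chrom": r.chrom, "start_bp": r.start_bp,
                         "end_bp": r.end_bp,
                         "mean_case": r.mean_case_autozygosity,
                         "mean_control": r.mean_control_autozygosity}
                        for r in regions],
        }

        # ---- stage 5: segregation funnel ----------------------------------
        funnel_out = None
        if annotation is not None and wgs_gm is not None:
            if "region" in config.filter:
                region = segfilter.parse_region(config.filter["region"])
            elif regions:
                # the region supported by both lines of evidence: prefer the
                # autozygosity-contrast interval holding the most
                # genome-wide-significant SNPs, falling back to the interval
                # nearest the single strongest association signal
                sig_pos = scan.loc[scan["minus_log10_p"] >= thr, "pos"]
                top_pos = report["gwas"]["top_snp"]["pos"]

                def _n_sig(r):
                    return int(((sig_pos >= r.start_bp)
                                & (sig_pos <= r.end_bp)).sum())

                def _dist(r):
                    if r.start_bp <= top_pos <= r.end_bp:
                        return 0
                    return min(abs(r.start_bp - top_pos),
                               abs(r.end_bp - top_pos))

                best = (max(regions, key=_n_sig)
                        if any(_n_sig(r) for r in regions)
                        else min(regions, key=_dist))
                region = (best.chrom, best.start_bp, best.end_bp)
            else:
                chrom = str(wgs_gm.variants["chrom"].iloc[0])
                region = (chrom, 1, int(wgs_gm.variants["pos"].max()))
            if quality is not None:
                keep, sq_removed = gio.site_quality_filter(quality)
                wgs_f = wgs_gm.subset(variant_mask=keep)
                report["site_quality"] = sq_removed
            else:
                wgs_f = wgs_gm
            fc = segfilter.FilterConfig(
                region=region,
                excluded_cases=frozenset(config.filter.get("excluded_cases", [])),
                af_max=float(config.filter.get("af_max", 0.05)),
                consensus_rule=config.filter.get("consensus_rule", "all"))
            retained, retained_svs, funnel = segfilter.run_funnel(
                annotation, wgs_f, fc)
            retained.to_csv(out / "retained_variants.tsv", sep="\t",
                            index=False, float_format="%.6g")
            retained_svs.to_csv(out / "retained_svs.tsv", sep="\t",
                                index=False, float_format="%.6g")
            funnel_out = {"region": {"chrom": region[0], "start_bp": region[1],
                                     "end_bp": region[2]},
                          "stages": funnel.as_dict(),
                          "n_retained_svs": len(retained_svs)}
            with open(out / "funnel.json", "w") as jfh:
                json.dump(_jsonable(funnel_out), jfh, indent=2, sort_keys=True)
            report["funnel"] = funnel_out

            # ---- stage 6: validation statistics ---------------------------
            validation = []
            status = wgs_f.samples["status"].to_numpy()
            col_of = {(c, p, r, a): i for i, (c, p, r, a) in enumerate(
                zip(wgs_f.variants["chrom"], wgs_f.variants["pos"],
                    wgs_f.variants["ref"], wgs_f.variants["alt"]))}
            for _, vrow in retained.iterrows():
                colk = col_of.get((vrow["chrom"], vrow["pos"], vrow["ref"],
                                   vrow["alt"]))
                if colk is None:
                    continue
                table = stats.genotype_status_table(wgs_f.dosage[:, colk],
                                                    status)
                rr_aa = stats.relative_risk(table, "AA", "RR")
                rr_ar = stats.relative_risk(table, "AR", "RR")
                exact_p = stats.fisher_exact(table.to_numpy())
                pct = stats.cohort_percentages(table)
                validation.append({
                    "variant": f"{vrow['chrom']}:{vrow['pos']}"
                               f"{vrow['ref']}>{vrow['alt']}",
                    "gene": vrow.get("gene"),
                    "table": table.to_dict(),
                    "rr_hom_alt": rr_aa.rr, "rr_hom_alt_p": rr_aa.p_value,
                    "rr_het": rr_ar.rr, "rr_het_p": rr_ar.p_value,
                    "fisher_exact_p": exact_p,
                    "percentages": pct,
                })
            report["validation"] = validation

        with open(out / "report.json", "w") as jfh:
            json.dump(_jsonable(report), jfh, indent=2, sort_keys=True)
        return report
    finally:
        log.removeHandler(fh)
        fh.close()
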