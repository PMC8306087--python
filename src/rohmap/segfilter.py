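"""Candidate-variant filtering under a recessive segregation model.

Within the mapped candidate region, a causal recessive variant must be
homozygous for the alternative allele in every (non-excluded) affected
individual and never homozygous-alternative in an unaffected one; it must be
rare or absent in a large multi-breed reference panel (alternative allele
frequency below ``af_max``, with panel-absent i.e. novel variants passing);
and, for exonic missense variants, it should be called deleterious by the
in-silico predictors (SIFT, PROVEAN, PANTHER-PSEP, PolyPhen-2) under the
configured consensus rule. ``run_funnel`` applies the stages in order and
reports the surviving-variant count at each stage.

Structural variants (consequence ``SV-*``) flow through the same region,
homozygosity, segregation and frequency logic but skip the missense /
deleteriousness stages and are reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

CONSEQUENCES = ("intergenic", "intronic", "synonymous", "missense",
                "other-exonic", "SV-deletion", "SV-insertion")
EXONIC = ("synonymous", "missense", "other-exonic")


@dataclass
class DeleteriousnessCutoffs:
    sift_max: float = 0.05
    provean_max: float = -2.5
    panther_min: float = 0.5
    polyphen_min: float = 0.5


@dataclass
class FilterConfig:
    region: tuple[str, int, int]            # (chrom, start_bp, end_bp), 1-based closed
    excluded_cases: frozenset[str] = frozenset()
    af_max: float = 0.05
    cutoffs: DeleteriousnessCutoffs = field(default_factory=DeleteriousnessCutoffs)
    consensus_rule: str = "all"             # all | majority | any
    hom_stage_mode: str = "all"             # all | any non-excluded case
    strict_missing_controls: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.af_max <= 1:
            raise ValueError("af_max must be in [0, 1]")
        if self.consensus_rule not in ("all", "majority", "any"):
            raise ValueError(f"unknown consensus rule {self.consensus_rule!r}")
        if self.hom_stage_mode not in ("all", "any"):
            raise ValueError("hom_stage_mode must be 'all' or 'any'")
        self.excluded_cases = frozenset(self.excluded_cases)


def panel_af(hom_alt: float, het: float, hom_ref: float) -> float:
    """Alternative-allele frequency implied by panel genotype counts."""
    total = hom_alt + het + hom_ref
    if total <= 0:
        raise ValueError("panel counts sum to zero")
    return (2 * hom_alt + het) / (2 * total)


def segregation_pass(dosages: Mapping[str, int], case_ids: Sequence[str],
                     control_ids: Sequence[str],
                     excluded_cases: Iterable[str] = (),
                     strict_missing_controls: bool = False) -> bool:
    """Recessive segregation test at one variant.

    True iff every non-excluded case is homozygous for the alternative
    allele and no control is. A MISSING call in a non-excluded case fails;
    MISSING in a control is ignored by default (fails in strict mode).
    """
    excluded = set(excluded_cases)
    active_cases = [c for c in case_ids if c not in excluded]
    if not active_cases:
        raise ValueError("no cases left after exclusions")
    for cid in active_cases:
        if dosages.get(cid, MISSING) != 2:
            return False
    for cid in control_ids:
        d = dosages.get(cid, MISSING)
        if d == 2:
            return False
        if d == MISSING and strict_missing_controls:
            return False
    return True


def af_pass(variant: Mapping, af_max: float = 0.05) -> bool:
    """Population-frequency filter; panel-absent (novel) variants pass."""
    af = variant.get("panel_af")
    if af is None or (isinstance(af, float) and math.isnan(af)):
        counts = [variant.get(k) for k in ("panel_hom_alt", "panel_het",
                                           "panel_hom_ref")]
        if any(c is None or (isinstance(c, float) and math.isnan(c))
               for c in counts):
            return True  # novel: no reference-panel record
        af = panel_af(*counts)
    return af < af_max


@dataclass(frozen=True)
class ConsensusResult:
    passed: bool
    unscored: bool
    calls: dict

    def __bool__(self) -> bool:
        return self.passed


def deleterious_consensus(variant: Mapping,
                          cutoffs: DeleteriousnessCutoffs | None = None,
                          rule: str = "all") -> ConsensusResult:
    """Combine per-tool deleteriousness calls for a missense variant.

    SIFT <= sift_max, PROVEAN <= provean_max, PANTHER-PSEP >= panther_min and
    PolyPhen-2 >= polyphen_min each vote deleterious; tools without a score
    abstain. ``rule`` combines the votes of scoring tools ("all", "majority",
    or "any"); a variant with no scores at all is flagged unscored and fails.
    """
    if cutoffs is None:
        cutoffs = DeleteriousnessCutoffs()
    rules = {
        "sift": ("le", cutoffs.sift_max),
        "provean": ("le", cutoffs.provean_max),
        "panther_psep": ("ge", cutoffs.panther_min),
        "polyphen2": ("ge", cutoffs.polyphen_min),
    }
    calls: dict[str, bool] = {}
    for tool, (op, cut) in rules.items():
        score = variant.get(tool)
        if score is None or (isinstance(score, float) and math.isnan(score)):
            continue
        calls[tool] = score <= cut if op == "le" else score >= cut
    if not calls:
        return ConsensusResult(False, True, {})
    votes = list(calls.values())
    if rule == "all":
        passed = all(votes)
    elif rule == "any":
        passed = any(votes)
    else:
        passed = sum(votes) > len(votes) / 2
    return ConsensusResult(passed, False, calls)


@dataclass
class FunnelReport:
    """Ordered surviving-variant counts through the filter stages."""

    stages: list[tuple[str, int]]

    def __post_init__(self) -> None:
        counts = [c for _, c in self.stages]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("funnel counts must be non-increasing")

    def as_dict(self) -> dict[str, int]:
        return dict(self.stages)


_STAGE_ORDER = ["total_in_region", "homozygous_in_cases", "case_private",
                "rare_or_novel", "exonic", "missense", "deleterious"]


def run_funnel(variants: pd.DataFrame, gm: GenotypeMatrix,
               config: FilterConfig,
               ) -> tuple[pd.DataFrame, pd.DataFrame, FunnelReport]:
    """Apply the full candidate-variant funnel.

    ``variants`` is the annotation table (chrom, pos, ref, alt, consequence,
    gene, scores, panel counts); genotypes come from ``gm`` matched on
    (chrom, pos, ref, alt). Returns (retained small variants, retained
    structural variants, funnel report). Structural variants stop after the
    frequency stage and are reported separately.
    """
    chrom, start, end = config.region
    case_ids = [s for s, st, ex in zip(gm.samples["sample_id"],
                                       gm.samples["status"],
                                       gm.samples["excluded"])
                if st == "affected" and not ex]
    control_ids = [s for s, st, ex in zip(gm.samples["sample_id"],
                                          gm.samples["status"],
                                          gm.samples["excluded"])
                   if st == "unaffected" and not ex]
    col_of = {(c, p, r, a): i for i, (c, p, r, a) in enumerate(
        zip(gm.variants["chrom"], gm.variants["pos"],
            gm.variants["ref"], gm.variants["alt"]))}
    sample_ids = gm.sample_ids

    v = variants.copy().reset_index(drop=True)
    in_region = (v["chrom"].astype(str) == str(chrom)) \
        & (v["pos"] >= start) & (v["pos"] <= end)
    v = v[in_region].reset_index(drop=True)
    is_sv = v["consequence"].astype(str).str.startswith("SV-")

    def dosage_map(row) -> dict[str, int] | None:
        col = col_of.get((row["chrom"], row["pos"], row["ref"], row["alt"]))
        if col is None:
            return None
        return {sid: int(gm.dosage[j, col]) for j, sid in enumerate(sample_ids)}

    n0 = len(v)
    hom_mask = np.zeros(n0, dtype=bool)
    seg_mask = np.zeros(n0, dtype=bool)
    active_cases = [c for c in case_ids if c not in config.excluded_cases]
    if not active_cases:
        raise ValueError("no cases left after exclusions")
    for i in range(n0):
        dmap = dosage_map(v.iloc[i])
        if dmap is None:
            continue
        case_dos = [dmap.get(c, MISSING) for c in active_cases]
        if config.hom_stage_mode == "all":
            hom_mask[i] = all(d == 2 for d in case_dos)
        else:
            hom_mask[i] = any(d == 2 for d in case_dos)
        if hom_mask[i] or config.hom_stage_mode == "any":
            seg_mask[i] = segregation_pass(
                dmap, case_ids, control_ids, config.excluded_cases,
                config.strict_missing_controls)

    af_mask = np.array([af_pass(v.iloc[i].to_dict(), config.af_max)
                        for i in range(n0)], dtype=bool)
    exonic_mask = v["consequence"].isin(EXONIC).to_numpy()
    missense_mask = (v["consequence"] == "missense").to_numpy()
    delet_mask = np.array([
        bool(deleterious_consensus(v.iloc[i].to_dict(), config.cutoffs,
                                   config.consensus_rule))
        for i in range(n0)], dtype=bool)

    snv = ~is_sv.to_numpy()
    stages = [("total_in_region", int(snv.sum()))]
    keep = snv & hom_mask
    stages.append(("homozygous_in_cases", int(keep.sum())))
    keep &= seg_mask
    stages.append(("case_private", int(keep.sum())))
    keep &= af_mask
    stages.append(("rare_or_novel", int(keep.sum())))
    keep &= exonic_mask
    stages.append(("exonic", int(keep.sum())))
    keep &= missense_mask
    stages.append(("missense", int(keep.sum())))
    keep &= delet_mask
    stages.append(("deleterious", int(keep.sum())))

    sv_keep = is_sv.to_numpy() & hom_mask & seg_mask & af_mask
    retained = v[keep].reset_index(drop=True)
    retained_svs = v[sv_keep].reset_index(drop=True)
    return retained, retained_svs, FunnelReport(stages)


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse a region string of the form 'chrom:start-end' (1-based closed)."""
    try:
        chrom, span = text.split(":")
        start, end = span.replace(",", "").split("-")
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise ValueError(f"cannot parse region {text!r}; "
                         "expected chrom:start-end") from exc
    if start_i < 1 or end_i < start_i:
        raise ValueError(f"invalid region bounds in {text!r}")
    return chrom, start_i, end_i
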