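# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `rohmap`. It is the
design record for maintainers; the README covers usage.

## The mapping problem

The workflow targets one situation: a fully penetrant (or nearly so)
autosomal-recessive condition segregating in a small, closed, inbred
population, genotyped with a SNP array and/or whole-genome sequencing.
Affected individuals are expected to be identical by descent (IBD) across
the causal locus — both haplotypes copies of the single ancestral mutant
haplotype — which is observable as (i) a long run of homozygosity (ROH)
shared by cases and rare in controls, and (ii) an association signal that
survives correction for the strong family structure. Within the mapped
region, the causal variant must satisfy a recessive segregation pattern,
be rare in the broader species panel, and (if protein-coding) look
deleterious in silico.

## Genotype model and QC

Genotypes live in a samples × variants dosage matrix coded 0/1/2 (count of
the alternative allele) with −1 for missing; coordinates are 1-based and
inclusive everywhere, converted to 0-based half-open only on BED export.
Positions are non-decreasing within a chromosome (split multi-allelic
records share a position); (chrom, pos, ref, alt) keys are unique.

QC defaults follow the usual array workflow: variants kept with minor
allele frequency strictly above 0.05 and missing rate at most 0.1, then
samples kept with missing rate at most 0.1. WGS sites additionally pass a
depth ≥ 4 and calling-quality ≥ 20 filter; the thresholds are inclusive on
the keep side, reading "fewer than 4 reads" as excluding only < 4.
Panel intersection matches variants on (chrom, pos, ref, alt) and accepts
allele-swapped records by complementing dosages (0 ↔ 2).

The inbreeding coefficient is the method-of-moments homozygote excess
F = (O − E)/(m − E), with per-sample expected homozygosity
E = Σᵢ [1 − 2pᵢ(1−pᵢ)·nᵢ/(nᵢ−1)] over the sample's non-missing variants,
pᵢ the cohort allele frequency and nᵢ the count of genotyped samples at
variant i (the n/(n−1) small-sample correction matches the convention of
the standard tooling; variants with nᵢ < 2 are excluded). Frequencies use
all samples by default, with an option to restrict (e.g. controls only) —
the choice is not settled by convention and both are defensible in small
case/control cohorts.

PCA standardizes dosages per variant (missing imputed to the variant
mean) and takes scores from the SVD of the standardized matrix —
numerically stabler than, and identical to, eigendecomposition of the
sample covariance. Axis signs are fixed by making each component's
largest-magnitude loading positive. The GRM is the standardized form
G = (1/m) Σᵢ (xᵢ−2pᵢ)(xᵢ−2pᵢ)ᵀ/(2pᵢ(1−pᵢ)), missing imputed to 2pᵢ,
monomorphic variants skipped with a warning. Imputation is internal to
PCA/GRM and never written back.

## Mixed-model association

Case/control status is analyzed as a quantitative 0/1 trait under
y = Wα + xβ + g + ε, g ~ N(0, λτ⁻¹G), ε ~ N(0, τ⁻¹I) — a linear, not
logistic, mixed model, the standard fast choice for small cohorts. With
the eigendecomposition G = U S Uᵀ computed once, the restricted likelihood
at a trial λ is (up to a constant)
−½[ Σ log dᵢ + log|XᵀD⁻¹X| + (n−c) log yᵀPy ], dᵢ = λsᵢ + 1,
maximized over log₁₀λ ∈ [−5, 5] by a 21-point grid followed by bounded
Brent refinement. Ties within numerical tolerance resolve toward the
smallest λ, so a flat profile (no genetic variance) returns the lower
bound. λ is estimated once under the null and reused for every SNP
(score-test-like economy); per-SNP re-estimation is available behind a
flag but is slower and changes little.

Per SNP, β̂ and its standard error come from GLS in the rotated basis
(closed-form 2×2 normal equations for the default intercept-only design,
vectorized across SNPs), with σ̂² = RSS/(n−c−1) and the two-sided Wald
statistic β̂²/se² referred to F(1, n−c−1). SNPs with MAF < 0.01 or
missing rate > 0.05 are discarded before the scan (emulating the default
filtering of the common mixed-model tool); SNPs degenerate after rotation
are flagged and reported with p = 1. The Bonferroni threshold is
−log₁₀(α/m) with m passed explicitly, because published thresholds may use
the merged-panel size rather than the post-filter count. The QQ export
includes the genomic inflation factor median(χ²₁(p))/0.4549.

On a single chromosome with a small cohort, an (almost) perfectly
structure-confounded trait can drive λ̂ to the upper search bound and
produce unstable tail p-values; the default simulated cohort deliberately
includes unaffected relatives of the cases (below), which anchors the
signal at the causal locus through the within-family contrast — exactly
as real cohorts containing case relatives do.

## ROH detection, autozygosity contrast, burden

The caller is the classical scanning-window algorithm with five segment
criteria: window of 15 SNPs sliding one SNP at a time (windows truncated
at chromosome ends are dropped, and only fully contained windows enter the
hit-rate denominator); a window is homozygous when it has at most
`window_het_allow` hets (default 0 — 15-SNP windows are short, so the
common 1-het allowance would be disproportionately permissive) and at most
`window_missing_allow` missing calls (default 1); a SNP is eligible when
its hit rate is ≥ 0.05 (boundary passes) and its own call is not
heterozygous; maximal eligible runs are split at inter-SNP gaps > 1 Mb and
kept when they have ≥ 15 SNPs, span ≥ 1 Mb, and have inverse density
≤ 100 kb/SNP. The minimum-SNP criterion is applied both as the scanning
window size and as a per-segment minimum; the two are independently
configurable because the published wording conflates the two parameters of
the standard algorithm. Implementation detail: runs are extracted
vectorized across samples (break columns inserted at oversized gaps, run
boundaries from a flattened diff), which keeps exhaustive oracle
comparisons over hundreds of thousands of genotype strings cheap; tests
verify exact equivalence with a plain-loop reimplementation.

The autozygosity track is, per variant position and group, the fraction of
the group's samples with a covering ROH. Candidate regions are maximal
intervals where case autozygosity ≥ 0.7 and control autozygosity ≤ 0.2 at
every SNP, merged across sub-threshold gaps narrower than the ROH gap
limit, optionally padded (`pad_bp`) — the published region was widened
manually, so the widening is exposed as an explicit parameter. The
pipeline selects, among detected regions, the one holding the most
genome-wide-significant SNPs (falling back to the one nearest the top
SNP): the region supported by both lines of evidence. The ROH burden
summary counts per-sample segments above 2 Mb, the scale on which
affected animals in such populations exceed controls.

## Segregation, frequency and deleteriousness funnel

Within the candidate region, stages apply in order and report surviving
counts: (1) homozygous-alternative in every non-excluded case (a looser
"any case" mode exists behind a flag); (2) case-private — additionally no
control is homozygous-alternative; a missing call in a non-excluded case
fails the variant, missing control calls are ignored by default (strict
mode available; small cohorts make strictness expensive); (3) rare or
novel — reference-panel alternative-allele frequency < 0.05, computed as
(2·hom_alt + het)/(2·total) from panel genotype counts, with panel-absent
variants passing (the archetypal causal hit is a novel mutation and must
be retained); (4) exonic; (5) missense; (6) deleterious consensus. The
published control-side wording ("heterozygous or homozygous for the
alternative allele") is treated as an error for *reference* — the printed
control genotype counts (0 recessive homozygotes / 9 het / 2 hom-ref)
force that reading.

Per-tool deleteriousness calls are SIFT ≤ 0.05, PROVEAN ≤ −2.5,
PANTHER-PSEP ≥ 0.5, PolyPhen-2 ≥ 0.5, combined over the tools that have a
score by an `all` (default), `majority` or `any` rule; unscored variants
fail with a flag. The PROVEAN cutoff printed alongside the source scores
(−0.25) contradicts the tool's conventional −2.5; the default is −2.5 and
the cutoff is fully configurable. Structural variants flow through the
same region/segregation/frequency logic but skip the missense and
deleteriousness stages and are reported separately.

## Validation statistics

Relative risk between genotype rows (a,b) and (c,d) is
[a/(a+b)] / [c/(c+d)], with a Yates-continuity-corrected chi-square on
that 2×2 — the correction uses the |ad−bc| − n/2 form, which is the
convention that reproduces the published heterozygous p-values (0.07,
0.09); the uncorrected statistic gives ≈ 0.036 and does not. Exact tests:
2×2 via the hypergeometric two-sided rule (scipy), R×C via Freeman–Halton
full enumeration over fixed margins using log-factorials and the
probability-at-most-observed rule (tolerance 1e−7 on the log scale for
ties), with a seeded Monte Carlo permutation fallback when the enumeration
bound (10⁷ tables) is exceeded. Reported percentages are rounded to
integer percent for display; raw proportions are always retained.

## The synthetic-data generator

The generator reproduces the *data situation* of the study, not its
genome: one chromosome ("chr17") of 50 Mb at 1 cM/Mb, a 5,000-variant
WGS panel and a 2,500-SNP evenly spaced array panel (1% missingness).

**Population.** A case line founded by one pair and propagated by
branching full-sib matings for four generations — pedigree inbreeding
follows F_t = ¼(1 + 2F_{t−1} + F_{t−2}), reaching 0.5, the scale reported
for the study breed — and a control line of four founders crossed without
sib mating (no recent autozygosity). Line allele frequencies drift from a
shared ancestral frequency (uniform MAF on [0.05, 0.5]) under a
Balding–Nichols model with θ = 0.5 per line. The θ models many
generations of breed-level drift whose IBD segments are far shorter than
the ROH detection scale: it produces the observed *homozygote-excess* F
(≈ 0.5 cohort mean, higher in cases than controls) when measured against
cohort frequencies, without giving controls long ROH — matching the
study's seemingly paradoxical combination of control F ≈ 0.48 with
single-digit control autozygosity on the candidate chromosome. θ was
calibrated once against that reported F scale.

**Causal variant and phenotypes.** The causal allele sits on one case-line
founder haplotype at 8 Mb (novel: absent from the reference panel;
missense with concordantly deleterious scores). Affection is recessive
with penetrance 1.0 and phenocopy rate 0 by default; phenocopies are
labeled internally (never in emitted files) so exclusion mechanisms can be
tested. Gene drops use Haldane (no-interference) crossovers — interference
is irrelevant at Mb scales. Because a single founder copy is lost to
drift in a fair fraction of drops, the generator redraws the gene drop
with deterministic sub-seeds until at least `min_cases` affected
final-generation individuals exist: ascertainment, since a mapping study
exists only where the disease segregates. Output is byte-identical under a
fixed seed.

**Cohort.** 20 affected finals and 20 unaffected finals are sampled; 5
controls are unaffected relatives from the case line. Without related
controls, status coincides exactly with line membership and the mixed
model degenerates (λ̂ at the search bound, spurious top SNPs); with them,
the within-family contrast exists only at the causal region. Real cohorts
include case relatives among controls for the same reason.

**Annotation decoys.** Five "decoy" variants near the causal position sit
on the same founder haplotype — they segregate *perfectly* with the causal
variant and survive every genotype-based stage — but carry common
reference-panel frequencies (0.10–0.30), so only the frequency filter
removes them (the analog of the intronic cluster the study excluded on
panel frequency). Additional linked rare intronic variants, one linked
missense with discordant scores (deleterious by SIFT only), case-private
structural variants near the locus, and background variants with
consequence mix 55% intergenic / 30% intronic / 8% synonymous / 7%
missense complete the annotation table.

**What the generator does not emulate:** linkage disequilibrium within
founder haplotypes (sites are independent given line frequencies),
genotyping error beyond uniform missingness, multi-chromosome genomes
(supported only as repeated independent simulations), variable-depth
sequencing batches, and age-dependent penetrance.

## What passing tests show — and don't

The oracle tests show the ROH caller, GLS machinery and exact tests are
*correct* implementations of their definitions; the parameter-recovery
tests show the full workflow localizes and retains a planted recessive
variant under the default conditions (region recovery ≥ 95/100 seeds,
funnel retention ≥ 99/100, decoy removal 100/100, measured on 40-sample
cohorts with a 2,500-SNP array on one 50-Mb chromosome — sizes chosen so
the whole suite replays quickly on one CPU). They do not show robustness
to LD structure, genotyping batch effects, partial penetrance at
realistic rates, or phenotype misclassification beyond the single-
phenocopy exclusion mechanism tested explicitly.

On one 50-Mb chromosome, realized individual autozygosity has only a few
independent IBD segments, so marker F is a noisy estimate of pedigree F:
the rank correlation across the simulated population is ≈ 0.5 (rising
toward ≈ 0.8 when several independent chromosomes are combined), while
per-generation mean F is strictly monotone in pedigree F. The tests
assert the latter two properties; whole-genome data would tighten the
individual-level correlation, as in the source study.

## Numerical and degenerate-input choices

- REML grid 21 points on log₁₀λ ∈ [−5, 5]; Brent `xatol` 1e−6; λ ties
  break toward 0; non-PSD GRM (eigenvalue < −1e−6·max) is an error
  advising a diagonal jitter.
- Degenerate SNPs (zero variance after rotation, det ≤ eps) are flagged,
  β = 0, p = 1.
- p-values floor at 1e−300 before −log₁₀.
- Fisher enumeration counts tables with log-probability ≤ observed + 1e−7.
- Empty candidate-region funnel is a warning, not an error; an all-variant
  QC wipeout raises with the report attached.
- PED reference alleles without a supplied table: majority allele,
  lexicographic tie-break (deterministic); "0 0" is missing; affection
  column uses the 1=unaffected / 2=affected / 0,−9=unknown dialect.
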