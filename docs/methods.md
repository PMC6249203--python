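# Methods

## Problem setting

Induced pluripotent stem cell (iPSC) lines are clonal cultures derived by
reprogramming somatic cells — here skin fibroblasts — and their genetic
integrity must be verified before they are used as disease models or for
therapeutic work. The package implements the computational arm of such a QC
workflow for a biobank cohort in which each donor contributes a blood sample
(independent germline reference), a polyclonal fibroblast culture (the cell
of origin), several iPSC clones made with integrating retroviral (RiPSC) or
non-integrating Sendai (SiPSC) vectors, and optionally neuronal progenitor
cells (NPC) differentiated from RiPSC clones.

The central biological model is **drift, not selection**: a fibroblast
culture is a mosaic of subclones, each carrying its private somatic variants
at heterozygous allele fraction (AF) 0.5 within its cells, so the bulk
fibroblast AF of a variant is

    f_bulk = 0.5 * (sum of the proportions of carrying subclones).

Colony picking at reprogramming is a single-cell bottleneck: one subclone is
fixed with probability equal to its proportion, and its variants appear in
the resulting clone at AF ≈ 0.5 ("fixed somatic"). Variants in other
subclones, sequencing noise and culture sub-populations appear at lower AF
("low-frequency somatic"). No fitness advantage is modelled anywhere.

## Somatic classification

Candidate somatic variants in a cultured sample are derived by three rules:

1. **Hard germline subtraction** — any variant with at least
   `evidence_threshold` (default 1) alt reads in the donor's blood sample is
   treated as germline and removed. Sites whose blood coverage is below
   `min_blood_depth` (default 20 reads) are retained but flagged
   `evaluable=False`, because at such depth the absence of an alt read is
   weak evidence.
2. **Factor-locus exclusion** — calls inside the reprogramming-factor gene
   loci (POU5F1, SOX2, KLF4, MYC) are removed: in retrovirally reprogrammed
   clones the integrated vector contributes reads whose mismatches to the
   genomic locus masquerade as somatic variants.
3. **AF thresholding** — AF ≥ 0.30 (inclusive) is classified *fixed*,
   AF < 0.30 *low frequency*. The 0.30 bound sits ~3 binomial standard
   deviations below 0.5 at exome depths, so true heterozygous fixed variants
   are essentially never lost to read sampling. Low-frequency calls are
   reported but marked unvalidated; no orthogonal confirmation is modelled.

Group comparisons (RiPSC vs SiPSC counts, dosage groups) use the unpaired
two-sided Mann-Whitney U test by default; a paired Wilcoxon signed-rank
variant is exposed for matched designs. Pairwise dosage comparisons report
Benjamini-Hochberg adjusted p-values alongside raw ones.

## Binomial detectability model

Whether bulk fibroblast sequencing shows any read support for a variant at
bulk AF `f` and site coverage `c` is a binomial draw. With one supporting
read accepted as evidence,

    P(detected) = 1 - (1 - f)^c,

and the AF detectable at coverage `c` with probability `p` is the inverse,
`1 - (1-p)^(1/c)`. Both are generalised to an arbitrary evidence level `k`
(binomial survival function / numeric root) for sensitivity analysis; the
default `k=1` is the working model, and sequencing error is deliberately
*not* folded into it — the empirical detection rate is compared against the
pure binomial expectation. Variants with zero fibroblast coverage are
excluded from the empirical rate (no draw occurred) rather than counted as
undetected. The descriptive AF–coverage relation is an OLS fit of
fibroblast AF on log(coverage) with fibroblast-AF bins
{none, ≤5%, ≤10%, >10%}.

## Mutational spectra and the UV signature

SNVs are collapsed onto the pyrimidine reference strand (G>A ≡ C>T), giving
the six canonical classes; transitions are C>T and T>C. Cultures founded on
UV-damaged subclones — skin fibroblasts can carry ultraviolet damage —
show CC>TT dinucleotide MNPs at dipyrimidine sites and an excess of C>T
transitions. Because no canonical numeric threshold exists for "UV
enriched", the package defines

    uv_score = w1 * (CC>TT fraction of MNPs) + w2 * (C>T fraction of SNVs)

with default weights w1 = w2 = 0.5, and flags samples whose score exceeds
the 99th percentile (quantile method `higher`) of the scores of samples
known to carry no UV channel. Calibrating on the analyzed cohort's own
non-UV null bounds the null firing rate at 1% by construction. The
dipyrimidine-context check on MNPs is enforced only when a context table is
available (the synthetic truth provides one); plain VCF input lacks flanking
sequence and skips it with a warning.

Missense (MODERATE-impact) calls are partitioned against pathogenicity-score
cutoffs CADD = 20, M-CAP = 0.025, REVEL = 0.5, inclusive (≥) by default —
the boundary rule is configurable because conventions differ. Fixed
HIGH-impact calls are flagged when their gene is in the COSMIC cancer gene
census, an OMIM disease-gene list or a brain-elevated expression set, with
pLI annotated.

## Somatic CNVs

Copy-number segments arrive as SEG/BED tables (microarray-derived; no raw
intensity processing). A clone segment is somatic when it is ≥ 100 kb and no
same-direction fibroblast segment reaches 50% reciprocal overlap — a
standard concordance heuristic standing in for expert visual review, both
thresholds configurable. Aneuploidy is called when ≥ 90% of a chromosome's
length is at one non-neutral state (the 10% slack tolerates centromeric or
acrocentric gaps); a length-weighted clonal fraction < 1 is reported as
mosaic. Lineage comparison (parent clone vs derivative, or low vs high
passage) matches segments by state and 50% reciprocal overlap and classifies
them retained / fraction-shifted / lost / gained; a previously fixed parent
CNV found at ≈ 0.5 fraction in the derivative flags the parent culture as
oligoclonal. Recurrent regions are maximal sweep-line intervals covered by
segments from ≥ 2 distinct clones (independent reprogramming events; copy
states may mix). The sweep footprint equals the union of pairwise
intersections, which remains non-empty for chained overlaps where a strict
common intersection would vanish. Descriptive OLS fits regress mean CNV
count per individual-and-passage group on passage, and per-individual mean
count on donor age; size and gene-count group comparisons exclude segments
over 5 Mb as outliers.

## Coverage analytics

Mitochondrial dosage is the length-weighted mean chrM coverage divided by
the mean over chromosome-1 capture targets (targets only, not the whole
chromosome, so the normaliser shares the capture bias of the numerator).
The ratio is a per-cell mtDNA copy-number proxy that orders materials as
fibroblast ≈ iPSC > NPC ≈ blood.

Vector integration in RiPSC clones is detected from factor-locus coverage
shape. An intron-free insert adds exon-only coverage, so per factor gene the
detector computes: exon/intron contrast (ε = 0.5 reads added to the intron
mean), panel-normalised enrichment (factor exon mean over the mean of a
non-factor gene panel, which divides out capture enrichment; k extra insert
copies give enrichment ≈ 1 + k/2), and boundary sharpness (fractional depth
drop from exons to intron coverage within ±200 bp of exon edges,
overlap-weighted). A gene is called integrated only when contrast ≥ 10,
exon depth ≥ 10, enrichment ≥ 1.5 (≥ 1 extra haploid copy) and sharpness
≥ 0.7 all hold; the thresholds were calibrated on synthetic non-integrated
profiles so that Sendai/fibroblast samples are never flagged while ≥ 2
insert copies at 100× are reliably caught. Insert copy number is reported
only as the relative enrichment, not as a calibrated estimate.

## Tiered QC and line planning

Each line receives a three-tier verdict: karyotype (input flag), CMA
(aneuploidy and unbalanced rearrangements fail; sub-chromosomal somatic
CNVs warn by default, since lines carrying reported CNVs remain
distributable under the default policy), and exome (a fixed ∧ HIGH-impact ∧
listed-gene variant fails). Tiers without data are `not_assessed` and
excluded from the overall verdict; every fail carries machine-readable
reasons. With per-line pass probability `p`, the chance that at least one
of `n` lines passes is `1 - (1-p)^n`; the minimal `n` reaching a target is
computed from the log-ratio formula with explicit n−1/n/n+1 checks to avoid
floating-point boundary errors.

## Synthetic cohort generator

The generator emulates exactly the structure above on a small synthetic
exome: 2,000 capture targets of 150 bp spread over 22 autosomes + X
(12–25 Mb each) plus chrM, with factor and panel gene models (5 × 200 bp
exons, 2 kb introns split into 200 bp capture-shoulder flanks and deep
cores) placed in a reserved tail of each chromosome so ordinary somatic
variants never fall inside them. Defaults are the cohort conditions the
analysis is designed for:

| parameter | default | meaning |
|---|---|---|
| `mean_depth` | 163 | mean on-target coverage (reads) |
| `depth_dispersion` | 30 | negative-binomial size; var = μ + μ²/k |
| `seq_error` | 1e-4 | residual called false-evidence rate per read |
| `n_subclones_per_fibroblast` | 8 | Dirichlet(1) proportions |
| `lambda_mosaic` | 35 | mean somatic variants per subclone |
| `uv_subclone_prob` / `uv_mnp_fraction` / `uv_ct_boost` | 0.2 / 0.25 / 3.0 | UV channel |
| `lambda_passage` | 0.2 | new fixed variants per passage (kept small and configurable; passaging shows no strong effect and no published per-passage rate exists) |
| `cnv_lambda`, `cnv_size_range` | 1.3, (100 kb, 6.4 Mb) | log-uniform somatic CNV sizes |
| `oligoclonal_prob` | 0.1 | two-pick cultures, mixture 0.6–0.8 |
| `chrM_multiplier` | blood 0.8, fibroblast/iPSC 2.0, NPC 1.1 | dosage by material |
| `integration_copies` | (2, 8) | per-factor insert copies in RiPSC |

`seq_error` is the rate of *called* false evidence surviving a caller's
internal quality filtering, not the raw per-base error: under the hard
"any blood read excludes" rule, the raw rate (~1e-3) would strip ~15% of
true somatic variants at 163×, which is inconsistent with the recovery the
hard filter is meant to achieve. At 1e-4 the expected loss is ~1.6%.

One master seed drives per-stage substreams (cohort structure, read
sampling, coverage), so partial re-runs are reproducible and two runs with
the same seed emit byte-identical files.

What the generator does **not** model: sequence-level reads (no FASTQ,
alignment or mapping artifacts), CNV effects on SNV depths, selection during
culture, telomere attrition, contamination, and real genomic context (gene
names and positions are abstract). Passing tests therefore demonstrate the
correctness and calibration of the analysis logic under the stated
generative model, not performance on real sequencing data.

## Numerical choices and problem sizes

- AF threshold comparison is inclusive (≥ 0.30); score cutoffs inclusive by
  default; both configurable.
- `detection_probability` uses the closed form for k = 1 and the binomial
  survival function otherwise; `detectable_af` uses Brent root-finding with
  1e-12 tolerance when k > 1.
- Observations with zero total depth carry an undefined AF flag and are
  excluded from AF-based classification rather than dividing by zero.
- Calibration tests use cohorts sized for tight statistical margins at
  desk scale: 20 donors × 3 clones for detection-model agreement and
  classifier recovery, 50 + 50 profiles for the integration detector, and
  100 replicate simulations of small cohorts for the null behaviour of the
  rank tests.

## Known limitations

- Only the stated blood-evidence hard filter is implemented; production
  callers apply additional quality/strand filters that are not
  reconstructible from a text description.
- The recurrence detector reports chance-overlap candidates at small region
  counts; it flags recurrence, it does not test significance against a
  genomic background model.
- CNV clonal fractions are taken from input segments; nothing is estimated
  from intensity or log-ratio data.
- The UV flag threshold is cohort-calibrated, so it requires a reasonable
  number of non-UV samples to be meaningful.
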