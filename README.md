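# ipsc-integrity

Genetic-integrity analytics for iPSC biobanks.

Reprogramming a polyclonal fibroblast culture into induced pluripotent stem
cells (iPSC) passes the genome through a single-cell bottleneck: colony
picking randomly fixes one fibroblast subclone, so every clone carries
somatic variants absent from the donor's germline — most of them
pre-existing mosaicism of the culture of origin rather than reprogramming
damage. This package implements the computational QC workflow for such
cohorts, for stem-cell facilities and labs that must decide which clones are
safe to distribute:

- **Somatic classification** — germline subtraction against an independent
  blood sample (any blood read evidence excludes), exclusion of the
  reprogramming-factor loci (POU5F1, SOX2, KLF4, MYC), and allele-fraction
  thresholding: AF ≥ 0.30 → *fixed*, AF < 0.30 → *low frequency*.
- **Mosaicism detectability** — the binomial draw model
  P(detected) = 1 − (1 − f)^c for a variant at bulk fibroblast AF *f* and
  coverage *c*, its inverse (the AF detectable at coverage *c* with given
  probability), the empirical detection rate over fixed calls, and the
  AF ~ log(coverage) regression.
- **Mutational spectra** — impact / variant-type / six-class substitution
  partitions, the UV-damage signature (CC>TT dinucleotide MNPs at
  dipyrimidines plus C>T excess) with a null-calibrated flag, pathogenicity
  score partitions (CADD 20, M-CAP 0.025, REVEL 0.5), and flagging of fixed
  loss-of-function variants in cancer/disease/brain gene lists.
- **Somatic CNV drift** — ≥100 kb segments absent from the donor fibroblast
  (reciprocal-overlap rule), aneuploidy calls, lineage drift across
  passage/differentiation with oligoclonality detection, recurrence
  hotspots, and descriptive passage/age regressions.
- **Coverage analytics** — chrM/chr1 mitochondrial-dosage ratios with group
  comparisons, and reprogramming-vector integration detection from
  exon-intron coverage breaks at factor loci.
- **Tiered QC** — karyotype / CMA / exome verdicts with machine-readable
  reasons, and the line-planning calculus 1 − (1 − p)^n.
- **Synthetic cohorts** — a generator reproducing the clonal structure the
  analysis assumes (subclone mosaicism, clone picking as drift, binomial
  read sampling at ~163×, CNVs of 100 kb–6.4 Mb, material-specific chrM
  dosage, exon-only factor-locus coverage in retroviral clones), so the
  whole pipeline is testable without any external data.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
from ipsc_integrity import simulate as sm, somatic as so, mosaicism as mo, qc

config = sm.SimConfig(n_donors=2, seed=42)
truth, metas = sm.simulate_cohort(config)
observations = sm.sample_reads(truth)

calls = so.subtract_germline(observations, metas)
calls = so.exclude_factor_loci(calls, truth.genome.factor_regions)
calls = so.classify_calls(calls)

summary, group_test = so.summarize_somatic(calls, metas)
print(summary[["sample_id", "material", "n_fixed", "n_low_frequency"]])

detection = mo.empirical_detection_rate(
    [c for c in calls if c.somatic_class == "fixed"]
)
print(f"fibroblast detection rate: {detection.p_hat:.3f}")
print(f"detectable AF at 163x, p=0.426: {mo.detectable_af(163, 0.426):.5f}")
print(f"P(>=1 of 3 lines passes | p=0.639) = {qc.pass_probability(0.639, 3):.3f}")
```

prints

```
  sample_id   material  n_fixed  n_low_frequency
       fD01 fibroblast        0              315
       fD02 fibroblast        0              237
iD01-R1-001      RiPSC       38                3
iD01-R1-002      RiPSC       48               40
iD01-S1-001      SiPSC       46                4
iD02-R1-001      RiPSC       29                6
iD02-R1-002      RiPSC       40                6
iD02-S1-001      SiPSC       26                4
pD01-R1-001        NPC       42                3
pD02-R1-001        NPC       30                3
fibroblast detection rate: 0.923
detectable AF at 163x, p=0.426: 0.00340
P(>=1 of 3 lines passes | p=0.639) = 0.953
```

Each cultured clone carries a few dozen fixed somatic variants (heterozygous,
AF ≈ 0.5) and a tail of low-frequency calls; the fibroblast bulks show only
low-frequency mosaicism, and NPCs mirror their parent clones. The detection
rate says how many fixed variants had at least one supporting read in the
fibroblast; its binomial complement — the AF detectable at a given coverage —
quantifies how deeply the culture of origin was probed. The same workflow
runs from the shell:

```bash
ipsc-integrity simulate --seed 42 --out-dir cohort/
ipsc-integrity classify --vcf cohort/cohort.vcf --meta cohort/samples.tsv \
    --factor-bed cohort/factor_loci.bed --out-dir classify/
ipsc-integrity mosaicism --calls classify/somatic_calls.tsv --out-dir mosaicism/
ipsc-integrity cnv --segments cohort/segments.seg --meta cohort/samples.tsv --out-dir cnv/
ipsc-integrity coverage --coverage cohort/coverage.tsv --meta cohort/samples.tsv --out-dir coverage/
ipsc-integrity qc --p 0.639 --n 3 --target 0.9
```

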