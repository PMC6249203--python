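"""Synthetic donor-cohort generator.

Emulates the clonal structure the integrity analysis assumes: polyclonal
fibroblast cultures carrying subclonal somatic variants (some of them UV
mutagenized), single-colony picks at reprogramming that fix one subclone's
variants at heterozygous allele fraction 0.5, per-passage variant accrual,
binomial read sampling at exome-like depths, somatic CNVs, material-specific
mitochondrial dosage, and exon-only elevated coverage at reprogramming-factor
loci for retrovirally reprogrammed clones.

The genome is a small synthetic exome (default 2,000 capture targets over 24
nuclear chromosomes plus chrM), not a real reference: positions and gene names
are abstract, coordinates are desk-scale but CNV sizes are realistic.

Clone picking is pure drift: the probability a subclone is fixed equals its
proportion in the fibroblast culture; no fitness selection is modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as fio
from .types import (
    CnvSegment,
    CoverageInterval,
    CoverageProfile,
    FACTOR_GENES,
    IntegrityError,
    Locus,
    SampleMeta,
    VariantObservation,
)

# substream labels so each stage draws from an independent, reproducible stream
_STAGE_COHORT = 1
_STAGE_READS = 2
_STAGE_COVERAGE = 3

# pyrimidine-collapsed SNV class weights for non-UV somatic variants; C>T
# transitions dominate as in typical somatic exome spectra
BASE_SNV_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASE_SNV_WEIGHTS = (0.11, 0.09, 0.40, 0.07, 0.24, 0.09)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")
IMPACT_WEIGHTS = (0.08, 0.52, 0.32, 0.08)


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass
class SimConfig:
    """Generator parameters. Defaults are the cohort conditions the analysis
    is designed for: ~163x mean on-target depth, CNVs of 100 kb to 6.4 Mb,
    and a fixed-variant scale of a few dozen per clone."""

    n_donors: int = 4
    donor_ages: Optional[Sequence[float]] = None  # drawn 22-73y when None
    n_subclones_per_fibroblast: int = 8
    subclone_proportion_concentration: float = 1.0
    lambda_mosaic: float = 35.0  # mean exonic somatic variants per subclone
    uv_subclone_prob: float = 0.2
    uv_mnp_fraction: float = 0.25  # fraction of a UV subclone's variants that are CC>TT MNPs
    uv_ct_boost: float = 3.0  # multiplier on the C>T class weight in UV subclones
    lambda_passage: float = 0.2  # mean new fixed variants per passage
    mean_depth: float = 163.0
    depth_dispersion: float = 30.0  # negative-binomial size; larger = closer to Poisson
    min_depth: int = 0  # hard floor on sampled depths (0 = none)
    seq_error: float = 1e-4  # residual called false-evidence rate per read
    n_germline: int = 120  # germline variants per donor in the site universe
    germline_hom_fraction: float = 0.3
    cnv_lambda: float = 1.3  # mean somatic CNVs per clone
    cnv_size_range: tuple[int, int] = (100_000, 6_400_000)
    cnv_mosaic_prob: float = 0.2
    fibroblast_cnv_lambda: float = 1.0  # inherited (germline) CNVs per donor
    aneuploidy_prob: float = 0.04
    npc_fraction_shift_prob: float = 0.15
    vector_snv_lambda: float = 1.0  # vector-derived SNVs at factor loci per RiPSC
    chrM_multiplier: dict[str, float] = field(
        default_factory=lambda: {
            "blood": 0.8,
            "fibroblast": 2.0,
            "RiPSC": 2.0,
            "SiPSC": 2.0,
            "NPC": 1.1,
        }
    )
    chrm_noise_sigma: float = 0.25  # lognormal sd of per-sample dosage
    oligoclonal_prob: float = 0.1
    integration_copies: tuple[int, int] = (2, 8)  # per-factor insert copies in RiPSC
    n_ripsc: int = 2
    n_sipsc: int = 1
    n_npc: int = 1  # NPCs derived from the first RiPSC clones (<= n_ripsc)
    ripsc_passage_range: tuple[int, int] = (7, 15)
    sipsc_passage_range: tuple[int, int] = (3, 9)
    npc_passage_range: tuple[int, int] = (5, 13)
    n_targets: int = 2000
    target_length: int = 150
    seed: int = 0

    def validate(self) -> None:
        if self.n_subclones_per_fibroblast < 1:
            raise IntegrityError("need at least one fibroblast subclone")
        if self.n_donors < 1:
            raise IntegrityError("need at least one donor")
        for name in ("lambda_mosaic", "lambda_passage", "cnv_lambda", "mean_depth", "seq_error"):
            if getattr(self, name) < 0:
                raise IntegrityError(f"{name} must be >= 0")
        for name in ("uv_subclone_prob", "uv_mnp_fraction", "oligoclonal_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise IntegrityError(f"{name} must be in [0, 1]")
        if self.cnv_size_range[0] > self.cnv_size_range[1]:
            raise IntegrityError("cnv_size_range lower bound exceeds upper bound")


# ---------------------------------------------------------------------------
# Genome model
# ---------------------------------------------------------------------------

@dataclass
class GenomeModel:
    """Synthetic exome: chromosome lengths, capture targets and gene models."""

    chrom_lengths: dict[str, int]
    targets: list[tuple[str, int, int, str]]  # chrom, start, end, gene
    factor_regions: list[tuple[str, int, int, str]]  # whole-locus spans
    gene_models: dict[str, dict]  # gene -> {chrom, exons: [(s,e)], introns: [(s,e)]}
    panel_genes: list[str]  # non-factor genes used for coverage normalisation

    @property
    def nuclear_chroms(self) -> list[str]:
        return [c for c in self.chrom_lengths if c != "chrM"]


def build_genome(config: SimConfig) -> GenomeModel:
    chrom_lengths: dict[str, int] = {}
    for i in range(1, 23):
        chrom_lengths[f"chr{i}"] = int(25_000_000 - (i - 1) * 700_000)
    chrom_lengths["chrX"] = 20_000_000
    chrom_lengths["chrY"] = 6_000_000
    chrom_lengths["chrM"] = 16_569

    # capture targets over autosomes + chrX, proportional to length, kept in
    # the first 80% of each chromosome; gene loci (factor + panel) live in the
    # reserved tail so ordinary somatic variants never fall inside them
    variant_chroms = [f"chr{i}" for i in range(1, 23)] + ["chrX"]
    lengths = np.array([chrom_lengths[c] for c in variant_chroms], dtype=float)
    counts = np.maximum(1, np.round(config.n_targets * lengths / lengths.sum()).astype(int))
    targets = []
    gene_no = 0
    for chrom, n in zip(variant_chroms, counts):
        usable = int(0.8 * chrom_lengths[chrom])
        spacing = usable // (n + 1)
        for j in range(n):
            start = (j + 1) * spacing
            gene_no += 1
            targets.append((chrom, start, start + config.target_length, f"G{gene_no:04d}"))

    gene_models: dict[str, dict] = {}

    def place_gene(gene: str, chrom: str, anchor: int) -> None:
        # introns are split into exon-adjacent flanks (capture shoulder) and
        # a deep-intron core, so exon-edge coverage breaks are representable
        exons, flanks, cores = [], [], []
        pos = anchor
        for k in range(5):
            exons.append((pos, pos + 200))
            if k < 4:
                flanks.append((pos + 200, pos + 400))
                cores.append((pos + 400, pos + 2000))
                flanks.append((pos + 2000, pos + 2200))
            pos += 2200
        gene_models[gene] = {
            "chrom": chrom,
            "exons": exons,
            "intron_flanks": flanks,
            "intron_cores": cores,
        }

    factor_chroms = {"POU5F1": "chr6", "SOX2": "chr3", "KLF4": "chr9", "MYC": "chr8"}
    factor_regions = []
    for gene, chrom in factor_chroms.items():
        anchor = int(0.9 * chrom_lengths[chrom])
        place_gene(gene, chrom, anchor)
        span = (gene_models[gene]["exons"][0][0], gene_models[gene]["exons"][-1][1])
        factor_regions.append((chrom, span[0], span[1], gene))

    panel_genes = []
    for k in range(20):
        chrom = f"chr{(k % 20) + 1}"
        gene = f"PANEL{k + 1:02d}"
        place_gene(gene, chrom, int(0.85 * chrom_lengths[chrom]) + 40_000)
        panel_genes.append(gene)

    return GenomeModel(
        chrom_lengths=chrom_lengths,
        targets=targets,
        factor_regions=factor_regions,
        gene_models=gene_models,
        panel_genes=panel_genes,
    )


# ---------------------------------------------------------------------------
# Truth structures
# ---------------------------------------------------------------------------

@dataclass
class TruthVariant:
    uid: int
    locus: Locus
    gene: str
    impact: str
    scores: dict[str, float]
    origin: str  # germline | subclone | culture | vector
    subclone: Optional[int] = None
    fib_af: float = 0.0  # bulk fibroblast AF (mosaic variants only)
    germline_af: float = 0.0
    context: str = ""  # local context for UV MNPs (dipyrimidine tracking)
    is_uv_mnp: bool = False


@dataclass
class CloneTruth:
    sample_id: str
    picks: list[tuple[int, float]]  # (subclone index, mixing proportion)
    culture_variants: list[TruthVariant]
    vector_variants: list[TruthVariant]
    cnvs: list[CnvSegment]
    insert_copies: dict[str, int]  # factor gene -> integrated copies (0 = none)
    oligoclonal: bool
    chrm_dosage: float  # realised chrM/chr1 dosage multiplier


@dataclass
class DonorTruth:
    donor_id: str
    age: float
    germline: list[TruthVariant]
    subclone_proportions: np.ndarray
    subclone_is_uv: list[bool]
    subclone_variants: list[TruthVariant]
    fibroblast_cnvs: list[CnvSegment]
    clones: dict[str, CloneTruth] = field(default_factory=dict)
    sample_dosage: dict[str, float] = field(default_factory=dict)

    def all_variants(self) -> list[TruthVariant]:
        # NPC clones share variant objects with their parent; dedupe by uid
        seen: dict[int, TruthVariant] = {}
        for v in list(self.germline) + list(self.subclone_variants):
            seen[v.uid] = v
        for clone in self.clones.values():
            for v in clone.culture_variants + clone.vector_variants:
                seen[v.uid] = v
        return list(seen.values())


@dataclass
class TruthSet:
    config: SimConfig
    genome: GenomeModel
    donors: dict[str, DonorTruth]
    meta: dict[str, SampleMeta]

    # -- truth queries ------------------------------------------------------

    def donor_of(self, sample_id: str) -> DonorTruth:
        return self.donors[self.meta[sample_id].donor_id]

    def sample_afs(self, sample_id: str) -> dict[int, float]:
        """True allele fraction of every donor-universe variant in a sample."""
        meta = self.meta[sample_id]
        donor = self.donors[meta.donor_id]
        afs = {v.uid: 0.0 for v in donor.all_variants()}
        for v in donor.germline:
            afs[v.uid] = v.germline_af
        if meta.material == "blood":
            return afs
        if meta.material == "fibroblast":
            for v in donor.subclone_variants:
                afs[v.uid] = v.fib_af
            return afs
        # RiPSC/SiPSC/NPC all have their own CloneTruth; an NPC's culture
        # variant list already includes its parent clone's variants
        clone = donor.clones[sample_id]
        for sub, mix in clone.picks:
            for v in donor.subclone_variants:
                if v.subclone == sub:
                    afs[v.uid] = 0.5 * mix
        for v in clone.culture_variants:
            afs[v.uid] = 0.5
        for v in clone.vector_variants:
            afs[v.uid] = 0.5
        return afs

    def fixed_truth(self, sample_id: str) -> list[TruthVariant]:
        """Truth-fixed somatic variants of a clone: present in every cell
        (true AF 0.5), excluding germline and vector-derived records."""
        donor = self.donor_of(sample_id)
        by_uid = {v.uid: v for v in donor.all_variants()}
        afs = self.sample_afs(sample_id)
        return [
            by_uid[uid]
            for uid, af in afs.items()
            if af == 0.5 and by_uid[uid].origin in ("subclone", "culture")
        ]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
            "donors": {},
        }
        for donor_id, donor in self.donors.items():
            payload["donors"][donor_id] = {
                "age": donor.age,
                "subclone_proportions": [round(float(p), 6) for p in donor.subclone_proportions],
                "subclone_is_uv": donor.subclone_is_uv,
                "n_germline": len(donor.germline),
                "n_mosaic": len(donor.subclone_variants),
                "clones": {
                    cid: {
                        "picks": [[s, round(m, 4)] for s, m in c.picks],
                        "oligoclonal": c.oligoclonal,
                        "n_culture_variants": len(c.culture_variants),
                        "insert_copies": c.insert_copies,
                        "n_cnvs": len(c.cnvs),
                    }
                    for cid, c in donor.clones.items()
                },
            }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Variant drawing helpers
# ---------------------------------------------------------------------------

def _draw_snv_alleles(rng: np.random.Generator, ct_boost: float = 1.0) -> tuple[str, str]:
    """Draw a single-base ref/alt pair from the six-class spectrum, with an
    optional boost on the C>T class, emitted on a random strand."""
    weights = np.array(BASE_SNV_WEIGHTS, dtype=float)
    weights[BASE_SNV_CLASSES.index("C>T")] *= ct_boost
    weights /= weights.sum()
    cls = BASE_SNV_CLASSES[rng.choice(len(BASE_SNV_CLASSES), p=weights)]
    ref, alt = cls.split(">")
    if rng.random() < 0.5:  # purine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return ref, alt


def _draw_scores(rng: np.random.Generator, impact: str) -> dict[str, float]:
    if impact != "MODERATE":  # scores only meaningful for missense
        return {}
    return {
        "CADD": float(np.clip(rng.normal(19.0, 8.0), 0.0, 50.0)),
        "M-CAP": float(np.clip(rng.beta(1.2, 8.0), 0.0, 1.0)),
        "REVEL": float(np.clip(rng.beta(2.0, 4.0), 0.0, 1.0)),
    }


class _SitePlacer:
    """Places variants at unique positions inside capture targets."""

    def __init__(self, genome: GenomeModel, rng: np.random.Generator):
        self.genome = genome
        self.rng = rng
        self.used: set[tuple[str, int]] = set()

    def place(self) -> tuple[str, int, str]:
        for _ in range(1000):
            chrom, start, end, gene = self.genome.targets[
                self.rng.integers(len(self.genome.targets))
            ]
            pos = int(self.rng.integers(start, end - 2))
            if (chrom, pos) not in self.used and (chrom, pos + 1) not in self.used:
                self.used.add((chrom, pos))
                return chrom, pos, gene
        raise IntegrityError("could not place variant; synthetic exome saturated")


def draw_somatic_variant(
    placer: _SitePlacer,
    rng: np.random.Generator,
    uid: int,
    origin: str,
    uv: bool = False,
    force_mnp: bool = False,
    ct_boost: float = 1.0,
) -> TruthVariant:
    chrom, pos, gene = placer.place()
    impact = IMPACT_CLASSES[rng.choice(len(IMPACT_CLASSES), p=IMPACT_WEIGHTS)]
    if force_mnp:
        ref, alt = ("CC", "TT") if rng.random() < 0.5 else ("GG", "AA")
        placer.used.add((chrom, pos + 1))
        # track the dipyrimidine context (5' flank + the dinucleotide itself)
        flank = "TC"[rng.integers(2)] if ref == "CC" else "GA"[rng.integers(2)]
        context = flank + ref
        is_uv = True
    else:
        ref, alt = _draw_snv_alleles(rng, ct_boost=ct_boost if uv else 1.0)
        context = ""
        is_uv = False
        if rng.random() < 0.06:  # small indel channel
            ins = "ACGT"[rng.integers(4)]
            if rng.random() < 0.5:
                ref, alt = ref, ref + ins
            else:
                ref, alt = ref + ins, ref
    return TruthVariant(
        uid=uid,
        locus=Locus(chrom, pos, ref, alt),
        gene=gene,
        impact=impact,
        scores=_draw_scores(rng, impact),
        origin=origin,
        context=context,
        is_uv_mnp=is_uv,
    )


def _draw_cnv(
    rng: np.random.Generator,
    genome: GenomeModel,
    config: SimConfig,
    sample_id: str,
    mosaic_allowed: bool = True,
) -> CnvSegment:
    chrom = genome.nuclear_chroms[rng.integers(len(genome.nuclear_chroms) - 1)]  # skip chrY
    lo, hi = config.cnv_size_range
    size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    size = min(size, genome.chrom_lengths[chrom] - 2)
    start = int(rng.integers(0, genome.chrom_lengths[chrom] - size))
    n_genes = sum(
        1 for c, s, e, _ in genome.targets if c == chrom and s < start + size and e > start
    )
    fraction = 1.0
    if mosaic_allowed and rng.random() < config.cnv_mosaic_prob:
        fraction = float(rng.uniform(0.2, 0.7))
    return CnvSegment(
        chrom=chrom,
        start=start,
        end=start + size,
        copy_state="loss" if rng.random() < 0.5 else "gain",
        clonal_fraction=fraction,
        n_genes=n_genes,
        sample_id=sample_id,
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> tuple[TruthSet, list[SampleMeta]]:
    """Generate the truth set and sample sheet for a full synthetic cohort.

    Per donor: one blood sample (germline only), one polyclonal fibroblast
    bulk, ``n_ripsc`` retroviral and ``n_sipsc`` Sendai clones (each a random
    subclone pick, occasionally an oligoclonal two-pick mixture), and
    ``n_npc`` NPCs differentiated from the first RiPSC clones.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STAGE_COHORT])
    genome = build_genome(config)
    placer = _SitePlacer(genome, rng)

    donors: dict[str, DonorTruth] = {}
    metas: list[SampleMeta] = []
    uid = 0

    if config.donor_ages is not None:
        ages = list(config.donor_ages)
        if len(ages) != config.n_donors:
            raise IntegrityError("donor_ages length must equal n_donors")
    else:
        ages = [float(rng.integers(22, 74)) for _ in range(config.n_donors)]

    for d in range(config.n_donors):
        donor_id = f"D{d + 1:02d}"
        age = ages[d]
        blood_id, fib_id = f"b{donor_id}", f"f{donor_id}"
        metas.append(SampleMeta(blood_id, donor_id, "blood", donor_age=age))
        metas.append(SampleMeta(fib_id, donor_id, "fibroblast", donor_age=age))

        germline = []
        for _ in range(config.n_germline):
            v = draw_somatic_variant(placer, rng, uid, origin="germline")
            v.germline_af = 1.0 if rng.random() < config.germline_hom_fraction else 0.5
            germline.append(v)
            uid += 1

        k = config.n_subclones_per_fibroblast
        proportions = rng.dirichlet(np.full(k, config.subclone_proportion_concentration))
        is_uv = [bool(rng.random() < config.uv_subclone_prob) for _ in range(k)]
        subclone_variants = []
        for sub in range(k):
            n_vars = rng.poisson(config.lambda_mosaic)
            for _ in range(n_vars):
                mnp = is_uv[sub] and rng.random() < config.uv_mnp_fraction
                v = draw_somatic_variant(
                    placer,
                    rng,
                    uid,
                    origin="subclone",
                    uv=is_uv[sub],
                    force_mnp=mnp,
                    ct_boost=config.uv_ct_boost,
                )
                v.subclone = sub
                v.fib_af = 0.5 * float(proportions[sub])
                subclone_variants.append(v)
                uid += 1

        fibroblast_cnvs = [
            _draw_cnv(rng, genome, config, fib_id, mosaic_allowed=False)
            for _ in range(rng.poisson(config.fibroblast_cnv_lambda))
        ]

        donor = DonorTruth(
            donor_id=donor_id,
            age=age,
            germline=germline,
            subclone_proportions=proportions,
            subclone_is_uv=is_uv,
            subclone_variants=subclone_variants,
            fibroblast_cnvs=fibroblast_cnvs,
        )

        def make_clone(sample_id: str, material: str, passage: int) -> CloneTruth:
            nonlocal uid
            oligo = bool(rng.random() < config.oligoclonal_prob) and k >= 2
            if oligo:
                picks_idx = rng.choice(k, size=2, replace=False, p=proportions)
                mix = float(rng.uniform(0.6, 0.8))
                picks = [(int(picks_idx[0]), mix), (int(picks_idx[1]), 1.0 - mix)]
            else:
                picks = [(int(rng.choice(k, p=proportions)), 1.0)]
            culture = []
            for _ in range(rng.poisson(config.lambda_passage * passage)):
                culture.append(draw_somatic_variant(placer, rng, uid, origin="culture"))
                uid += 1
            vector = []
            insert_copies: dict[str, int] = {g: 0 for g in FACTOR_GENES}
            if material == "RiPSC":
                lo, hi = config.integration_copies
                for g in FACTOR_GENES:
                    insert_copies[g] = int(rng.integers(lo, hi + 1))
                for _ in range(rng.poisson(config.vector_snv_lambda)):
                    chrom, fstart, fend, gname = genome.factor_regions[
                        rng.integers(len(genome.factor_regions))
                    ]
                    pos = int(rng.integers(fstart, fend))
                    ref, alt = _draw_snv_alleles(rng)
                    vector.append(
                        TruthVariant(
                            uid=uid,
                            locus=Locus(chrom, pos, ref, alt),
                            gene=gname,
                            impact="MODIFIER",
                            scores={},
                            origin="vector",
                        )
                    )
                    uid += 1
            cnvs = list(fibroblast_cnvs)  # inherited from the culture of origin
            cnvs = [
                CnvSegment(c.chrom, c.start, c.end, c.copy_state, c.clonal_fraction, c.n_genes, sample_id)
                for c in cnvs
            ]
            for _ in range(rng.poisson(config.cnv_lambda)):
                cnvs.append(_draw_cnv(rng, genome, config, sample_id))
            if rng.random() < config.aneuploidy_prob:
                chrom = "chr12"
                cnvs.append(
                    CnvSegment(
                        chrom,
                        0,
                        genome.chrom_lengths[chrom],
                        "gain",
                        clonal_fraction=float(rng.uniform(0.4, 1.0)),
                        n_genes=sum(1 for c, *_ in genome.targets if c == chrom),
                        sample_id=sample_id,
                    )
                )
            return CloneTruth(
                sample_id=sample_id,
                picks=picks,
                culture_variants=culture,
                vector_variants=vector,
                cnvs=cnvs,
                insert_copies=insert_copies,
                oligoclonal=oligo,
                chrm_dosage=0.0,
            )

        ripsc_ids = []
        for r in range(config.n_ripsc):
            sid = f"i{donor_id}-R1-{r + 1:03d}"
            passage = int(rng.integers(*config.ripsc_passage_range))
            metas.append(SampleMeta(sid, donor_id, "RiPSC", passage, "retroviral", age, fib_id))
            donor.clones[sid] = make_clone(sid, "RiPSC", passage)
            ripsc_ids.append(sid)
        for s in range(config.n_sipsc):
            sid = f"i{donor_id}-S1-{s + 1:03d}"
            passage = int(rng.integers(*config.sipsc_passage_range))
            metas.append(SampleMeta(sid, donor_id, "SiPSC", passage, "sendai", age, fib_id))
            donor.clones[sid] = make_clone(sid, "SiPSC", passage)
        for n in range(min(config.n_npc, config.n_ripsc)):
            parent = ripsc_ids[n]
            sid = f"p{donor_id}-R1-{n + 1:03d}"
            passage = int(rng.integers(*config.npc_passage_range))
            metas.append(SampleMeta(sid, donor_id, "NPC", passage, "retroviral", age, parent))
            parent_clone = donor.clones[parent]
            culture = []
            for _ in range(rng.poisson(config.lambda_passage * passage)):
                culture.append(draw_somatic_variant(placer, rng, uid, origin="culture"))
                uid += 1
            npc_cnvs = [
                CnvSegment(c.chrom, c.start, c.end, c.copy_state, c.clonal_fraction, c.n_genes, sid)
                for c in parent_clone.cnvs
            ]
            if npc_cnvs and rng.random() < config.npc_fraction_shift_prob:
                j = int(rng.integers(len(npc_cnvs)))
                c = npc_cnvs[j]
                npc_cnvs[j] = CnvSegment(c.chrom, c.start, c.end, c.copy_state, 0.5, c.n_genes, sid)
            donor.clones[sid] = CloneTruth(
                sample_id=sid,
                picks=list(parent_clone.picks),
                culture_variants=parent_clone.culture_variants + culture,
                vector_variants=list(parent_clone.vector_variants),
                cnvs=npc_cnvs,
                insert_copies=dict(parent_clone.insert_copies),
                oligoclonal=parent_clone.oligoclonal,
                chrm_dosage=0.0,
            )

        for m in metas:
            if m.donor_id == donor_id:
                base = config.chrM_multiplier.get(m.material, 1.0)
                donor.sample_dosage[m.sample_id] = float(
                    base * rng.lognormal(0.0, config.chrm_noise_sigma)
                )

        donors[donor_id] = donor

    meta_map = {m.sample_id: m for m in metas}
    return TruthSet(config=config, genome=genome, donors=donors, meta=meta_map), metas


# ---------------------------------------------------------------------------
# Read sampling
# ---------------------------------------------------------------------------

def _draw_depths(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    """Over-dispersed depths: negative binomial with mean ``mean_depth`` and
    variance mean + mean^2/dispersion, floored at ``min_depth``."""
    k = config.depth_dispersion
    mu = config.mean_depth
    p = k / (k + mu)
    depths = rng.negative_binomial(k, p, size=n)
    if config.min_depth > 0:
        depths = np.maximum(depths, config.min_depth)
    return depths


def sample_reads(truth: TruthSet, config: Optional[SimConfig] = None) -> list[VariantObservation]:
    """Binomial read sampling of every donor-universe site in every sample.

    alt_depth ~ Binomial(total_depth, true AF); at non-carrier sites a
    residual false-evidence rate of ``seq_error`` per read applies, so blood
    and fibroblast samples can show spurious single-read support.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, _STAGE_READS])
    observations: list[VariantObservation] = []
    for donor in truth.donors.values():
        variants = donor.all_variants()
        sample_ids = [m for m in truth.meta.values() if m.donor_id == donor.donor_id]
        for meta in sample_ids:
            afs = truth.sample_afs(meta.sample_id)
            af_vec = np.array([afs[v.uid] for v in variants])
            af_vec = np.where(af_vec > 0.0, af_vec, config.seq_error)
            depths = _draw_depths(rng, len(variants), config)
            alts = rng.binomial(depths, af_vec)
            for v, dp, ad in zip(variants, depths, alts):
                observations.append(
                    VariantObservation(
                        locus=v.locus,
                        sample_id=meta.sample_id,
                        alt_depth=int(ad),
                        total_depth=int(dp),
                        impact=v.impact,
                        gene=v.gene,
                        scores=dict(v.scores),
                    )
                )
    return observations


# ---------------------------------------------------------------------------
# Coverage profiles
# ---------------------------------------------------------------------------

def simulate_coverage_profiles(
    truth: TruthSet, config: Optional[SimConfig] = None
) -> list[CoverageProfile]:
    """Capture-like coverage: enriched exons with shoulder-depth flanking
    introns, low anti-target depth, chrM bins scaled by material dosage, and
    exon-only additive coverage at factor loci proportional to integrated
    insert copies for retrovirally reprogrammed clones."""
    config = config or truth.config
    rng = np.random.default_rng([config.seed, _STAGE_COVERAGE])
    genome = truth.genome
    profiles = []
    chr1_targets = [t for t in genome.targets if t[0] == "chr1"][:30]
    chrm_bins = [(b * 2000, min((b + 1) * 2000, genome.chrom_lengths["chrM"])) for b in range(8)]

    for sample_id, meta in truth.meta.items():
        donor = truth.donors[meta.donor_id]
        clone = None
        if meta.material in ("RiPSC", "SiPSC"):
            clone = donor.clones.get(sample_id)
        elif meta.material == "NPC":
            clone = donor.clones.get(sample_id)
        profile = CoverageProfile(sample_id=sample_id)
        covered_genes = list(FACTOR_GENES) + genome.panel_genes
        for gene in covered_genes:
            model = genome.gene_models[gene]
            chrom = model["chrom"]
            gene_base = config.mean_depth * rng.lognormal(0.0, 0.05)
            extra = 0.0
            if clone is not None and gene in clone.insert_copies and clone.insert_copies[gene] > 0:
                # integrated intron-free insert: copies/2 extra relative to the
                # two genomic copies, confined to exons
                extra = gene_base * clone.insert_copies[gene] / 2.0
            for s, e in model["exons"]:
                depth = (gene_base + extra) * rng.lognormal(0.0, 0.05)
                profile.intervals.append(CoverageInterval(chrom, s, e, "exon", gene, depth))
            # capture shoulder decays off the probe; the insert adds nothing
            for s, e in model["intron_flanks"]:
                depth = 0.45 * gene_base * rng.lognormal(0.0, 0.10)
                profile.intervals.append(CoverageInterval(chrom, s, e, "intron", gene, depth))
            for s, e in model["intron_cores"]:
                depth = 0.05 * gene_base * rng.lognormal(0.0, 0.15)
                profile.intervals.append(CoverageInterval(chrom, s, e, "intron", gene, depth))
        for chrom, s, e, gene in chr1_targets:
            depth = config.mean_depth * rng.lognormal(0.0, 0.08)
            profile.intervals.append(CoverageInterval(chrom, s, e, "chr1_target", gene, depth))
        dosage = donor.sample_dosage[sample_id]
        for s, e in chrm_bins:
            depth = config.mean_depth * dosage * rng.lognormal(0.0, 0.05)
            profile.intervals.append(CoverageInterval("chrM", s, e, "chrM_bin", "", depth))
        # a little anti-target background
        profile.intervals.append(
            CoverageInterval("chr2", 100_000, 110_000, "anti_target", "",
                             0.02 * config.mean_depth * rng.lognormal(0.0, 0.2))
        )
        profiles.append(profile)
    return profiles


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def emit_cohort(
    truth: TruthSet,
    observations: Sequence[VariantObservation],
    out_dir: str | Path,
    profiles: Optional[Sequence[CoverageProfile]] = None,
) -> dict[str, Path]:
    """Write the cohort as the files the pipeline reads back: VCF, metadata
    TSV, SEG segments, factor-locus BED, coverage TSV and a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "meta": out / "samples.tsv",
        "segments": out / "segments.seg",
        "factor_bed": out / "factor_loci.bed",
        "coverage": out / "coverage.tsv",
        "truth": out / "truth.json",
    }
    sample_order = sorted(truth.meta)
    fio.write_multisample_vcf(
        observations, paths["vcf"], sample_order=sample_order, contigs=truth.genome.chrom_lengths
    )
    fio.write_sample_metadata(
        sorted(truth.meta.values(), key=lambda m: m.sample_id), paths["meta"]
    )
    segments = []
    for donor in truth.donors.values():
        segments.extend(donor.fibroblast_cnvs)
        for clone in donor.clones.values():
            segments.extend(clone.cnvs)
    fio.write_segments(segments, paths["segments"], dialect="seg")
    fio.write_bed_regions(truth.genome.factor_regions, paths["factor_bed"])
    if profiles is None:
        profiles = simulate_coverage_profiles(truth)
    fio.write_coverage(profiles, paths["coverage"])
    truth.to_json(paths["truth"])
    return paths
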