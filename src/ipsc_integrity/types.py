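"""Shared domain types for the iPSC genetic-integrity pipeline.

All genomic intervals are 0-based half-open internally; VCF positions are
converted on I/O. Every downstream module consumes these types rather than
re-parsing files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

VALID_BASES = set("ACGTN")

MATERIALS = ("blood", "fibroblast", "RiPSC", "SiPSC", "NPC")
METHODS = ("retroviral", "sendai", "none")
IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER", "unknown")
VAR_TYPES = ("SNV", "MNP", "indel")
COPY_STATES = ("loss", "gain", "neutral")
COVERAGE_ROLES = ("exon", "intron", "anti_target", "chrM_bin", "chr1_target")

#: Yamanaka reprogramming-factor genes whose loci are excluded from calling.
FACTOR_GENES = ("POU5F1", "SOX2", "KLF4", "MYC")


class IntegrityError(Exception):
    """Base class for pipeline errors."""


class FormatError(IntegrityError):
    """Malformed or unsupported input format."""


class IdentityError(IntegrityError):
    """Sample identity mismatch between files."""


class CoordinateError(IntegrityError):
    """Degenerate or inconsistent genomic coordinates."""


class PairingError(IntegrityError):
    """A required lineage partner (e.g. donor blood sample) is missing."""


class DomainError(IntegrityError):
    """Numeric argument outside its mathematical domain."""


def infer_var_type(ref: str, alt: str) -> str:
    """Classify an allele pair as SNV (1<->1), MNP (k<->k, k>1) or indel."""
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNP"
    return "indel"


@dataclass(frozen=True)
class Locus:
    """A variant coordinate. ``pos`` is 0-based internally (VCF pos - 1)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise CoordinateError(f"negative position {self.pos} on {self.chrom}")
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or not set(allele) <= VALID_BASES:
                raise FormatError(f"invalid {name} allele {allele!r} at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise FormatError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def var_type(self) -> str:
        return infer_var_type(self.ref, self.alt)


@dataclass
class VariantObservation:
    """One variant in one sample, with read support and annotations."""

    locus: Locus
    sample_id: str
    alt_depth: int
    total_depth: int
    impact: str = "unknown"
    gene: str = ""
    scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.alt_depth <= self.total_depth:
            raise FormatError(
                f"alt_depth {self.alt_depth} outside [0, total_depth={self.total_depth}] "
                f"for {self.sample_id} at {self.locus.chrom}:{self.locus.pos}"
            )
        if self.impact not in IMPACTS:
            self.impact = "unknown"

    @property
    def af(self) -> Optional[float]:
        """Alt allele fraction; None (undefined) when no reads cover the site."""
        if self.total_depth == 0:
            return None
        return self.alt_depth / self.total_depth

    @property
    def var_type(self) -> str:
        return self.locus.var_type


@dataclass
class SampleMeta:
    """Descriptor of one sequenced sample driving grouping and pairing."""

    sample_id: str
    donor_id: str
    material: str
    passage: Optional[int] = None
    method: str = "none"
    donor_age: float = 0.0
    parent_sample: Optional[str] = None

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise FormatError(f"unknown material {self.material!r} for {self.sample_id}")
        if self.method not in METHODS:
            raise FormatError(f"unknown method {self.method!r} for {self.sample_id}")
        if self.material == "blood" and self.parent_sample is not None:
            raise FormatError(f"blood sample {self.sample_id} must not have a parent")
        if self.passage is not None and self.passage < 0:
            raise FormatError(f"negative passage for {self.sample_id}")


def validate_lineage(metas: Sequence[SampleMeta]) -> None:
    """Check parent chains are acyclic and resolve within each donor."""
    by_id = {m.sample_id: m for m in metas}
    for m in metas:
        seen = {m.sample_id}
        cur = m
        while cur.parent_sample is not None:
            if cur.parent_sample not in by_id:
                raise PairingError(f"{cur.sample_id} has unknown parent {cur.parent_sample}")
            cur = by_id[cur.parent_sample]
            if cur.sample_id in seen:
                raise PairingError(f"cyclic parent chain at {cur.sample_id}")
            seen.add(cur.sample_id)
            if cur.donor_id != m.donor_id:
                raise PairingError(
                    f"{m.sample_id} (donor {m.donor_id}) resolves to sample of donor {cur.donor_id}"
                )


@dataclass
class CnvSegment:
    """A copy-number segment, 0-based half-open."""

    chrom: str
    start: int
    end: int
    copy_state: str
    clonal_fraction: float = 1.0
    n_genes: int = 0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise CoordinateError(
                f"degenerate segment {self.chrom}:{self.start}-{self.end}"
            )
        if self.copy_state not in COPY_STATES:
            raise FormatError(f"unknown copy state {self.copy_state!r}")
        if not 0.0 < self.clonal_fraction <= 1.0:
            raise FormatError(f"clonal_fraction {self.clonal_fraction} outside (0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CoverageInterval:
    chrom: str
    start: int
    end: int
    role: str
    gene: str
    mean_depth: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise CoordinateError(f"degenerate interval {self.chrom}:{self.start}-{self.end}")
        if self.role not in COVERAGE_ROLES:
            raise FormatError(f"unknown coverage role {self.role!r}")
        if self.mean_depth < 0:
            raise FormatError("negative mean depth")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageProfile:
    """Per-interval mean depths for one sample (dosage/integration analytics)."""

    sample_id: str
    intervals: list[CoverageInterval] = field(default_factory=list)

    def by_role(self, role: str) -> list[CoverageInterval]:
        return [iv for iv in self.intervals if iv.role == role]


@dataclass
class GeneAnnotationSet:
    """Curated gene lists used to flag fixed loss-of-function variants."""

    cgc: set[str] = field(default_factory=set)
    omim: dict[str, str] = field(default_factory=dict)
    brain_elevated: set[str] = field(default_factory=set)
    pli: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, value in self.pli.items():
            if not 0.0 <= value <= 1.0:
                raise FormatError(f"pLI for {gene} outside [0, 1]: {value}")

    def lists_hit(self, gene: str) -> set[str]:
        hits = set()
        if gene in self.cgc:
            hits.add("CGC")
        if gene in self.omim:
            hits.add("OMIM")
        if gene in self.brain_elevated:
            hits.add("HPA")
        return hits
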