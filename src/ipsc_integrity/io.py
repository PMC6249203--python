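"""Readers and writers for the external formats the pipeline consumes.

VCF is read with cyvcf2 (AD/DP or the freebayes AO/RO dialect); segments come
as SEG (1-based inclusive) or BED (0-based half-open) tables; metadata, gene
lists and coverage profiles are plain TSV. All coordinates are normalised to
0-based half-open on the way in.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    CnvSegment,
    CoordinateError,
    CoverageInterval,
    CoverageProfile,
    FormatError,
    GeneAnnotationSet,
    IdentityError,
    Locus,
    SampleMeta,
    VariantObservation,
    validate_lineage,
)

logger = logging.getLogger(__name__)

SCORE_INFO_KEYS = {"CADD": "CADD", "M-CAP": "MCAP", "REVEL": "REVEL"}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_multisample_vcf(
    path: str | Path,
    sample_meta: Sequence[SampleMeta] | Mapping[str, SampleMeta],
) -> list[VariantObservation]:
    """Read a multi-sample VCF into one VariantObservation per (variant, sample).

    Multiallelic records are decomposed into biallelic observations with
    per-allele depths taken verbatim (no left-alignment). Depths come from
    FORMAT AD/DP, or from the freebayes AO/RO dialect when AD is absent.
    """
    if isinstance(sample_meta, Mapping):
        meta_ids = set(sample_meta)
    else:
        meta_ids = {m.sample_id for m in sample_meta}
    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    unknown = [s for s in vcf_samples if s not in meta_ids]
    if unknown:
        raise IdentityError(f"VCF samples not in metadata: {', '.join(unknown)}")

    observations: list[VariantObservation] = []
    for record in vcf:
        alts = record.ALT
        if not alts:
            continue
        gene = record.INFO.get("GENE") or ""
        impact = record.INFO.get("IMPACT") or "unknown"
        scores = {}
        for name, key in SCORE_INFO_KEYS.items():
            value = record.INFO.get(key)
            if value is not None:
                scores[name] = float(value)

        def fmt(field):
            try:
                return record.format(field)
            except KeyError:
                return None

        ad = fmt("AD")
        dp = fmt("DP")
        ao = ro = None
        if ad is None:
            ao = fmt("AO")
            ro = fmt("RO")
            if ao is None or ro is None:
                raise FormatError(
                    f"record {record.CHROM}:{record.POS} lacks AD/DP and AO/RO depth fields"
                )

        for alt_index, alt in enumerate(alts):
            try:
                locus = Locus(record.CHROM, record.POS - 1, record.REF, alt)
            except FormatError:
                logger.warning("skipping non-ACGTN allele at %s:%d", record.CHROM, record.POS)
                continue
            for sample_index, sample_id in enumerate(vcf_samples):
                if ad is not None:
                    row = ad[sample_index]
                    alt_depth = int(row[alt_index + 1])
                    if dp is not None:
                        total = int(np.atleast_1d(dp[sample_index])[0])
                    else:
                        total = int(sum(max(int(x), 0) for x in row))
                else:
                    alt_depth = int(np.atleast_1d(ao[sample_index])[alt_index])
                    ref_depth = int(np.atleast_1d(ro[sample_index])[0])
                    if dp is not None:
                        total = int(np.atleast_1d(dp[sample_index])[0])
                    else:
                        total = ref_depth + int(np.atleast_1d(ao[sample_index]).sum())
                alt_depth = max(alt_depth, 0)
                total = max(total, alt_depth)
                observations.append(
                    VariantObservation(
                        locus=locus,
                        sample_id=sample_id,
                        alt_depth=alt_depth,
                        total_depth=total,
                        impact=impact,
                        gene=gene,
                        scores=dict(scores),
                    )
                )
    return observations


def write_multisample_vcf(
    observations: Iterable[VariantObservation],
    path: str | Path,
    sample_order: Optional[Sequence[str]] = None,
    contigs: Optional[Mapping[str, int]] = None,
) -> None:
    """Write observations as a site x sample VCF 4.2 with AD/DP FORMAT fields.

    Sites absent for a sample are written as AD=.,. DP=. (missing). Annotation
    (gene/impact/scores) is carried in INFO, site-level.
    """
    obs_list = list(observations)
    if sample_order is None:
        sample_order = sorted({o.sample_id for o in obs_list})
    by_site: dict[tuple, dict[str, VariantObservation]] = {}
    for o in obs_list:
        key = (o.locus.chrom, o.locus.pos, o.locus.ref, o.locus.alt)
        by_site.setdefault(key, {})[o.sample_id] = o

    def chrom_rank(chrom: str) -> tuple:
        name = chrom.removeprefix("chr")
        return (0, int(name)) if name.isdigit() else (1, name)

    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=IMPACT,Number=1,Type=String,Description="Predicted impact class">',
        '##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD phred score">',
        '##INFO=<ID=MCAP,Number=1,Type=Float,Description="M-CAP score">',
        '##INFO=<ID=REVEL,Number=1,Type=Float,Description="REVEL score">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
    ]
    if contigs:
        for chrom in sorted(contigs, key=chrom_rank):
            lines.append(f"##contig=<ID={chrom},length={contigs[chrom]}>")
    else:
        for chrom in sorted({k[0] for k in by_site}, key=chrom_rank):
            lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_order)
    )

    for key in sorted(by_site, key=lambda k: (chrom_rank(k[0]), k[1], k[2], k[3])):
        chrom, pos, ref, alt = key
        per_sample = by_site[key]
        any_obs = next(iter(per_sample.values()))
        info_parts = []
        if any_obs.gene:
            info_parts.append(f"GENE={any_obs.gene}")
        if any_obs.impact != "unknown":
            info_parts.append(f"IMPACT={any_obs.impact}")
        for name, infokey in SCORE_INFO_KEYS.items():
            if name in any_obs.scores:
                info_parts.append(f"{infokey}={any_obs.scores[name]:.4f}")
        info = ";".join(info_parts) if info_parts else "."
        fields = [chrom, str(pos + 1), ".", ref, alt, ".", "PASS", info, "AD:DP"]
        for sample_id in sample_order:
            o = per_sample.get(sample_id)
            if o is None:
                fields.append(".,.:.")
            else:
                fields.append(f"{o.total_depth - o.alt_depth},{o.alt_depth}:{o.total_depth}")
        lines.append("\t".join(fields))

    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Segments (SEG / BED)
# ---------------------------------------------------------------------------

SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "copy_state", "clonal_fraction", "n_genes"]


def read_segments(
    path: str | Path,
    sample_id: Optional[str] = None,
    dialect: str = "seg",
) -> list[CnvSegment]:
    """Read CNV segments from a tab-separated table.

    ``dialect='seg'`` means 1-based inclusive input coordinates, ``'bed'``
    means 0-based half-open; both are normalised to 0-based half-open.
    A leading ``sample_id`` column is optional; when absent, ``sample_id``
    (the argument) is assigned to every segment, otherwise it filters.
    Missing ``clonal_fraction`` defaults to 1.0, missing ``n_genes`` to 0.
    """
    if dialect not in ("seg", "bed"):
        raise FormatError(f"unknown segment dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    has_sample = "sample_id" in cols
    required = {"chrom", "start", "end", "copy_state"}
    if not required <= set(cols):
        raise FormatError(f"segment table missing columns {sorted(required - set(cols))}")

    segments = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        row_sample = getattr(row, "sample_id", None) if has_sample else None
        if has_sample and sample_id is not None and row_sample != sample_id:
            continue
        start = int(str(row.start).replace(",", ""))
        end = int(str(row.end).replace(",", ""))
        if dialect == "seg":
            start -= 1  # 1-based inclusive -> 0-based half-open
        if start >= end:
            raise CoordinateError(f"{path} line {line_no}: degenerate segment after normalization")
        fraction = getattr(row, "clonal_fraction", None)
        n_genes = getattr(row, "n_genes", None)
        segments.append(
            CnvSegment(
                chrom=row.chrom,
                start=start,
                end=end,
                copy_state=row.copy_state,
                clonal_fraction=1.0 if fraction is None or pd.isna(fraction) else float(fraction),
                n_genes=0 if n_genes is None or pd.isna(n_genes) else int(float(n_genes)),
                sample_id=row_sample if row_sample is not None else (sample_id or ""),
            )
        )
    return segments


def write_segments(segments: Iterable[CnvSegment], path: str | Path, dialect: str = "seg") -> None:
    """Write segments in SEG (1-based inclusive) or BED-like (half-open) dialect."""
    if dialect not in ("seg", "bed"):
        raise FormatError(f"unknown segment dialect {dialect!r}")
    rows = []
    for seg in segments:
        start = seg.start + 1 if dialect == "seg" else seg.start
        rows.append(
            {
                "sample_id": seg.sample_id,
                "chrom": seg.chrom,
                "start": start,
                "end": seg.end,
                "copy_state": seg.copy_state,
                "clonal_fraction": round(seg.clonal_fraction, 4),
                "n_genes": seg.n_genes,
            }
        )
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

META_COLUMNS = ["sample_id", "donor_id", "material", "passage", "method", "donor_age", "parent_sample"]


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    metas = []
    for row in df.itertuples(index=False):
        passage = getattr(row, "passage", None)
        parent = getattr(row, "parent_sample", None)
        metas.append(
            SampleMeta(
                sample_id=row.sample_id,
                donor_id=row.donor_id,
                material=row.material,
                passage=None if passage is None or pd.isna(passage) or passage == "" else int(float(passage)),
                method=getattr(row, "method", "none") or "none",
                donor_age=float(getattr(row, "donor_age", 0.0) or 0.0),
                parent_sample=None if parent is None or pd.isna(parent) or parent == "" else parent,
            )
        )
    validate_lineage(metas)
    return metas


def write_sample_metadata(metas: Iterable[SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "donor_id": m.donor_id,
            "material": m.material,
            "passage": "" if m.passage is None else m.passage,
            "method": m.method,
            "donor_age": m.donor_age,
            "parent_sample": m.parent_sample or "",
        }
        for m in metas
    ]
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------

def read_gene_lists(
    cgc: Optional[str | Path] = None,
    omim: Optional[str | Path] = None,
    brain_elevated: Optional[str | Path] = None,
    pli: Optional[str | Path] = None,
) -> GeneAnnotationSet:
    """Load curated gene lists.

    ``cgc`` and ``brain_elevated`` are one-symbol-per-line lists; ``omim`` is a
    two-column TSV (gene, phenotype); ``pli`` is a two-column TSV (gene, pLI).
    Duplicate symbols are deduplicated.
    """

    def read_symbols(p) -> set[str]:
        return {
            line.strip()
            for line in Path(p).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        }

    annotation = GeneAnnotationSet()
    if cgc is not None:
        annotation.cgc = read_symbols(cgc)
    if brain_elevated is not None:
        annotation.brain_elevated = read_symbols(brain_elevated)
    if omim is not None:
        for line in Path(omim).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            annotation.omim[parts[0].strip()] = parts[1].strip() if len(parts) > 1 else ""
    if pli is not None:
        for line_no, line in enumerate(Path(pli).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"pLI file line {line_no}: expected two columns")
            try:
                value = float(parts[1])
            except ValueError as exc:
                raise FormatError(f"pLI file line {line_no}: unreadable value {parts[1]!r}") from exc
            annotation.pli[parts[0].strip()] = value
    return GeneAnnotationSet(
        cgc=annotation.cgc,
        omim=annotation.omim,
        brain_elevated=annotation.brain_elevated,
        pli=annotation.pli,
    )


# ---------------------------------------------------------------------------
# Coverage profiles
# ---------------------------------------------------------------------------

COVERAGE_COLUMNS = ["sample_id", "chrom", "start", "end", "role", "gene", "mean_depth"]


def read_coverage(path: str | Path) -> list[CoverageProfile]:
    df = pd.read_csv(path, sep="\t", comment="#")
    profiles: dict[str, CoverageProfile] = {}
    for row in df.itertuples(index=False):
        profile = profiles.setdefault(row.sample_id, CoverageProfile(sample_id=row.sample_id))
        gene = getattr(row, "gene", "")
        profile.intervals.append(
            CoverageInterval(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                role=row.role,
                gene="" if pd.isna(gene) else str(gene),
                mean_depth=float(row.mean_depth),
            )
        )
    return list(profiles.values())


def write_coverage(profiles: Iterable[CoverageProfile], path: str | Path) -> None:
    rows = []
    for profile in profiles:
        for iv in profile.intervals:
            rows.append(
                {
                    "sample_id": profile.sample_id,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "role": iv.role,
                    "gene": iv.gene,
                    "mean_depth": round(iv.mean_depth, 4),
                }
            )
    pd.DataFrame(rows, columns=COVERAGE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Factor-locus BED
# ---------------------------------------------------------------------------

def read_bed_regions(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a BED file of (chrom, start, end, name) regions, half-open."""
    regions = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path} line {line_no}: expected >=3 BED columns")
        start, end = int(parts[1]), int(parts[2])
        if start >= end:
            raise CoordinateError(f"{path} line {line_no}: degenerate BED interval")
        regions.append((parts[0], start, end, parts[3] if len(parts) > 3 else ""))
    return regions


def write_bed_regions(regions: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    lines = ["\t".join((chrom, str(start), str(end), name)) for chrom, start, end, name in regions]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(
    results: Mapping[str, object],
    out_dir: str | Path,
    seed: Optional[int] = None,
    config: Optional[Mapping[str, object]] = None,
) -> list[Path]:
    """Write deterministic TSV/JSON reports.

    DataFrames become ``<name>.tsv`` (fixed column order, floats at 4
    decimals, a ``#`` header block echoing seed and config); dicts/lists
    become ``<name>.json`` with sorted keys. Same inputs produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header_lines = []
    if seed is not None:
        header_lines.append(f"# seed: {seed}")
    if config:
        header_lines.append("# config: " + json.dumps(config, sort_keys=True, default=str))
    written = []
    for name in sorted(results):
        value = results[name]
        if isinstance(value, pd.DataFrame):
            target = out / f"{name}.tsv"
            body = value.to_csv(sep="\t", index=False, float_format="%.4f")
            target.write_text("".join(f"{line}\n" for line in header_lines) + body)
        else:
            target = out / f"{name}.json"
            target.write_text(json.dumps(value, indent=2, sort_keys=True, default=str) + "\n")
        written.append(target)
    return written
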