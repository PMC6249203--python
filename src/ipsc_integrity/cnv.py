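"""Somatic CNV calling against the parental fibroblast, aneuploidy detection,
lineage drift, recurrence hotspots and descriptive regressions.

A clone segment is *somatic* when it is at least ``min_size`` (default
100 kb) long and has no same-direction fibroblast segment with reciprocal
overlap of 50% or more ("present in the culture of origin"). Aneuploidy is
called when >=90% of a chromosome's length carries a non-neutral state.
Recurrent regions are maximal genomic intervals where segments from at least
two independent reprogramming events overlap, copy states mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .somatic import rank_test
from .types import CnvSegment, DomainError, PairingError, SampleMeta

MIN_SOMATIC_SIZE = 100_000
SIZE_OUTLIER_BP = 5_000_000  # segments above this are excluded from size/gene panels


def reciprocal_overlap(a: CnvSegment, b: CnvSegment) -> float:
    """Min of the two overlap fractions; 0 when chromosomes differ."""
    if a.chrom != b.chrom:
        return 0.0
    overlap = min(a.end, b.end) - max(a.start, b.start)
    if overlap <= 0:
        return 0.0
    return min(overlap / a.length, overlap / b.length)


@dataclass
class SomaticCnv:
    segment: CnvSegment
    donor_id: str
    absent_in_fibroblast: bool = True
    derived_from: str = ""  # lineage note, e.g. the fibroblast sample id


@dataclass
class RecurrentRegion:
    chrom: str
    start: int
    end: int
    supporting_clones: set[str] = field(default_factory=set)
    donors: set[str] = field(default_factory=set)
    copy_states: set[str] = field(default_factory=set)


def call_somatic_cnvs(
    clone_segments: Sequence[CnvSegment],
    fibroblast_segments: Sequence[CnvSegment],
    donor_id: str = "",
    min_size: int = MIN_SOMATIC_SIZE,
    overlap_rule: float = 0.5,
    fibroblast_id: str = "",
) -> list[SomaticCnv]:
    """Clone segments >= min_size with no same-direction fibroblast segment at
    reciprocal overlap >= overlap_rule are emitted as somatic."""
    somatic = []
    for seg in clone_segments:
        if seg.length < min_size:
            continue
        present = any(
            fib.copy_state == seg.copy_state
            and reciprocal_overlap(seg, fib) >= overlap_rule
            for fib in fibroblast_segments
        )
        if not present:
            somatic.append(
                SomaticCnv(segment=seg, donor_id=donor_id, derived_from=fibroblast_id)
            )
    return somatic


def call_cohort_somatic_cnvs(
    segments: Sequence[CnvSegment],
    sample_meta: Sequence[SampleMeta] | Mapping[str, SampleMeta],
    min_size: int = MIN_SOMATIC_SIZE,
    overlap_rule: float = 0.5,
) -> list[SomaticCnv]:
    """Pair every cultured clone with its donor fibroblast and call somatic
    CNVs across the whole cohort."""
    metas = (
        dict(sample_meta)
        if isinstance(sample_meta, Mapping)
        else {m.sample_id: m for m in sample_meta}
    )
    fibroblast_by_donor = {
        m.donor_id: m.sample_id for m in metas.values() if m.material == "fibroblast"
    }
    by_sample: dict[str, list[CnvSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    out: list[SomaticCnv] = []
    for sample_id, segs in sorted(by_sample.items()):
        meta = metas.get(sample_id)
        if meta is None or meta.material in ("blood", "fibroblast"):
            continue
        fib_id = fibroblast_by_donor.get(meta.donor_id)
        if fib_id is None:
            raise PairingError(f"clone {sample_id} has no donor fibroblast segments source")
        out.extend(
            call_somatic_cnvs(
                segs,
                by_sample.get(fib_id, []),
                donor_id=meta.donor_id,
                min_size=min_size,
                overlap_rule=overlap_rule,
                fibroblast_id=fib_id,
            )
        )
    return out


def detect_aneuploidy(
    segments: Sequence[CnvSegment],
    chrom_lengths: Mapping[str, int],
    chromosome_fraction: float = 0.9,
) -> pd.DataFrame:
    """Whole-chromosome gain/loss: >=90% of the chromosome length at one
    non-neutral state. A length-weighted clonal fraction < 1 is reported as
    mosaic aneuploidy."""
    rows = []
    by_sample: dict[str, list[CnvSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    for sample_id, segs in sorted(by_sample.items()):
        for chrom, length in chrom_lengths.items():
            for state in ("gain", "loss"):
                relevant = [s for s in segs if s.chrom == chrom and s.copy_state == state]
                covered = sum(s.length for s in relevant)
                if covered >= chromosome_fraction * length:
                    fraction = sum(s.clonal_fraction * s.length for s in relevant) / covered
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "chrom": chrom,
                            "state": state,
                            "call": "trisomy" if state == "gain" else "monosomy",
                            "clonal_fraction": round(fraction, 4),
                            "mosaic": fraction < 0.999,
                        }
                    )
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "state", "call", "clonal_fraction", "mosaic"]
    )


def compare_lineage(
    parent_cnvs: Sequence[CnvSegment],
    derivative_cnvs: Sequence[CnvSegment],
    fraction_shift_min: float = 0.3,
    overlap_rule: float = 0.5,
) -> dict:
    """Classify parent CNVs as retained / fraction_shifted / lost in a
    derivative (e.g. NPC vs its RiPSC, or high vs low passage), and
    derivative-only CNVs as gained. A previously fixed parent CNV shifting to
    a ~50% fraction flags culture oligoclonality."""
    matched_deriv: set[int] = set()
    records = []
    oligoclonal = False
    for p in parent_cnvs:
        match = None
        for j, d in enumerate(derivative_cnvs):
            if j in matched_deriv or d.copy_state != p.copy_state:
                continue
            if reciprocal_overlap(p, d) >= overlap_rule:
                match = (j, d)
                break
        if match is None:
            records.append({"chrom": p.chrom, "start": p.start, "end": p.end,
                            "copy_state": p.copy_state, "status": "lost",
                            "fraction_parent": p.clonal_fraction, "fraction_derivative": None})
            continue
        j, d = match
        matched_deriv.add(j)
        shifted = abs(p.clonal_fraction - d.clonal_fraction) >= fraction_shift_min
        status = "fraction_shifted" if shifted else "retained"
        if shifted and p.clonal_fraction >= 0.9 and abs(d.clonal_fraction - 0.5) <= 0.1:
            oligoclonal = True
        records.append({"chrom": p.chrom, "start": p.start, "end": p.end,
                        "copy_state": p.copy_state, "status": status,
                        "fraction_parent": p.clonal_fraction,
                        "fraction_derivative": d.clonal_fraction})
    for j, d in enumerate(derivative_cnvs):
        if j not in matched_deriv:
            records.append({"chrom": d.chrom, "start": d.start, "end": d.end,
                            "copy_state": d.copy_state, "status": "gained",
                            "fraction_parent": None, "fraction_derivative": d.clonal_fraction})
    counts = {"retained": 0, "fraction_shifted": 0, "lost": 0, "gained": 0}
    for r in records:
        counts[r["status"]] += 1
    return {"records": records, "counts": counts, "oligoclonality_flag": oligoclonal}


def find_recurrent_regions(
    somatic_cnvs: Sequence[SomaticCnv],
    min_supporters: int = 2,
) -> list[RecurrentRegion]:
    """Maximal intervals where >=2 somatic CNVs from independent reprogramming
    events (distinct clone samples) overlap; copy states may mix.

    Implemented as a sweep over segment endpoints: the reported footprint is
    the union of pairwise intersections, which stays non-empty for chained
    overlaps where the strict common intersection would vanish.
    """
    by_chrom: dict[str, list[SomaticCnv]] = {}
    for cnv in somatic_cnvs:
        by_chrom.setdefault(cnv.segment.chrom, []).append(cnv)
    regions: list[RecurrentRegion] = []
    for chrom, cnvs in sorted(by_chrom.items()):
        points = sorted({c.segment.start for c in cnvs} | {c.segment.end for c in cnvs})
        current: Optional[RecurrentRegion] = None
        for left, right in zip(points[:-1], points[1:]):
            covering = [
                c for c in cnvs if c.segment.start <= left and c.segment.end >= right
            ]
            clones = {c.segment.sample_id for c in covering}
            if len(clones) >= min_supporters:
                if current is not None and current.end == left:
                    current.end = right
                    current.supporting_clones |= clones
                    current.donors |= {c.donor_id for c in covering}
                    current.copy_states |= {c.segment.copy_state for c in covering}
                else:
                    current = RecurrentRegion(
                        chrom=chrom,
                        start=left,
                        end=right,
                        supporting_clones=set(clones),
                        donors={c.donor_id for c in covering},
                        copy_states={c.segment.copy_state for c in covering},
                    )
                    regions.append(current)
            else:
                current = None
    return regions


def recurrent_frame(regions: Sequence[RecurrentRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_clones": len(r.supporting_clones),
                "clones": ",".join(sorted(r.supporting_clones)),
                "donors": ",".join(sorted(r.donors)),
                "copy_states": ",".join(sorted(r.copy_states)),
            }
            for r in regions
        ]
    )


def cnv_regressions(
    somatic_cnvs: Sequence[SomaticCnv],
    sample_meta: Sequence[SampleMeta] | Mapping[str, SampleMeta],
    size_outlier_bp: int = SIZE_OUTLIER_BP,
    paired: bool = False,
) -> dict:
    """Descriptive fits and group comparisons.

    OLS of the mean somatic CNV count (aggregated per individual and passage
    group) on passage number, and of the per-individual mean count on donor
    age; unpaired rank comparisons of count / size / gene count between
    retroviral and Sendai clones, with segments above the size outlier cut
    excluded from the size and gene panels.
    """
    metas = (
        dict(sample_meta)
        if isinstance(sample_meta, Mapping)
        else {m.sample_id: m for m in sample_meta}
    )
    clones = [m for m in metas.values() if m.material in ("RiPSC", "SiPSC")]
    counts = {m.sample_id: 0 for m in clones}
    for cnv in somatic_cnvs:
        sid = cnv.segment.sample_id
        if sid in counts:
            counts[sid] += 1

    frame = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "donor_id": m.donor_id,
                "material": m.material,
                "passage": m.passage,
                "age": m.donor_age,
                "n_cnvs": counts[m.sample_id],
            }
            for m in clones
        ]
    )

    def ols_fit(x: np.ndarray, y: np.ndarray) -> dict:
        if len(x) < 3:
            raise DomainError("need >= 3 aggregation units for the regression")
        model = sm.OLS(y, sm.add_constant(x)).fit()
        ci = model.conf_int()
        return {
            "n": int(len(x)),
            "slope": float(model.params[1]),
            "intercept": float(model.params[0]),
            "slope_ci": (float(ci[1][0]), float(ci[1][1])),
            "r_squared": float(model.rsquared),
            "pvalue": float(model.f_pvalue),
        }

    by_passage = (
        frame.dropna(subset=["passage"])
        .groupby(["donor_id", "passage"], as_index=False)["n_cnvs"]
        .mean()
    )
    passage_fit = ols_fit(
        by_passage["passage"].to_numpy(dtype=float), by_passage["n_cnvs"].to_numpy(dtype=float)
    )
    by_age = frame.groupby("donor_id", as_index=False).agg(
        age=("age", "first"), n_cnvs=("n_cnvs", "mean")
    )
    age_fit = ols_fit(by_age["age"].to_numpy(dtype=float), by_age["n_cnvs"].to_numpy(dtype=float))

    r_counts = frame.loc[frame.material == "RiPSC", "n_cnvs"].tolist()
    s_counts = frame.loc[frame.material == "SiPSC", "n_cnvs"].tolist()
    comparisons = {"count": rank_test(r_counts, s_counts, paired=paired)}
    sizes = {"RiPSC": [], "SiPSC": []}
    genes = {"RiPSC": [], "SiPSC": []}
    for cnv in somatic_cnvs:
        meta = metas.get(cnv.segment.sample_id)
        if meta is None or meta.material not in sizes:
            continue
        if cnv.segment.length > size_outlier_bp:
            continue  # outlier excluded from size/gene panels
        sizes[meta.material].append(cnv.segment.length)
        genes[meta.material].append(cnv.segment.n_genes)
    for name, data in (("size", sizes), ("gene_count", genes)):
        if data["RiPSC"] and data["SiPSC"]:
            comparisons[name] = rank_test(data["RiPSC"], data["SiPSC"], paired=False)
        else:
            comparisons[name] = {"test": None, "statistic": None, "pvalue": None}

    return {
        "per_clone": frame,
        "passage_fit": passage_fit,
        "age_fit": age_fit,
        "group_comparisons": comparisons,
    }
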