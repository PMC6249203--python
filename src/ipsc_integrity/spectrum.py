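"""Mutational type, impact and signature spectra of somatic calls.

SNVs are collapsed to the pyrimidine reference strand (G>A counts as C>T),
yielding the six canonical substitution classes; transitions are C>T and
T>C. The UV-damage signature is scored from the fraction of MNPs that are
CC>TT dinucleotide changes at dipyrimidines (GG>AA after strand collapse)
together with the C>T excess among SNVs; samples are flagged UV-enriched
against a null-calibrated threshold because no canonical numeric cutoff
exists for this score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .somatic import SomaticCall
from .types import GeneAnnotationSet

logger = logging.getLogger(__name__)

SNV_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TRANSITIONS = ("C>T", "T>C")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SCORE_CUTOFFS = {"CADD": 20.0, "M-CAP": 0.025, "REVEL": 0.5}
PYRIMIDINES = set("CT")


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def collapse_snv(ref: str, alt: str) -> str:
    """Pyrimidine-strand substitution class of a single-base change."""
    if ref in "GA":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def is_cc_tt(ref: str, alt: str) -> bool:
    """CC>TT dinucleotide MNP, counting the GG>AA strand equivalent."""
    return (ref, alt) == ("CC", "TT") or (ref, alt) == ("GG", "AA")


@dataclass
class SpectrumSummary:
    """Per-sample counts along the impact / type / substitution axes."""

    sample_id: str
    impact_counts: dict[str, int] = field(default_factory=dict)
    type_counts: dict[str, int] = field(default_factory=dict)
    snv_spectrum: dict[str, int] = field(default_factory=lambda: {c: 0 for c in SNV_CLASSES})
    transitions: int = 0
    transversions: int = 0
    mnp_cc_tt_count: int = 0
    n_calls: int = 0

    @property
    def spectrum_fractions(self) -> dict[str, float]:
        total = sum(self.snv_spectrum.values())
        if total == 0:
            return {c: 0.0 for c in SNV_CLASSES}
        return {c: n / total for c, n in self.snv_spectrum.items()}


def partition_spectrum(calls: Iterable[SomaticCall]) -> dict[str, SpectrumSummary]:
    """Count calls per sample by impact group, variant type and (for SNVs)
    pyrimidine-collapsed substitution class."""
    summaries: dict[str, SpectrumSummary] = {}
    for call in calls:
        s = summaries.setdefault(call.sample_id, SpectrumSummary(sample_id=call.sample_id))
        s.n_calls += 1
        impact = call.obs.impact
        if impact == "unknown":
            logger.warning(
                "call with unknown impact at %s:%d", call.locus.chrom, call.locus.pos
            )
        s.impact_counts[impact] = s.impact_counts.get(impact, 0) + 1
        vt = call.obs.var_type
        s.type_counts[vt] = s.type_counts.get(vt, 0) + 1
        if vt == "SNV":
            cls = collapse_snv(call.locus.ref, call.locus.alt)
            s.snv_spectrum[cls] += 1
            if cls in TRANSITIONS:
                s.transitions += 1
            else:
                s.transversions += 1
        elif vt == "MNP" and is_cc_tt(call.locus.ref, call.locus.alt):
            s.mnp_cc_tt_count += 1
    return summaries


def spectrum_frame(summaries: Mapping[str, SpectrumSummary]) -> pd.DataFrame:
    rows = []
    for sample_id in sorted(summaries):
        s = summaries[sample_id]
        row = {
            "sample_id": sample_id,
            "n_calls": s.n_calls,
            "transitions": s.transitions,
            "transversions": s.transversions,
            "mnp_cc_tt": s.mnp_cc_tt_count,
        }
        for impact in ("HIGH", "MODERATE", "LOW", "MODIFIER", "unknown"):
            row[f"impact_{impact}"] = s.impact_counts.get(impact, 0)
        for vt in ("SNV", "MNP", "indel"):
            row[f"type_{vt}"] = s.type_counts.get(vt, 0)
        for cls in SNV_CLASSES:
            row[f"snv_{cls}"] = s.snv_spectrum[cls]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# UV signature
# ---------------------------------------------------------------------------

def uv_scores(
    calls: Iterable[SomaticCall],
    weights: tuple[float, float] = (0.5, 0.5),
    contexts: Optional[Mapping[tuple[str, int], str]] = None,
) -> pd.DataFrame:
    """Per-sample UV score: w1 * (CC>TT fraction of MNPs) + w2 * (C>T fraction
    of SNVs).

    When a context table (chrom, pos) -> local sequence is supplied (synthetic
    truth provides one), CC>TT MNPs are only counted at dipyrimidine
    contexts; without context the check is skipped with a warning, since VCF
    alleles alone carry no flanking sequence.
    """
    w1, w2 = weights
    if contexts is None:
        logger.warning("no context table; dipyrimidine check skipped for CC>TT MNPs")
    per_sample: dict[str, dict[str, int]] = {}
    for call in calls:
        d = per_sample.setdefault(
            call.sample_id, {"mnp": 0, "cc_tt": 0, "snv": 0, "c_t": 0}
        )
        vt = call.obs.var_type
        if vt == "MNP":
            d["mnp"] += 1
            if is_cc_tt(call.locus.ref, call.locus.alt):
                if contexts is not None:
                    ctx = contexts.get((call.locus.chrom, call.locus.pos), "")
                    # the pyrimidine pair itself must appear in the recorded
                    # local context (either strand); otherwise not UV-type
                    if "CC" not in ctx and "GG" not in ctx:
                        continue
                d["cc_tt"] += 1
        elif vt == "SNV":
            d["snv"] += 1
            if collapse_snv(call.locus.ref, call.locus.alt) == "C>T":
                d["c_t"] += 1
    rows = []
    for sample_id in sorted(per_sample):
        d = per_sample[sample_id]
        mnp_fraction = d["cc_tt"] / d["mnp"] if d["mnp"] else 0.0
        ct_fraction = d["c_t"] / d["snv"] if d["snv"] else 0.0
        rows.append(
            {
                "sample_id": sample_id,
                "n_mnp": d["mnp"],
                "n_cc_tt": d["cc_tt"],
                "n_snv": d["snv"],
                "n_c_t": d["c_t"],
                "cc_tt_fraction": mnp_fraction,
                "c_t_fraction": ct_fraction,
                "uv_score": w1 * mnp_fraction + w2 * ct_fraction,
            }
        )
    return pd.DataFrame(rows)


def uv_threshold_from_null(null_scores: Sequence[float], q: float = 0.99) -> float:
    """Null-calibrated UV flag threshold: the q-quantile (method='higher') of
    UV scores from samples known to carry no UV channel, so that strictly
    greater scores fire on at most (1-q) of the null by construction."""
    scores = np.asarray(list(null_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("empty null score set")
    return float(np.quantile(scores, q, method="higher"))


def flag_uv(score_table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    out = score_table.copy()
    out["uv_flag"] = out["uv_score"] > threshold
    return out


# ---------------------------------------------------------------------------
# Classifier-score partition
# ---------------------------------------------------------------------------

def score_partition(
    missense_calls: Iterable[SomaticCall],
    cutoffs: Mapping[str, float] = SCORE_CUTOFFS,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Fraction of missense calls at or above each pathogenicity cutoff
    (CADD 20, M-CAP 0.025, REVEL 0.5 by default). Calls missing a score are
    excluded per score axis; the boundary rule defaults to inclusive (>=)."""
    values: dict[str, list[float]] = {name: [] for name in cutoffs}
    for call in missense_calls:
        for name in cutoffs:
            value = call.obs.scores.get(name)
            if value is not None:
                values[name].append(float(value))
    rows = []
    for name, cutoff in cutoffs.items():
        vals = np.asarray(values[name], dtype=float)
        if vals.size == 0:
            logger.warning("no %s scores present", name)
            above = 0
        else:
            above = int(np.sum(vals >= cutoff) if inclusive else np.sum(vals > cutoff))
        rows.append(
            {
                "score": name,
                "cutoff": cutoff,
                "n_total": int(vals.size),
                "n_above": above,
                "fraction_above": above / vals.size if vals.size else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene-list flagging
# ---------------------------------------------------------------------------

@dataclass
class FlaggedVariant:
    """A fixed loss-of-function variant in a curated gene list."""

    sample_id: str
    gene: str
    consequence: str
    lists_hit: set[str]
    pli: Optional[float]


def flag_listed_genes(
    fixed_calls: Iterable[SomaticCall],
    annotation: GeneAnnotationSet,
) -> list[FlaggedVariant]:
    """Retain fixed HIGH-impact calls whose gene hits at least one curated
    list (CGC cancer census, OMIM disease genes, HPA brain-elevated)."""
    flagged = []
    for call in fixed_calls:
        if call.somatic_class != "fixed" or call.obs.impact != "HIGH":
            continue
        hits = annotation.lists_hit(call.obs.gene)
        if not hits:
            continue
        flagged.append(
            FlaggedVariant(
                sample_id=call.sample_id,
                gene=call.obs.gene,
                consequence=f"{call.locus.ref}>{call.locus.alt}",
                lists_hit=hits,
                pli=annotation.pli.get(call.obs.gene),
            )
        )
    flagged.sort(key=lambda f: (f.sample_id, f.gene))
    return flagged


def flagged_frame(flagged: Sequence[FlaggedVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": f.sample_id,
                "gene": f.gene,
                "consequence": f.consequence,
                "lists_hit": ",".join(sorted(f.lists_hit)),
                "pli": f.pli,
            }
            for f in flagged
        ]
    )
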