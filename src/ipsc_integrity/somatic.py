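"""Somatic small-variant classification against an independent germline sample.

Candidate somatic variants in a cultured sample are derived by hard germline
subtraction (any read evidence in the donor's blood excludes a site),
exclusion of the reprogramming-factor gene loci, and allele-fraction
thresholding: AF >= 0.30 is called *fixed* (carried by essentially all cells
of the clone), AF < 0.30 *low frequency*. Low-frequency calls are reported
but flagged unvalidated; no orthogonal confirmation is modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from .types import (
    DomainError,
    Locus,
    PairingError,
    SampleMeta,
    VariantObservation,
)

logger = logging.getLogger(__name__)

FIXED_THRESHOLD = 0.30


@dataclass
class SomaticCall:
    """A candidate somatic variant in one cultured sample, with the matched
    blood and fibroblast read support used for filtering and mosaicism."""

    obs: VariantObservation
    donor_id: str
    blood_alt_depth: int
    blood_total_depth: int
    fibroblast_alt_depth: int = 0
    fibroblast_total_depth: int = 0
    somatic_class: Optional[str] = None  # fixed | low_frequency
    evaluable: bool = True  # blood depth adequate for confident subtraction

    @property
    def sample_id(self) -> str:
        return self.obs.sample_id

    @property
    def locus(self) -> Locus:
        return self.obs.locus

    @property
    def af(self) -> Optional[float]:
        return self.obs.af


def subtract_germline(
    observations: Iterable[VariantObservation],
    sample_meta: Sequence[SampleMeta] | Mapping[str, SampleMeta],
    evidence_threshold: int = 1,
    min_blood_depth: int = 20,
) -> list[SomaticCall]:
    """Hard-filter culture variants against the donor's blood sample.

    A variant with ``blood alt reads >= evidence_threshold`` is removed; a
    variant whose blood coverage is below ``min_blood_depth`` is retained but
    flagged ``evaluable=False`` (high sampling variance, not invalid).
    Culture observations with zero alt reads are never emitted. Fibroblast
    depths at the same locus are attached when available.
    """
    if evidence_threshold < 1:
        raise DomainError("evidence_threshold must be >= 1")
    metas = (
        dict(sample_meta)
        if isinstance(sample_meta, Mapping)
        else {m.sample_id: m for m in sample_meta}
    )
    blood_by_donor: dict[str, str] = {}
    fibroblast_by_donor: dict[str, str] = {}
    for m in metas.values():
        if m.material == "blood":
            blood_by_donor[m.donor_id] = m.sample_id
        elif m.material == "fibroblast":
            fibroblast_by_donor[m.donor_id] = m.sample_id

    obs_list = list(observations)
    depth_index: dict[tuple[str, Locus], tuple[int, int]] = {
        (o.sample_id, o.locus): (o.alt_depth, o.total_depth) for o in obs_list
    }

    calls: list[SomaticCall] = []
    for o in obs_list:
        meta = metas.get(o.sample_id)
        if meta is None or meta.material == "blood":
            continue
        if o.alt_depth == 0:
            continue
        donor = meta.donor_id
        if donor not in blood_by_donor:
            raise PairingError(
                f"donor {donor} has no blood sample; germline subtraction impossible"
            )
        blood_ad, blood_dp = depth_index.get((blood_by_donor[donor], o.locus), (0, 0))
        if blood_ad >= evidence_threshold:
            continue  # read evidence in blood: treated as germline
        fib_ad, fib_dp = (0, 0)
        if donor in fibroblast_by_donor and meta.material != "fibroblast":
            fib_ad, fib_dp = depth_index.get((fibroblast_by_donor[donor], o.locus), (0, 0))
        calls.append(
            SomaticCall(
                obs=o,
                donor_id=donor,
                blood_alt_depth=blood_ad,
                blood_total_depth=blood_dp,
                fibroblast_alt_depth=fib_ad,
                fibroblast_total_depth=fib_dp,
                evaluable=blood_dp >= min_blood_depth,
            )
        )
    return calls


def exclude_factor_loci(
    calls: Iterable[SomaticCall],
    factor_regions: Sequence[tuple[str, int, int, str]],
) -> list[SomaticCall]:
    """Remove calls inside the reprogramming-factor gene loci (half-open
    intervals). Vector-derived SNVs in retroviral clones otherwise masquerade
    as somatic variants absent from the fibroblast."""
    regions = list(factor_regions)
    if not regions:
        logger.warning("empty factor-region set; factor-locus exclusion is a no-op")
        return list(calls)

    def inside(locus: Locus) -> bool:
        return any(
            locus.chrom == chrom and start <= locus.pos < end
            for chrom, start, end, _ in regions
        )

    kept, removed = [], 0
    for call in calls:
        if inside(call.locus):
            removed += 1
        else:
            kept.append(call)
    logger.info("factor-locus exclusion removed %d calls", removed)
    return kept


def classify_by_af(call: SomaticCall, fixed_threshold: float = FIXED_THRESHOLD) -> str:
    """AF >= threshold (inclusive) -> fixed; below -> low_frequency."""
    af = call.af
    if af is None:
        raise DomainError(
            f"undefined AF (zero depth) for {call.sample_id} at "
            f"{call.locus.chrom}:{call.locus.pos}; exclude upstream"
        )
    call.somatic_class = "fixed" if af >= fixed_threshold else "low_frequency"
    return call.somatic_class


def classify_calls(
    calls: Iterable[SomaticCall], fixed_threshold: float = FIXED_THRESHOLD
) -> list[SomaticCall]:
    out = []
    for call in calls:
        if call.obs.total_depth == 0:
            continue
        classify_by_af(call, fixed_threshold)
        out.append(call)
    return out


def calls_to_frame(calls: Iterable[SomaticCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": c.sample_id,
                "donor_id": c.donor_id,
                "chrom": c.locus.chrom,
                "pos": c.locus.pos,
                "ref": c.locus.ref,
                "alt": c.locus.alt,
                "var_type": c.obs.var_type,
                "gene": c.obs.gene,
                "impact": c.obs.impact,
                "alt_depth": c.obs.alt_depth,
                "total_depth": c.obs.total_depth,
                "af": c.af,
                "blood_alt_depth": c.blood_alt_depth,
                "blood_total_depth": c.blood_total_depth,
                "fibroblast_alt_depth": c.fibroblast_alt_depth,
                "fibroblast_total_depth": c.fibroblast_total_depth,
                "somatic_class": c.somatic_class,
                "evaluable": c.evaluable,
                "validated": False,  # low-frequency calls are never validated here
            }
        )
    return pd.DataFrame(rows)


def rank_test(x: Sequence[float], y: Sequence[float], paired: bool = False) -> dict:
    """Two-sided rank test between two groups of counts.

    Unpaired Mann-Whitney U by default; the paired Wilcoxon signed-rank
    variant is exposed for matched designs.
    """
    x, y = list(x), list(y)
    if paired:
        if len(x) != len(y):
            raise DomainError("paired rank test requires equal-length samples")
        if all(a == b for a, b in zip(x, y)):
            return {"test": "wilcoxon", "statistic": 0.0, "pvalue": 1.0}
        res = stats.wilcoxon(x, y, alternative="two-sided")
        return {"test": "wilcoxon", "statistic": float(res.statistic), "pvalue": float(res.pvalue)}
    if not x or not y:
        raise DomainError("rank test requires non-empty groups")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return {"test": "mannwhitneyu", "statistic": float(res.statistic), "pvalue": float(res.pvalue)}


def summarize_somatic(
    calls: Iterable[SomaticCall],
    sample_meta: Sequence[SampleMeta] | Mapping[str, SampleMeta],
    paired: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-sample fixed / low-frequency counts (with var_type breakdown) and
    the RiPSC-vs-SiPSC fixed-count rank test."""
    metas = (
        dict(sample_meta)
        if isinstance(sample_meta, Mapping)
        else {m.sample_id: m for m in sample_meta}
    )
    rows = {
        m.sample_id: {
            "sample_id": m.sample_id,
            "donor_id": m.donor_id,
            "material": m.material,
            "method": m.method,
            "n_fixed": 0,
            "n_low_frequency": 0,
            "n_SNV": 0,
            "n_MNP": 0,
            "n_indel": 0,
        }
        for m in metas.values()
        if m.material not in ("blood",)
    }
    for c in calls:
        if c.somatic_class is None or c.sample_id not in rows:
            continue
        row = rows[c.sample_id]
        if c.somatic_class == "fixed":
            row["n_fixed"] += 1
            row[f"n_{c.obs.var_type}"] += 1
        else:
            row["n_low_frequency"] += 1
    frame = pd.DataFrame(list(rows.values())).sort_values("sample_id").reset_index(drop=True)

    ripsc = frame.loc[frame.material == "RiPSC", "n_fixed"].tolist()
    sipsc = frame.loc[frame.material == "SiPSC", "n_fixed"].tolist()
    group_test: dict = {"comparison": "RiPSC_vs_SiPSC_fixed_counts"}
    if ripsc and sipsc and (not paired or len(ripsc) == len(sipsc)):
        group_test.update(rank_test(ripsc, sipsc, paired=paired))
        group_test["median_RiPSC"] = float(pd.Series(ripsc).median())
        group_test["median_SiPSC"] = float(pd.Series(sipsc).median())
    else:
        group_test.update({"test": None, "statistic": None, "pvalue": None})
    return frame, group_test
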