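"""Tiered per-line QC verdicts and the binomial line-planning calculus.

A line is inspected on three pillars: conventional karyotyping (tier 1, an
input flag), chromosomal microarray (tier 2: aneuploidy and unbalanced
rearrangements fail; sub-chromosomal somatic CNVs warn by default), and
exome sequencing (tier 3: a fixed HIGH-impact variant in a curated disease /
cancer / brain-expressed gene fails). With a per-line pass probability p,
the chance that at least one of n independent lines passes is 1 - (1-p)^n,
which drives how many lines to start with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .spectrum import FlaggedVariant
from .types import DomainError


@dataclass
class QcPolicy:
    """Which tier-2 findings fail a line. The defaults mirror a policy where
    lines carrying reported sub-chromosomal CNVs remain distributable."""

    aneuploidy_fails: bool = True
    unbalanced_rearrangement_fails: bool = True
    subchromosomal_cnv_fails: bool = False  # warn only by default
    flagged_variant_fails: bool = True


@dataclass
class TierResult:
    status: str  # pass | fail | not_assessed
    reasons: list[str] = field(default_factory=list)


@dataclass
class QcVerdict:
    sample_id: str
    tier1_karyotype: TierResult
    tier2_cma: TierResult
    tier3_exome: TierResult
    warnings: list[str] = field(default_factory=list)

    @property
    def overall(self) -> str:
        statuses = [
            t.status for t in (self.tier1_karyotype, self.tier2_cma, self.tier3_exome)
        ]
        evaluated = [s for s in statuses if s != "not_assessed"]
        if not evaluated:
            return "not_assessed"
        return "pass" if all(s == "pass" for s in evaluated) else "fail"


def evaluate_line(
    sample_id: str,
    karyotype_flag: Optional[bool],
    aneuploidies: Optional[pd.DataFrame],
    somatic_cnvs: Optional[Sequence] = None,
    flagged_variants: Optional[Sequence[FlaggedVariant]] = None,
    policy: Optional[QcPolicy] = None,
    unbalanced_rearrangement: bool = False,
) -> QcVerdict:
    """Combine the karyotype input flag, CNV findings and exome findings into
    a tiered verdict. ``None`` inputs mark a tier not_assessed and exclude it
    from the overall verdict; every fail carries machine-readable reasons."""
    policy = policy or QcPolicy()

    if karyotype_flag is None:
        tier1 = TierResult("not_assessed")
    elif karyotype_flag:
        tier1 = TierResult("pass")
    else:
        tier1 = TierResult("fail", ["karyotype:aberration"])

    warnings: list[str] = []
    if aneuploidies is None and somatic_cnvs is None:
        tier2 = TierResult("not_assessed")
    else:
        reasons = []
        if aneuploidies is not None and len(aneuploidies):
            mine = aneuploidies[aneuploidies["sample_id"] == sample_id]
            if policy.aneuploidy_fails:
                for row in mine.itertuples(index=False):
                    reasons.append(f"cma:aneuploidy:{row.call}:{row.chrom}")
        if unbalanced_rearrangement and policy.unbalanced_rearrangement_fails:
            reasons.append("cma:unbalanced_rearrangement")
        for cnv in somatic_cnvs or []:
            seg = cnv.segment
            note = f"cma:somatic_cnv:{seg.chrom}:{seg.start}-{seg.end}:{seg.copy_state}"
            if policy.subchromosomal_cnv_fails:
                reasons.append(note)
            else:
                warnings.append(note)
        tier2 = TierResult("fail" if reasons else "pass", reasons)

    if flagged_variants is None:
        tier3 = TierResult("not_assessed")
    else:
        reasons = []
        if policy.flagged_variant_fails:
            for fv in flagged_variants:
                if fv.sample_id == sample_id:
                    reasons.append(
                        f"exome:fixed_lof:{fv.gene}:{','.join(sorted(fv.lists_hit))}"
                    )
        tier3 = TierResult("fail" if reasons else "pass", reasons)

    return QcVerdict(
        sample_id=sample_id,
        tier1_karyotype=tier1,
        tier2_cma=tier2,
        tier3_exome=tier3,
        warnings=warnings,
    )


def verdict_frame(verdicts: Sequence[QcVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": v.sample_id,
                "tier1_karyotype": v.tier1_karyotype.status,
                "tier2_cma": v.tier2_cma.status,
                "tier3_exome": v.tier3_exome.status,
                "overall": v.overall,
                "reasons": ";".join(
                    v.tier1_karyotype.reasons + v.tier2_cma.reasons + v.tier3_exome.reasons
                ),
                "warnings": ";".join(v.warnings),
            }
            for v in verdicts
        ]
    )


def recommendation_rate(n_pass: int, n_total: int) -> float:
    """Fraction of lines recommended, as a percentage."""
    if n_total < 1 or n_pass < 0 or n_pass > n_total:
        raise DomainError("need 0 <= n_pass <= n_total, n_total >= 1")
    return 100.0 * n_pass / n_total


def pass_probability(p: float, n: int) -> float:
    """Probability that at least one of n lines passes: 1 - (1-p)^n."""
    if not 0.0 <= p <= 1.0:
        raise DomainError("per-line pass probability must be in [0, 1]")
    if n < 1:
        raise DomainError("number of lines must be >= 1")
    return 1.0 - (1.0 - p) ** n


def required_lines(p: float, target: float) -> int:
    """Smallest n with pass_probability(p, n) >= target.

    Uses the log-ratio formula with explicit n-1 / n / n+1 boundary checks to
    dodge floating-point rounding at exact thresholds.
    """
    if not 0.0 < p <= 1.0:
        raise DomainError("unattainable: per-line pass probability must be > 0")
    if not 0.0 < target < 1.0:
        raise DomainError("target probability must be in (0, 1)")
    if p == 1.0:
        return 1
    n = max(1, math.ceil(math.log(1.0 - target) / math.log(1.0 - p)))
    for candidate in (n - 1, n, n + 1):
        if candidate >= 1 and pass_probability(p, candidate) >= target:
            return candidate
    raise AssertionError("boundary search failed")  # pragma: no cover
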