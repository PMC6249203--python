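"""Binomial detectability model for fibroblast somatic mosaicism.

A variant fixed in an iPSC clone originates, in most cases, from a subclone
of the polyclonal fibroblast culture of origin, where it sits at a bulk
allele fraction f well below the heterozygous 0.5. Whether bulk exome
sequencing of the fibroblast shows any supporting read is a binomial draw:
with site coverage c, the detection probability at the one-read evidence
level is 1 - (1 - f)^c. The module provides the forward model, its inverse
(the AF detectable at given coverage with fixed probability), the empirical
detection-rate estimate over fixed calls, and the descriptive AF ~ log
(coverage) regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .somatic import SomaticCall
from .types import DomainError

logger = logging.getLogger(__name__)

AF_BINS = ("none", "<=5.0%", "<=10.0%", ">10%")


def detection_probability(f, c, evidence_reads: int = 1):
    """P(alt reads >= evidence_reads | Binomial(c, f)).

    ``f`` is the fibroblast allele fraction, ``c`` the read coverage at the
    site. For the default one-read evidence level this is 1 - (1 - f)^c.
    Accepts scalars or arrays.
    """
    f_arr = np.asarray(f, dtype=float)
    c_arr = np.asarray(c)
    if np.any((f_arr < 0) | (f_arr > 1)):
        raise DomainError("allele fraction outside [0, 1]")
    if np.any(np.asarray(c_arr) < 0):
        raise DomainError("coverage must be >= 0")
    if evidence_reads < 1:
        raise DomainError("evidence_reads must be >= 1")
    if evidence_reads == 1:
        result = 1.0 - np.power(1.0 - f_arr, c_arr)
    else:
        result = stats.binom.sf(evidence_reads - 1, c_arr, f_arr)
    if np.isscalar(f) and np.isscalar(c):
        return float(result)
    return result


def detectable_af(c: int, p: float, evidence_reads: int = 1) -> float:
    """The allele fraction detectable at coverage ``c`` with probability ``p``.

    Inverse of :func:`detection_probability` in f; closed form
    1 - (1 - p)^(1/c) at the one-read evidence level, numeric root otherwise.
    Monotone decreasing in c.
    """
    if c < 1:
        raise DomainError("coverage must be >= 1")
    if not 0.0 < p < 1.0:
        raise DomainError("probability must be in (0, 1)")
    if evidence_reads == 1:
        return 1.0 - (1.0 - p) ** (1.0 / c)
    if evidence_reads > c:
        raise DomainError("evidence_reads exceeds coverage; no AF attains p")

    def objective(f: float) -> float:
        return detection_probability(f, c, evidence_reads) - p

    return float(optimize.brentq(objective, 1e-12, 1.0 - 1e-12, xtol=1e-12))


@dataclass
class MosaicismSummary:
    """Partition of fixed iPSC variants by fibroblast read evidence."""

    n_detected: int
    n_undetected: int
    evidence_reads: int = 1
    af_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def p_hat(self) -> float:
        total = self.n_detected + self.n_undetected
        return self.n_detected / total if total else float("nan")


def empirical_detection_rate(
    fixed_calls: Iterable[SomaticCall], evidence_reads: int = 1
) -> MosaicismSummary:
    """Partition fixed calls by fibroblast alt reads >= evidence_reads.

    Calls with zero fibroblast coverage are excluded entirely (no draw
    occurred), not counted as undetected. The af_table carries per-variant
    iPSC AF/coverage and fibroblast AF/coverage for plotting and regression,
    with fibroblast-AF bins matching the conventional colouring
    (none / <=5% / <=10% / >10%).
    """
    rows = []
    n_detected = n_undetected = 0
    for call in fixed_calls:
        if call.somatic_class != "fixed":
            continue
        if call.fibroblast_total_depth == 0:
            continue
        detected = call.fibroblast_alt_depth >= evidence_reads
        if detected:
            n_detected += 1
        else:
            n_undetected += 1
        fib_af = call.fibroblast_alt_depth / call.fibroblast_total_depth
        rows.append(
            {
                "sample_id": call.sample_id,
                "chrom": call.locus.chrom,
                "pos": call.locus.pos,
                "ipsc_af": call.af,
                "ipsc_coverage": call.obs.total_depth,
                "fibroblast_af": fib_af,
                "fibroblast_coverage": call.fibroblast_total_depth,
                "detected": detected,
                "fibroblast_af_bin": af_bin(fib_af),
            }
        )
    if n_detected + n_undetected == 0:
        logger.warning("no evaluable fixed calls; empty mosaicism summary")
    return MosaicismSummary(
        n_detected=n_detected,
        n_undetected=n_undetected,
        evidence_reads=evidence_reads,
        af_table=pd.DataFrame(rows),
    )


def af_bin(fib_af: float) -> str:
    if fib_af == 0.0:
        return "none"
    if fib_af <= 0.05:
        return "<=5.0%"
    if fib_af <= 0.10:
        return "<=10.0%"
    return ">10%"


def coverage_af_regression(
    af_table: pd.DataFrame, x_column: str = "ipsc_coverage"
) -> dict:
    """OLS of fibroblast AF on log(coverage) (the y ~ log(x) fit).

    ``x_column`` selects the coverage axis: the iPSC-culture coverage by
    default, or ``fibroblast_coverage``. Points with non-positive coverage
    are dropped; a constant-coverage design raises a singular-fit error.
    """
    data = af_table[(af_table[x_column] > 0) & (af_table["fibroblast_coverage"] > 0)]
    if len(data) < 3:
        raise DomainError("need >= 3 points with positive coverage for the regression")
    x = np.log(data[x_column].to_numpy(dtype=float))
    y = data["fibroblast_af"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DomainError("constant coverage: singular y ~ log(x) fit")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int()
    return {
        "formula": f"fibroblast_af ~ log({x_column})",
        "n": int(len(data)),
        "intercept": float(model.params[0]),
        "slope": float(model.params[1]),
        "slope_ci": (float(ci[1][0]), float(ci[1][1])),
        "r_squared": float(model.rsquared),
        "pvalue": float(model.f_pvalue) if not math.isnan(model.f_pvalue) else float("nan"),
        "bin_counts": data["fibroblast_af_bin"].value_counts().to_dict(),
    }
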