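"""Assay robustness and reproducibility statistics.

The Z' factor, Z' = 1 − 3(σ_p + σ_n)/|μ_p − μ_n|, summarises how well an
assay separates positive from negative controls; Z' > 0.5 is the usual
bar for a screening-grade assay. Sample SDs (n−1) are used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


class QCError(ValueError):
    """Invalid input to a QC statistic."""


@dataclass(frozen=True)
class ZPrimeResult:
    z_prime: float
    mu_p: float
    mu_n: float
    sigma_p: float
    sigma_n: float
    n_p: int
    n_n: int
    assay_id: str | None = None


@dataclass(frozen=True)
class ConcordanceResult:
    r: float
    r2: float
    n: int


def z_prime(
    positive: Sequence[float],
    negative: Sequence[float],
    assay_id: str | None = None,
) -> ZPrimeResult:
    """Z' factor from positive- and negative-control replicates.

    Z' = 1 − 3(σ_p + σ_n)/|μ_p − μ_n|; equals 1 only when both SDs are
    zero, and can be arbitrarily negative for overlapping controls.
    """
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise QCError(f"need >= 2 replicates per control set, got {pos.size} and {neg.size}")
    mu_p, mu_n = float(np.mean(pos)), float(np.mean(neg))
    if mu_p == mu_n:
        raise QCError("no assay window: positive and negative control means are equal")
    s_p, s_n = float(np.std(pos, ddof=1)), float(np.std(neg, ddof=1))
    z = 1.0 - 3.0 * (s_p + s_n) / abs(mu_p - mu_n)
    return ZPrimeResult(z, mu_p, mu_n, s_p, s_n, int(pos.size), int(neg.size), assay_id)


def replicate_concordance(rep1: Sequence[float], rep2: Sequence[float]) -> ConcordanceResult:
    """Pearson r and r² between two biological replicates over complete pairs."""
    a = np.asarray(rep1, dtype=float)
    b = np.asarray(rep2, dtype=float)
    if a.shape != b.shape:
        raise QCError(f"replicate length mismatch: {a.size} vs {b.size}")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise QCError(f"need >= 3 complete pairs, got {a.size}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise QCError("undefined correlation: zero variance in a replicate")
    r = float(stats.pearsonr(a, b).statistic)
    return ConcordanceResult(r=r, r2=r * r, n=int(a.size))


def robustness_gate(
    qc: Sequence[ZPrimeResult], threshold: float = 0.5
) -> list[tuple[ZPrimeResult, bool]]:
    """Pass/fail per assay: pass iff Z' strictly exceeds the threshold."""
    return [(res, res.z_prime > threshold) for res in qc]


def timecourse_peak(times: Sequence[float], signals: Sequence[float]) -> float:
    """Sampled time of maximal signal; ties broken by the earliest time point."""
    t = np.asarray(times, dtype=float)
    s = np.asarray(signals, dtype=float)
    if t.size == 0:
        raise QCError("empty time course")
    if t.size != s.size:
        raise QCError("times and signals differ in length")
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise QCError("times must be strictly increasing")
    return float(t[int(np.argmax(s))])


def qc_report(results: Sequence[tuple[ZPrimeResult, bool]]) -> str:
    """TSV report: assay_id, control stats, Z', pass flag."""
    lines = ["assay_id\tmu_p\tsigma_p\tmu_n\tsigma_n\tz_prime\tpass"]
    for res, ok in results:
        lines.append(
            f"{res.assay_id or 'NA'}\t{res.mu_p!r}\t{res.sigma_p!r}\t"
            f"{res.mu_n!r}\t{res.sigma_n!r}\t{res.z_prime!r}\t{ok}"
        )
    return "\n".join(lines) + "\n"
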