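"""Per-scaffold cross-assay correlation, clustering, and domain-deletion tests.

The core procedure: within each ligand scaffold (chemical class), activity
profiles measured in different cell contexts are compared by Pearson
correlation, with significance from the F-test for nonzero regression
slope, F = (n−2)·r²/(1−r²) on (1, n−2) degrees of freedom — identical to
the two-tailed t-test on the slope (t² = F). Scaffolds are then assigned
to signaling-specificity clusters from the three canonical cross-cell-type
comparisons (breast GREB1 vs endometrial E-Luc vs liver L-Luc):

* cluster 1 — all three comparisons significantly positive: consistent,
  canonical signaling across cell types;
* cluster 2 — some but not all comparisons significant: partially
  cell-specific signaling;
* cluster 3 — none significant: fully cell-specific signaling.

AF-1 dependence is assessed per scaffold by a Student t-test of wild-type
receptor activity against the AB-domain-deletion construct, and
correlation gain/loss under domain deletion is flagged per comparison.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .ligand_data import ActivityPanel

DEFAULT_ALPHA = 0.05

#: the three canonical cross-cell-type comparisons, in figure row order
CANONICAL_PAIRS = (
    ("GREB1", "E-Luc"),
    ("GREB1", "L-Luc_ERa_WT"),
    ("E-Luc", "L-Luc_ERa_WT"),
)


class AnalysisError(ValueError):
    pass


class SignificanceFlag(str, enum.Enum):
    sig_positive = "sig_positive"
    sig_negative = "sig_negative"
    not_significant = "not_significant"


class ClusterLabel(str, enum.Enum):
    cluster1 = "cluster1"
    cluster2 = "cluster2"
    cluster3 = "cluster3"


class Shift(str, enum.Enum):
    gained = "+"
    lost = "-"
    unchanged = "unchanged"


class Direction(str, enum.Enum):
    reduced = "reduced"
    increased = "increased"
    unchanged = "unchanged"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r2: float
    f_stat: float
    p_value: float
    n: int
    assay_x: str | None = None
    assay_y: str | None = None
    scaffold: str | None = None
    evaluable: bool = True
    reason: str | None = None

    @classmethod
    def unevaluable(
        cls, reason: str, n: int = 0, assay_x=None, assay_y=None, scaffold=None
    ) -> "CorrelationResult":
        return cls(
            r=float("nan"), r2=float("nan"), f_stat=float("nan"),
            p_value=float("nan"), n=n, assay_x=assay_x, assay_y=assay_y,
            scaffold=scaffold, evaluable=False, reason=reason,
        )


@dataclass(frozen=True)
class ClusterCall:
    scaffold: str
    flags: tuple[SignificanceFlag, SignificanceFlag, SignificanceFlag]
    label: ClusterLabel


@dataclass(frozen=True)
class DomainSensitivityResult:
    scaffold: str
    t_stat: float
    p_value: float
    direction: Direction
    n: int
    mean_wt: float
    mean_mutant: float
    mode: str


@dataclass(frozen=True)
class DeletionShift:
    comparison: str
    flag_wt: SignificanceFlag
    flag_mutant: SignificanceFlag
    shift: Shift


def _complete_pairs(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise AnalysisError(f"length mismatch: {a.size} vs {b.size}")
    keep = np.isfinite(a) & np.isfinite(b)
    return a[keep], b[keep]


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    assay_x: str | None = None,
    assay_y: str | None = None,
    scaffold: str | None = None,
) -> CorrelationResult:
    """Pearson r with F-test significance for a nonzero regression slope.

    F = (n−2)·r²/(1−r²) at (1, n−2) df; the p-value is the upper-tail F
    probability, identical to the two-tailed slope t-test. Perfect
    collinearity (r² = 1) yields p = 0. Missing pairs are dropped.
    """
    a, b = _complete_pairs(x, y)
    n = a.size
    if n < 3:
        raise AnalysisError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise AnalysisError("zero variance: correlation undefined")
    am, bm = a - a.mean(), b - b.mean()
    r = float(am @ bm / np.sqrt((am @ am) * (bm @ bm)))
    r = max(-1.0, min(1.0, r))
    r2 = r * r
    if r2 >= 1.0:
        f = float("inf")
        p = 0.0
    else:
        f = (n - 2) * r2 / (1.0 - r2)
        p = float(stats.f.sf(f, 1, n - 2))
    return CorrelationResult(
        r=r, r2=r2, f_stat=f, p_value=p, n=int(n),
        assay_x=assay_x, assay_y=assay_y, scaffold=scaffold,
    )


def significance_flag(res: CorrelationResult, alpha: float = DEFAULT_ALPHA) -> SignificanceFlag:
    """Classify a correlation as significantly positive/negative at p ≤ alpha."""
    if not res.evaluable or not np.isfinite(res.p_value):
        return SignificanceFlag.not_significant
    if res.p_value <= alpha:
        if res.r > 0:
            return SignificanceFlag.sig_positive
        if res.r < 0:
            return SignificanceFlag.sig_negative
    return SignificanceFlag.not_significant


def scaffold_correlation_matrix(
    panel: ActivityPanel,
    scaffold: str,
    pairs: Sequence[tuple[str, str]] = CANONICAL_PAIRS,
) -> list[CorrelationResult]:
    """One :class:`CorrelationResult` per assay pair, over one scaffold's ligands.

    Pairs with fewer than 3 complete observations (or zero variance) are
    returned marked unevaluable rather than dropped.
    """
    out: list[CorrelationResult] = []
    for ax, ay in pairs:
        x = panel.scaffold_values(scaffold, ax)
        y = panel.scaffold_values(scaffold, ay)
        try:
            out.append(correlate(x, y, assay_x=ax, assay_y=ay, scaffold=scaffold))
        except AnalysisError as exc:
            a, b = _complete_pairs(x, y)
            out.append(
                CorrelationResult.unevaluable(
                    str(exc), n=int(a.size), assay_x=ax, assay_y=ay, scaffold=scaffold
                )
            )
    return out


def assign_cluster(
    flags: Sequence[SignificanceFlag], scaffold: str = ""
) -> ClusterCall:
    """Cluster from the count k of significantly positive canonical comparisons.

    k = 3 → cluster 1; k ∈ {1, 2} → cluster 2; k = 0 → cluster 3. The rule
    depends only on the count, not the order of comparisons.
    """
    flags = tuple(flags)
    if len(flags) != 3:
        raise AnalysisError(f"expected exactly 3 flags, got {len(flags)}")
    k = sum(f is SignificanceFlag.sig_positive for f in flags)
    label = (
        ClusterLabel.cluster1 if k == 3
        else ClusterLabel.cluster3 if k == 0
        else ClusterLabel.cluster2
    )
    return ClusterCall(scaffold=scaffold, flags=flags, label=label)


def classify_scaffolds(
    panel: ActivityPanel,
    pairs: Sequence[tuple[str, str]] = CANONICAL_PAIRS,
    alpha: float = DEFAULT_ALPHA,
) -> list[ClusterCall]:
    """Correlate the canonical pairs and assign a cluster for every scaffold."""
    calls = []
    for scf in panel.scaffolds:
        results = scaffold_correlation_matrix(panel, scf, pairs)
        flags = tuple(significance_flag(r, alpha) for r in results)
        calls.append(assign_cluster(flags, scaffold=scf))
    return calls


def domain_dependence_test(
    panel: ActivityPanel,
    scaffold: str,
    assay_wt: str,
    assay_mutant: str,
    mode: str = "paired",
    alpha: float = DEFAULT_ALPHA,
) -> DomainSensitivityResult:
    """Student t-test of scaffold activity in the wild-type vs a deletion construct.

    ``paired`` (default): two-tailed paired t on per-ligand WT−mutant
    differences (each ligand measured in both constructs), df = n−1.
    ``two_sample``: pooled-variance two-tailed Student t, df = n1+n2−2.
    Direction is ``reduced`` when mean(WT) > mean(mutant) at p ≤ alpha,
    ``increased`` for the opposite sign, else ``unchanged``.
    """
    x = panel.scaffold_values(scaffold, assay_wt).to_numpy(dtype=float)
    y = panel.scaffold_values(scaffold, assay_mutant).to_numpy(dtype=float)
    if mode == "paired":
        keep = np.isfinite(x) & np.isfinite(y)
        a, b = x[keep], y[keep]
        n = int(a.size)
        if n < 3:
            raise AnalysisError(f"scaffold {scaffold!r}: need >= 3 paired ligands, got {n}")
        d = a - b
        if np.ptp(d) == 0:
            if d[0] == 0:
                t, p = 0.0, 1.0
            else:  # exact separation: constant nonzero difference
                t, p = float(np.sign(d[0]) * np.inf), 0.0
        else:
            t, p = stats.ttest_rel(a, b)
            t, p = float(t), float(p)
        mean_wt, mean_mut = float(a.mean()), float(b.mean())
    elif mode == "two_sample":
        a, b = x[np.isfinite(x)], y[np.isfinite(y)]
        if a.size < 3 or b.size < 3:
            raise AnalysisError(
                f"scaffold {scaffold!r}: need >= 3 ligands per group, "
                f"got {a.size} and {b.size}"
            )
        n = int(min(a.size, b.size))
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            if a[0] == b[0]:
                t, p = 0.0, 1.0
            else:
                t, p = float(np.sign(a[0] - b[0]) * np.inf), 0.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
            t, p = float(t), float(p)
        mean_wt, mean_mut = float(a.mean()), float(b.mean())
    else:
        raise AnalysisError(f"mode must be 'paired' or 'two_sample', got {mode!r}")

    if p <= alpha and mean_wt > mean_mut:
        direction = Direction.reduced
    elif p <= alpha and mean_wt < mean_mut:
        direction = Direction.increased
    else:
        direction = Direction.unchanged
    return DomainSensitivityResult(
        scaffold=scaffold, t_stat=t, p_value=p, direction=direction,
        n=n, mean_wt=mean_wt, mean_mutant=mean_mut, mode=mode,
    )


def deletion_shift(
    flag_wt: SignificanceFlag,
    flag_mutant: SignificanceFlag,
    comparison: str = "",
) -> DeletionShift:
    """Flag a correlation gained (+) or lost (−) upon domain deletion."""
    if flag_wt is not SignificanceFlag.sig_positive and flag_mutant is SignificanceFlag.sig_positive:
        shift = Shift.gained
    elif flag_wt is SignificanceFlag.sig_positive and flag_mutant is not SignificanceFlag.sig_positive:
        shift = Shift.lost
    else:
        shift = Shift.unchanged
    return DeletionShift(comparison=comparison, flag_wt=flag_wt, flag_mutant=flag_mutant, shift=shift)


def correlation_table(results: Sequence[CorrelationResult]) -> str:
    """Long-format TSV: scaffold, assay pair, r, r², F, p, n, flag."""
    lines = ["scaffold\tassay_x\tassay_y\tr\tr2\tF\tp\tn\tflag"]
    for res in results:
        flag = significance_flag(res).value if res.evaluable else "unevaluable"
        fmt = lambda v: "NA" if not np.isfinite(v) else repr(float(v))
        lines.append(
            f"{res.scaffold or 'NA'}\t{res.assay_x}\t{res.assay_y}\t"
            f"{fmt(res.r)}\t{fmt(res.r2)}\t{fmt(res.f_stat)}\t{fmt(res.p_value)}\t"
            f"{res.n}\t{flag}"
        )
    return "\n".join(lines) + "\n"


def cluster_table(calls: Sequence[ClusterCall]) -> str:
    """Cluster-call TSV: scaffold, the three comparison flags, cluster label."""
    lines = ["scaffold\tflag1\tflag2\tflag3\tcluster"]
    for c in calls:
        f1, f2, f3 = (f.value for f in c.flags)
        lines.append(f"{c.scaffold}\t{f1}\t{f2}\t{f3}\t{c.label.value}")
    return "\n".join(lines) + "\n"
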