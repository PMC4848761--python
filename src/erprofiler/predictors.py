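"""Simple linear regression predictors of downstream ligand activities.

One activity (e.g. MCF-7 proliferation or GREB1 induction) is treated as
the response and each other assay in turn as a single predictor, per
scaffold — a matrix of pairwise ordinary-least-squares fits whose p-values
coincide with the corresponding correlation F-tests (t² = F).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .class_analysis import AnalysisError, correlate
from .ligand_data import ActivityPanel


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int
    predictor: str | None = None
    response: str | None = None
    scaffold: str | None = None
    evaluable: bool = True
    reason: str | None = None

    @classmethod
    def unevaluable(cls, reason, n=0, predictor=None, response=None, scaffold=None):
        return cls(
            slope=float("nan"), intercept=float("nan"), r2=float("nan"),
            p_value=float("nan"), n=n, predictor=predictor, response=response,
            scaffold=scaffold, evaluable=False, reason=reason,
        )


def fit_simple_regression(
    x: Sequence[float],
    y: Sequence[float],
    predictor: str | None = None,
    response: str | None = None,
    scaffold: str | None = None,
) -> RegressionResult:
    """OLS fit y = slope·x + intercept over complete pairs.

    r² and the F-test p-value match :func:`~erprofiler.class_analysis.correlate`
    on the same data; a constant response gives slope 0, r² = 0, p = 1.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise AnalysisError(f"length mismatch: {a.size} vs {b.size}")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = int(a.size)
    if n < 3:
        raise AnalysisError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(a) == 0:
        raise AnalysisError("predictor has zero variance")
    if np.ptp(b) == 0:
        # flat response: slope exactly 0, nothing to explain
        return RegressionResult(
            slope=0.0, intercept=float(b[0]), r2=0.0, p_value=1.0, n=n,
            predictor=predictor, response=response, scaffold=scaffold,
        )
    fit = stats.linregress(a, b)
    cor = correlate(a, b)
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r2=cor.r2, p_value=cor.p_value, n=n,
        predictor=predictor, response=response, scaffold=scaffold,
    )


def prediction_matrix(
    panel: ActivityPanel,
    response: str,
    predictors: Sequence[str],
    by_scaffold: bool = True,
) -> list[RegressionResult]:
    """Fit every (scaffold, predictor) → response regression in a panel.

    Cells that cannot be fitted (too few complete pairs, zero predictor
    variance, all-missing response) are flagged unevaluable, never dropped
    or zeroed.
    """
    groups = panel.scaffolds if by_scaffold else [None]
    out: list[RegressionResult] = []
    for scf in groups:
        for pred in predictors:
            if scf is None:
                x = panel.values[pred]
                y = panel.values[response]
            else:
                x = panel.scaffold_values(scf, pred)
                y = panel.scaffold_values(scf, response)
            try:
                out.append(
                    fit_simple_regression(
                        x, y, predictor=pred, response=response, scaffold=scf
                    )
                )
            except AnalysisError as exc:
                out.append(
                    RegressionResult.unevaluable(
                        str(exc), predictor=pred, response=response, scaffold=scf
                    )
                )
    return out


def prediction_matrix_tables(
    results: Sequence[RegressionResult], alpha: float = 0.05
) -> tuple[str, str, str]:
    """Heat-map-ready TSVs: (r² matrix, p matrix, flag matrix).

    Rows are predictor→response comparisons, columns scaffolds; unevaluable
    cells are explicit ``NA`` tokens.
    """
    rows = sorted({f"{r.predictor}->{r.response}" for r in results})
    cols = list(dict.fromkeys(r.scaffold for r in results))
    cell: dict[tuple[str, str | None], RegressionResult] = {
        (f"{r.predictor}->{r.response}", r.scaffold): r for r in results
    }

    def table(value) -> str:
        lines = ["comparison\t" + "\t".join(str(c) for c in cols)]
        for row in rows:
            vals = []
            for c in cols:
                r = cell.get((row, c))
                vals.append("NA" if r is None or not r.evaluable else value(r))
            lines.append(row + "\t" + "\t".join(vals))
        return "\n".join(lines) + "\n"

    r2_tsv = table(lambda r: repr(float(r.r2)))
    p_tsv = table(lambda r: repr(float(r.p_value)))
    # slope sign carried in the flag so signed or unsigned heat-maps can be drawn
    flag_tsv = table(
        lambda r: ("sig+" if r.slope > 0 else "sig-") if r.p_value <= alpha else "ns"
    )
    return r2_tsv, p_tsv, flag_tsv
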