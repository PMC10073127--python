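"""Case-control association testing over the copy-state matrix.

Each retained atomic region is tested twice — loss carriers vs the rest
and gain carriers vs the rest — with a two-sided Fisher's exact test on
the 2x2 carrier table

    ==============  =========  =============
    .               carrier    non-carrier
    ==============  =========  =============
    cases           a          b
    controls        c          d
    ==============  =========  =============

Samples whose state at the region is CONFLICT (deletion and duplication
consensus both covering it) are excluded from that region's denominators.
The odds ratio (a*d)/(b*c) is reported with a Wald 95% confidence interval
on the log scale; when any cell is zero the Haldane-Anscombe 0.5
continuity correction is applied (the default) so the estimate and its
variance are defined.

The two-sided p-value follows the minimum-likelihood rule: the sum over
the hypergeometric support of all tables with the observed margins whose
probability does not exceed that of the observed table (a relative tie
tolerance of 1e-7 guards against floating-point ties).

The global burden summary contrasts the odds-ratio distributions of
significant losses vs significant gains with a two-sided Wilcoxon rank-sum
(Mann-Whitney) test on the log odds ratios — exact enumeration when both
groups are small and untied, the tie-corrected normal approximation
otherwise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .consensus import AtomicRegion, CopyState, CopyStateMatrix
from .errors import UsageError, ValidationError
from .io_formats import SampleSheet

#: Relative tolerance for probability ties in the two-sided sum.
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier counts: a/b case carriers/non-carriers, c/d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError(f"negative cell in table {self}")
        if self.total < 1:
            raise ValidationError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ContingencyTable2x2":
        """Case/control rows exchanged."""
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


class Direction(str, enum.Enum):
    RISK = "RISK"          # OR > 1: carriers enriched in cases
    PROTECTIVE = "PROTECTIVE"  # OR < 1
    NULL = "NULL"          # OR == 1


@dataclass(frozen=True)
class AssociationResult:
    """One region x event-type association test."""

    region: AtomicRegion
    event_type: CopyState  # LOSS or GAIN
    table: ContingencyTable2x2
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    direction: Direction
    q_value: Optional[float] = None


@lru_cache(maxsize=1 << 20)
def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    n1 = a + b      # cases
    k = a + c       # carriers
    n = a + b + c + d
    lo = max(0, k - (c + d))
    hi = min(n1, k)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, n1, k)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return min(p, 1.0)


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p-value by the minimum-likelihood rule."""
    return _fisher_p(table.a, table.b, table.c, table.d)


def odds_ratio(
    table: ContingencyTable2x2, correction: str = "haldane"
) -> tuple[float, float, float]:
    """Odds ratio with a Wald 95% CI on the log scale.

    ``correction="haldane"`` adds 0.5 to every cell iff any cell is zero;
    ``correction="none"`` raises on a zero cell (the OR is undefined).
    """
    if correction not in ("none", "haldane"):
        raise UsageError(f"unknown correction {correction!r}")
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        if correction == "none":
            raise UsageError(
                f"odds ratio undefined for table {table} with a zero cell "
                "(use correction='haldane')"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_)
    lo = float(np.exp(log_or - 1.96 * se))
    hi = float(np.exp(log_or + 1.96 * se))
    return or_, lo, hi


def _direction(or_: float) -> Direction:
    if or_ > 1:
        return Direction.RISK
    if or_ < 1:
        return Direction.PROTECTIVE
    return Direction.NULL


def test_all_regions(
    matrix: CopyStateMatrix,
    sheet: SampleSheet,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    correction: str = "haldane",
    add_q_values: bool = True,
) -> list[AssociationResult]:
    """Fisher-test every region for loss and gain carriers separately.

    A (region, event) pair with zero carriers among the selected samples is
    skipped.  CONFLICT samples are excluded from the region's denominators.
    Benjamini-Hochberg q-values are attached across all emitted results
    (reported only; selection uses raw p-values).
    """
    if not case_ids or not control_ids:
        raise UsageError("case and control strata must both be non-empty")
    known = set(sheet.frame["sample_id"])
    for sid in list(case_ids) + list(control_ids):
        if sid not in known:
            raise UsageError(f"sample {sid!r} not in sample sheet")

    cases = matrix.sample_columns(case_ids)     # regions x n_case
    ctrls = matrix.sample_columns(control_ids)

    results: list[AssociationResult] = []
    for state in (CopyState.LOSS, CopyState.GAIN):
        case_carrier = (cases == state).sum(axis=1)
        ctrl_carrier = (ctrls == state).sum(axis=1)
        case_ok = (cases != CopyState.CONFLICT).sum(axis=1)
        ctrl_ok = (ctrls != CopyState.CONFLICT).sum(axis=1)
        for i, region in enumerate(matrix.regions):
            a = int(case_carrier[i])
            c = int(ctrl_carrier[i])
            if a + c == 0:
                continue
            table = ContingencyTable2x2(
                a, int(case_ok[i]) - a, c, int(ctrl_ok[i]) - c
            )
            p = fisher_exact(table)
            or_, lo, hi = odds_ratio(table, correction)
            results.append(
                AssociationResult(
                    region=region,
                    event_type=state,
                    table=table,
                    p_value=p,
                    odds_ratio=or_,
                    ci_low=lo,
                    ci_high=hi,
                    direction=_direction(or_),
                )
            )
    if add_q_values and results:
        _, q, _, _ = multipletests(
            [r.p_value for r in results], method="fdr_bh"
        )
        results = [replace(r, q_value=float(qv)) for r, qv in zip(results, q)]
    return results


@dataclass
class BurdenSummary:
    """Odds-ratio distributions of significant losses vs gains."""

    loss_ors: list[float]
    gain_ors: list[float]
    median_loss_or: Optional[float]
    median_gain_or: Optional[float]
    ranksum_p: Optional[float]
    p_threshold: float


def _ranksum_two_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney p: exact for small untied samples, else the
    tie-corrected normal approximation (no continuity correction)."""
    pooled = list(x) + list(y)
    has_ties = len(set(pooled)) < len(pooled)
    if len(x) <= 10 and len(y) <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.pvalue)


def global_burden_summary(
    results: Sequence[AssociationResult], p_threshold: float = 1e-5
) -> BurdenSummary:
    """Summarise the direction asymmetry of significant losses vs gains.

    Collects odds ratios of results with ``p < p_threshold`` per event
    class, reports each class's median, and compares the two log-OR
    distributions with a two-sided Wilcoxon rank-sum test.  If either class
    is empty, that class's median is None and the rank-sum is skipped.
    """
    loss = sorted(
        r.odds_ratio
        for r in results
        if r.event_type is CopyState.LOSS and r.p_value < p_threshold
    )
    gain = sorted(
        r.odds_ratio
        for r in results
        if r.event_type is CopyState.GAIN and r.p_value < p_threshold
    )
    ranksum = None
    if loss and gain:
        ranksum = _ranksum_two_sided(
            list(np.log(loss)), list(np.log(gain))
        )
    return BurdenSummary(
        loss_ors=loss,
        gain_ors=gain,
        median_loss_or=float(np.median(loss)) if loss else None,
        median_gain_or=float(np.median(gain)) if gain else None,
        ranksum_p=ranksum,
        p_threshold=p_threshold,
    )
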