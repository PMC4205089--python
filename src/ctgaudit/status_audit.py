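"""Recruitment-status conflict auditing and recency statistics.

A record is *conflicting* when it advertises an open recruitment status
("Recruiting" or "Not yet recruiting") while its stated study completion date
lies entirely in the past relative to the audit reference date.  Fuzzy dates
are compared under the latest-day interpretation: a month-precision date only
counts as past once its last calendar day has elapsed, so partial dates never
produce false conflict flags.

Recency comparisons between groups (e.g. conflicting vs. clean records) use a
one-sided Mann-Whitney U test, with exact enumeration for small untied
samples and a tie-corrected, continuity-corrected normal approximation
otherwise.
"""

from __future__ import annotations

import calendar
import math
from dataclasses import dataclass
from datetime import date
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .registry_io import Corpus, DatePrecision, FuzzyDate, TrialRecord
from ._util import percent_round_half_away

__all__ = [
    "StatusAuditResult",
    "RankSumResult",
    "StalenessError",
    "latest_day",
    "earliest_day",
    "flag_conflict",
    "days_since_update",
    "rank_sum_test",
    "audit_corpus",
    "conflict_table",
]


class StalenessError(ValueError):
    """last_update falls after the audit reference date (corrupted input)."""


def latest_day(d: FuzzyDate) -> date:
    """Latest calendar day consistent with a fuzzy date.

    Day precision maps to itself, month precision to the last day of that
    month, year precision to December 31.
    """
    if d.precision is DatePrecision.DAY:
        return date(d.year, d.month, d.day)
    if d.precision is DatePrecision.MONTH:
        return date(d.year, d.month, calendar.monthrange(d.year, d.month)[1])
    return date(d.year, 12, 31)


def earliest_day(d: FuzzyDate) -> date:
    if d.precision is DatePrecision.DAY:
        return date(d.year, d.month, d.day)
    if d.precision is DatePrecision.MONTH:
        return date(d.year, d.month, 1)
    return date(d.year, 1, 1)


@dataclass(frozen=True)
class StatusAuditResult:
    nct_id: str
    is_open_status: bool
    completion_in_past: Optional[bool]
    conflicting: bool
    days_since_update: int


def days_since_update(record: TrialRecord, reference_date: date) -> int:
    """Whole days between the record's last update and the reference date.

    Uses the latest-day reading of the update date, clamped at zero when the
    update month straddles the reference day.  An update that cannot precede
    the reference date at all signals a corrupted fixture and raises
    :class:`StalenessError`.
    """
    if earliest_day(record.last_update) > reference_date:
        raise StalenessError(
            f"{record.nct_id}: last_update after reference date {reference_date}"
        )
    return max(0, (reference_date - latest_day(record.last_update)).days)


def flag_conflict(record: TrialRecord, reference_date: date) -> StatusAuditResult:
    """Apply the open-status / past-completion conflict rule to one record."""
    is_open = record.overall_status.is_open
    if record.completion_date is None:
        in_past: Optional[bool] = None
    else:
        in_past = latest_day(record.completion_date) < reference_date
    return StatusAuditResult(
        nct_id=record.nct_id,
        is_open_status=is_open,
        completion_in_past=in_past,
        conflicting=bool(is_open and in_past),
        days_since_update=days_since_update(record, reference_date),
    )


# ---------------------------------------------------------------------------
# One-sided Mann-Whitney U


@dataclass(frozen=True)
class RankSumResult:
    u_statistic: float
    p_value: float
    alternative: str  # "less" | "greater"
    method: str  # "exact" | "normal_approx"


_EXACT_ENUMERATION_CAP = 2_000_000  # number of rank subsets we will enumerate


def _exact_p(u_obs: float, n1: int, n2: int, alternative: str) -> float:
    """One-sided p by full enumeration of the C(n1+n2, n1) rank assignments."""
    n = n1 + n2
    offset = n1 * (n1 + 1) / 2
    total = 0
    hits = 0
    for ranks in combinations(range(1, n + 1), n1):
        u = sum(ranks) - offset
        total += 1
        if alternative == "less":
            hits += u <= u_obs + 1e-9
        else:
            hits += u >= u_obs - 1e-9
    return hits / total


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "less",
    exact_threshold: int = 8,
) -> RankSumResult:
    """One-sided Mann-Whitney U test of ``x`` against ``y``.

    The U statistic reported is that of the first sample (small U supports
    ``alternative="less"``).  For untied data with ``min(n1, n2) <=
    exact_threshold`` the p-value comes from full enumeration of rank
    assignments; otherwise a normal approximation with midranks, the usual
    tie correction of the variance, and a 0.5 continuity correction is used.
    """
    if alternative not in ("less", "greater"):
        raise ValueError(f"alternative must be 'less' or 'greater', got {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)  # midranks
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if (
        not has_ties
        and min(n1, n2) <= exact_threshold
        and math.comb(n, min(n1, n2)) <= _EXACT_ENUMERATION_CAP
    ):
        return RankSumResult(u1, _exact_p(u1, n1, n2, alternative), alternative, "exact")

    mean = n1 * n2 / 2
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        return RankSumResult(u1, 1.0, alternative, "normal_approx")
    sd = math.sqrt(var)
    if alternative == "less":
        z = (u1 + 0.5 - mean) / sd
        p = float(stats.norm.cdf(z))
    else:
        z = (u1 - 0.5 - mean) / sd
        p = float(stats.norm.sf(z))
    return RankSumResult(u1, min(max(p, 0.0), 1.0), alternative, "normal_approx")


# ---------------------------------------------------------------------------
# Corpus-level audit


def audit_corpus(corpus: Corpus) -> list[StatusAuditResult]:
    """Audit every record against its domain's reference date."""
    return [
        flag_conflict(r, corpus.reference_dates[r.domain_tag]) for r in corpus.records
    ]


def conflict_table(
    corpus: Corpus, results: Optional[Iterable[StatusAuditResult]] = None
) -> pd.DataFrame:
    """Per-domain and overall conflict counts and whole-percent rates.

    Percentages are rounded half away from zero.  The returned frame is
    indexed by domain tag with a final ``overall`` row.
    """
    if results is None:
        results = audit_corpus(corpus)
    by_id = {res.nct_id: res for res in results}
    rows = []
    total_n = total_c = 0
    for tag in corpus.domains:
        recs = corpus.by_domain(tag)
        n = len(recs)
        c = sum(by_id[r.nct_id].conflicting for r in recs)
        total_n += n
        total_c += c
        rows.append((tag, n, c, percent_round_half_away(c, n)))
    rows.append(("overall", total_n, total_c, percent_round_half_away(total_c, total_n)))
    return pd.DataFrame(
        rows, columns=["domain", "n_trials", "n_conflicting", "percent_conflicting"]
    ).set_index("domain")
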