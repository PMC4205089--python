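"""Follow-up verification machinery: stratified sampling, contact plans,
and outcome classification.

The verification study samples open, US-located trials per clinical domain:
the eligible list is ordered by date last updated, cut into four
as-equal-as-possible segments, and up to ten trials are drawn at random from
each segment.  For each sampled trial a contact plan is built — the three
recruitment locations nearest a fixed reference point (Boston, MA), then the
trial's overall and backup contacts — and responses to the (simulated)
outreach are classified into four categories: ``open``, ``closed``,
``dont_know`` and ``no_answer``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .registry_io import ContactInfo, Corpus, FuzzyDate, TrialRecord
from .status_audit import latest_day
from ._util import percent_round_half_away

__all__ = [
    "BOSTON",
    "SamplingPlan",
    "ContactAttempt",
    "ContactPlan",
    "OutcomeCategory",
    "AttemptResult",
    "ResponseKind",
    "FollowUpOutcome",
    "haversine_km",
    "followup_eligible",
    "stratified_sample",
    "build_contact_plan",
    "classify_outcome",
    "followup_table",
]

#: Reference point for distance ordering (Boston, Massachusetts).
BOSTON = (42.3601, -71.0589)

_EARTH_RADIUS_KM = 6371.0


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in kilometers between (lat, lon) pairs in degrees."""
    for lat, lon in (a, b):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude out of range: {lat}")
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude out of range: {lon}")
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def followup_eligible(record: TrialRecord) -> bool:
    """Open status and at least one United States location."""
    return record.overall_status.is_open and any(
        loc.country == "United States" for loc in record.locations
    )


@dataclass(frozen=True)
class SamplingPlan:
    domain_tag: str
    eligible_ids: tuple[str, ...]  # ordered ascending by last update
    segment_boundaries: tuple[tuple[int, int], ...]  # half-open index ranges
    sampled_ids: tuple[str, ...]
    seed: int
    per_segment: int
    dropped_ids: tuple[str, ...] = ()

    @property
    def active_sampled_ids(self) -> tuple[str, ...]:
        dropped = set(self.dropped_ids)
        return tuple(i for i in self.sampled_ids if i not in dropped)


def _segment_sizes(n: int, segments: int) -> list[int]:
    # as-equal-as-possible contiguous segments, remainder to the earliest ones
    q, r = divmod(n, segments)
    return [q + 1 if i < r else q for i in range(segments)]


def stratified_sample(
    trials: Sequence[TrialRecord],
    per_segment: int = 10,
    segments: int = 4,
    seed: int = 0,
    domain_tag: Optional[str] = None,
) -> SamplingPlan:
    """Last-update-ordered stratified sample of follow-up candidates.

    ``trials`` must already be filtered to eligible records (open status, US
    location).  They are ordered ascending by the latest-day reading of the
    last update (trial id breaks ties), cut into ``segments`` contiguous
    as-equal-as-possible pieces, and up to ``per_segment`` trials are drawn
    from each piece without replacement with a seeded generator.  Segments
    smaller than ``per_segment`` are taken whole.  An empty eligible list
    yields an empty plan.
    """
    tag = domain_tag or (trials[0].domain_tag if trials else "")
    ordered = sorted(trials, key=lambda r: (latest_day(r.last_update), r.nct_id))
    ids = tuple(r.nct_id for r in ordered)
    rng = np.random.default_rng(seed)
    boundaries: list[tuple[int, int]] = []
    sampled: list[str] = []
    start = 0
    for size in _segment_sizes(len(ids), segments):
        end = start + size
        boundaries.append((start, end))
        take = min(per_segment, size)
        if take:
            picks = rng.choice(size, size=take, replace=False)
            sampled.extend(ids[start + i] for i in sorted(picks))
        start = end
    return SamplingPlan(
        domain_tag=tag,
        eligible_ids=ids,
        segment_boundaries=tuple(boundaries),
        sampled_ids=tuple(sampled),
        seed=seed,
        per_segment=per_segment,
    )


@dataclass(frozen=True)
class ContactAttempt:
    kind: str  # "location" | "overall" | "backup"
    label: str
    contact: ContactInfo
    distance_km: Optional[float] = None
    max_calls: int = 3
    max_emails: int = 1


@dataclass(frozen=True)
class ContactPlan:
    nct_id: str
    attempts: tuple[ContactAttempt, ...]


def build_contact_plan(
    record: TrialRecord, reference_point: tuple[float, float] = BOSTON
) -> ContactPlan:
    """Up to three nearest locations with contact info, then overall, then backup.

    Location order is a content-based total order — distance first, facility
    and city as tie-breaks, locations without coordinates last — so the
    chosen nearest-3 set never depends on input ordering.  Locations without
    any contact info are skipped, not counted against the three.
    """
    withc = [loc for loc in record.locations if loc.contact is not None]

    def key(loc):
        if loc.latitude is None or loc.longitude is None:
            return (1, 0.0, loc.facility, loc.city)
        d = haversine_km(reference_point, (loc.latitude, loc.longitude))
        return (0, d, loc.facility, loc.city)

    attempts: list[ContactAttempt] = []
    for loc in sorted(withc, key=key)[:3]:
        d = (
            haversine_km(reference_point, (loc.latitude, loc.longitude))
            if loc.latitude is not None and loc.longitude is not None
            else None
        )
        attempts.append(
            ContactAttempt("location", loc.facility, loc.contact, distance_km=d)
        )
    if record.overall_contact is not None:
        attempts.append(ContactAttempt("overall", "overall", record.overall_contact))
    if record.backup_contact is not None:
        attempts.append(ContactAttempt("backup", "backup", record.backup_contact))
    return ContactPlan(nct_id=record.nct_id, attempts=tuple(attempts))


class OutcomeCategory(str, Enum):
    OPEN = "open"
    CLOSED = "closed"
    DONT_KNOW = "dont_know"
    NO_ANSWER = "no_answer"


class ResponseKind(str, Enum):
    CONFIRMED_OPEN = "confirmed_open"
    CONFIRMED_CLOSED = "confirmed_closed"
    REFUSED = "refused"
    UNREACHABLE = "unreachable"


@dataclass(frozen=True)
class AttemptResult:
    kind: ResponseKind
    date: Optional[FuzzyDate] = None  # recruitment close date, when reported


@dataclass(frozen=True)
class FollowUpOutcome:
    nct_id: str
    category: OutcomeCategory
    close_date: Optional[FuzzyDate] = None
    attempts_used: int = 0

    def __post_init__(self):
        if self.close_date is not None and self.category is not OutcomeCategory.CLOSED:
            raise ValueError("close_date only accompanies a 'closed' outcome")


def classify_outcome(
    nct_id: str, responses: Sequence[AttemptResult]
) -> FollowUpOutcome:
    """First informative response wins; refusals degrade to 'don't know';
    no responses at all (e.g. a record without any contact info) is 'no answer'."""
    refused = False
    for i, r in enumerate(responses, start=1):
        if r.kind is ResponseKind.CONFIRMED_OPEN:
            return FollowUpOutcome(nct_id, OutcomeCategory.OPEN, attempts_used=i)
        if r.kind is ResponseKind.CONFIRMED_CLOSED:
            return FollowUpOutcome(
                nct_id, OutcomeCategory.CLOSED, close_date=r.date, attempts_used=i
            )
        if r.kind is ResponseKind.REFUSED:
            refused = True
    n = len(responses)
    if refused:
        return FollowUpOutcome(nct_id, OutcomeCategory.DONT_KNOW, attempts_used=n)
    return FollowUpOutcome(nct_id, OutcomeCategory.NO_ANSWER, attempts_used=n)


def followup_table(
    outcomes_by_domain: Mapping[str, Sequence[FollowUpOutcome]],
    dropped_by_domain: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Category tallies per domain plus an overall row with whole percents.

    ``dropped_by_domain`` reports trials removed before classification (e.g.
    completed between corpus creation and contact download); they are listed
    in a ``dropped`` column and excluded from ``n`` and the percentages.
    """
    dropped_by_domain = dropped_by_domain or {}
    cats = [c.value for c in OutcomeCategory]
    rows = []
    totals = {c: 0 for c in cats}
    total_n = 0
    total_dropped = 0
    for tag in sorted(outcomes_by_domain):
        outs = outcomes_by_domain[tag]
        counts = {c: sum(o.category.value == c for o in outs) for c in cats}
        n = len(outs)
        d = dropped_by_domain.get(tag, 0)
        for c in cats:
            totals[c] += counts[c]
        total_n += n
        total_dropped += d
        rows.append([tag, n, d] + [counts[c] for c in cats])
    rows.append(["overall", total_n, total_dropped] + [totals[c] for c in cats])
    frame = pd.DataFrame(
        rows, columns=["domain", "n", "dropped"] + cats
    ).set_index("domain")
    for c in cats:
        frame[f"percent_{c}"] = [
            percent_round_half_away(k, n) for k, n in zip(frame[c], frame["n"])
        ]
    return frame
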