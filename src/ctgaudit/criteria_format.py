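"""Eligibility-text macro-format classification and criterion segmentation.

Registry eligibility blocks come, overwhelmingly, in one of two layouts:

* the *suggested* format — a bulleted list under an "Inclusion Criteria"
  heading, optionally followed by an "Exclusion Criteria" section, in that
  order;
* the *extended* format, common in cancer trials — inclusion-only criteria
  (possibly negated, "No prior ...") grouped under the topics "disease
  characteristics", "patient characteristics" and "prior concurrent therapy".

Anything else is left unclassified; such blocks cannot be segmented and are
reported separately by downstream tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import pandas as pd

from .registry_io import Corpus
from ._util import percent_round_half_away

__all__ = [
    "Role",
    "Criterion",
    "FormatClassification",
    "FormatError",
    "classify_format",
    "segment_criteria",
    "format_table",
]


class FormatError(ValueError):
    """Segmentation requested for a block in neither recognized format."""


class Role(str, Enum):
    INCLUSION = "inclusion"
    EXCLUSION = "exclusion"


@dataclass(frozen=True)
class Criterion:
    """One segmented eligibility item.

    ``indent_depth`` counts nesting below the top bullet level (0 = top);
    ``negated`` marks extended-format items phrased as "No ..."; ``ordinal``
    is the 0-based position within the criterion's role section.
    """

    text: str
    role: Role
    indent_depth: int
    negated: bool
    ordinal: int


@dataclass(frozen=True)
class FormatClassification:
    suggested: bool
    extended: bool

    @property
    def either(self) -> bool:
        return self.suggested or self.extended


_HEAD = r"^\s*(?:\d+[.)]\s*)?{}\s*:?\s*$"
INCLUSION_RE = re.compile(_HEAD.format("inclusion criteria"), re.I)
EXCLUSION_RE = re.compile(_HEAD.format("exclusion criteria"), re.I)
TOPIC_RES = {
    name: re.compile(_HEAD.format(name), re.I)
    for name in (
        "disease characteristics",
        "patient characteristics",
        "prior concurrent therapy",
    )
}
# leading "-", "*", "•" or "N." bullets
BULLET_RE = re.compile(r"^(\s*)(?:[-*•]|\d+\.)\s+(\S.*)$")

_NEGATION_RE = re.compile(r"^no\b", re.I)


def _is_heading(line: str) -> bool:
    return bool(
        INCLUSION_RE.match(line)
        or EXCLUSION_RE.match(line)
        or any(p.match(line) for p in TOPIC_RES.values())
    )


def classify_format(eligibility_text: str) -> FormatClassification:
    """Classify an eligibility block into suggested / extended / neither.

    Suggested requires an "Inclusion Criteria" heading before any "Exclusion
    Criteria" heading (the exclusion section may be absent) with at least one
    bullet after it.  Extended requires at least two of the three topic
    headings, each followed by a bulleted list.
    """
    lines = eligibility_text.expandtabs(4).splitlines()
    bullet_idx = [i for i, ln in enumerate(lines) if BULLET_RE.match(ln)]

    inc_idx = next((i for i, ln in enumerate(lines) if INCLUSION_RE.match(ln)), None)
    exc_idx = next((i for i, ln in enumerate(lines) if EXCLUSION_RE.match(ln)), None)
    suggested = (
        inc_idx is not None
        and (exc_idx is None or inc_idx < exc_idx)
        and any(i > inc_idx for i in bullet_idx)
    )

    heading_idx = sorted(i for i, ln in enumerate(lines) if _is_heading(ln))
    topics_with_list = 0
    for pat in TOPIC_RES.values():
        t_idx = next((i for i, ln in enumerate(lines) if pat.match(ln)), None)
        if t_idx is None:
            continue
        next_head = next((h for h in heading_idx if h > t_idx), len(lines))
        if any(t_idx < i < next_head for i in bullet_idx):
            topics_with_list += 1
    extended = topics_with_list >= 2

    return FormatClassification(suggested=suggested, extended=extended)


def segment_criteria(
    eligibility_text: str, classification: Optional[FormatClassification] = None
) -> list[Criterion]:
    """Split a classified eligibility block into individual criteria.

    One criterion per bullet; continuation lines (no bullet marker) are joined
    with a single space.  The role follows the governing heading; all
    extended-format items are inclusion criteria, flagged ``negated`` when
    they open with "No".  Indent depth counts nesting steps below the top
    bullet level: each additional indent of at least 2 spaces opens one level,
    whatever its width (tabs expand to 4 spaces).
    """
    if classification is None:
        classification = classify_format(eligibility_text)
    if not classification.either:
        raise FormatError("text matches neither recognized eligibility format")

    lines = eligibility_text.expandtabs(4).splitlines()
    out: list[Criterion] = []
    role: Optional[Role] = None
    negation_mode = False
    indent_stack: list[int] = []  # bullet indents, one entry per open level
    counters = {Role.INCLUSION: 0, Role.EXCLUSION: 0}
    current: Optional[dict] = None

    def _flush():
        nonlocal current
        if current is None:
            return
        out.append(
            Criterion(
                text=current["text"],
                role=current["role"],
                indent_depth=current["depth"],
                negated=current["negated"],
                ordinal=current["ordinal"],
            )
        )
        current = None

    for line in lines:
        if not line.strip():
            _flush()
            continue
        if INCLUSION_RE.match(line):
            _flush()
            role, negation_mode = Role.INCLUSION, False
            continue
        if EXCLUSION_RE.match(line):
            _flush()
            role, negation_mode = Role.EXCLUSION, False
            continue
        if any(p.match(line) for p in TOPIC_RES.values()):
            _flush()
            role, negation_mode = Role.INCLUSION, True
            continue
        m = BULLET_RE.match(line)
        if m and role is not None:
            _flush()
            indent = len(m.group(1))
            # one depth level per >=2-space indent step, whatever its width
            while len(indent_stack) > 1 and indent <= indent_stack[-1] - 2:
                indent_stack.pop()
            if not indent_stack:
                indent_stack.append(indent)
            elif indent >= indent_stack[-1] + 2:
                indent_stack.append(indent)
            depth = len(indent_stack) - 1
            text = m.group(2).strip()
            current = {
                "text": text,
                "role": role,
                "depth": depth,
                "negated": negation_mode and bool(_NEGATION_RE.match(text)),
                "ordinal": counters[role],
            }
            counters[role] += 1
            continue
        if current is not None:
            current["text"] += " " + line.strip()
    _flush()
    return out


def format_table(corpus: Corpus) -> pd.DataFrame:
    """Per-domain and overall adherence to the two formats, in whole percent.

    Columns: trial count, percent in the suggested format, percent in either
    format, and the count of unclassifiable blocks (reported, not dropped).
    The overall row pools trials, i.e. it is the trial-count-weighted mean.
    """
    rows = []
    tot = {"n": 0, "sug": 0, "either": 0, "neither": 0}
    for tag in corpus.domains:
        recs = corpus.by_domain(tag)
        n = len(recs)
        cls = [classify_format(r.eligibility_text) for r in recs]
        sug = sum(c.suggested for c in cls)
        either = sum(c.either for c in cls)
        rows.append(
            (
                tag,
                n,
                percent_round_half_away(sug, n),
                percent_round_half_away(either, n),
                n - either,
            )
        )
        tot["n"] += n
        tot["sug"] += sug
        tot["either"] += either
        tot["neither"] += n - either
    rows.append(
        (
            "overall",
            tot["n"],
            percent_round_half_away(tot["sug"], tot["n"]),
            percent_round_half_away(tot["either"], tot["n"]),
            tot["neither"],
        )
    )
    return pd.DataFrame(
        rows,
        columns=["domain", "n_trials", "percent_suggested", "percent_either", "n_unclassified"],
    ).set_index("domain")
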