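"""Rule-based detection of four machine-readability barriers in criteria.

The four barrier categories capture, per criterion, properties that make
automated eligibility interpretation hard:

* **sub-population** — the criterion applies only to a subset of the cohort,
  signaled lexically (conditionals such as "If patients are receiving ...")
  or structurally (child criteria indented under a subgroup header);
* **labs and scores** — a laboratory analyte or named medical score with a
  quantitative level ("ANC >= 1,500/uL", "ECOG performance status 0-2");
* **temporal** — a quantity with a time unit anchored to a temporal relation
  ("at least 2 weeks since therapy with the drug");
* **patient behavior/abilities** — volition or ability phrases ("willing to
  comply with ...", "able to walk on a treadmill").

Detection is intentionally rule-based and transparent: the patterns live in a
versioned rule pack (a YAML document shipped with the package, swappable at
run time), every positive flag carries the matched evidence span, and the
version tag is recorded on every output.  Criteria about age or gender are
excluded from temporal and lab detection because the registry already carries
those as structured fields.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .criteria_format import (
    Criterion,
    FormatError,
    Role,
    classify_format,
    segment_criteria,
)
from .registry_io import Corpus, TrialRecord
from ._util import percent_round_half_away

__all__ = [
    "Evidence",
    "CategoryHit",
    "CriterionFlags",
    "BarrierFlags",
    "RulePack",
    "load_rule_pack",
    "detect_temporal",
    "detect_lab_or_score",
    "detect_patient_dependency",
    "detect_subpopulation",
    "annotate_criteria",
    "annotate_trial",
    "annotate_corpus",
    "barrier_table",
    "CATEGORIES",
]

CATEGORIES = ("subpopulation", "lab_or_score", "temporal", "patient_dependent")

# length-preserving normalization so evidence offsets index the original text
_NORMALIZE = str.maketrans({"≤": "<", "≥": ">", "×": "x", "µ": "u", "μ": "u",
                            "–": "-", "—": "-"})


def _normalize(text: str) -> str:
    return text.translate(_NORMALIZE)


@dataclass(frozen=True)
class Evidence:
    """One matched span supporting a barrier flag.

    ``start``/``end`` are character offsets into the *original* criterion
    text; slicing it at the offsets reproduces ``text``.
    """

    category: str
    text: str
    start: int
    end: int


@dataclass(frozen=True)
class CategoryHit:
    flag: bool
    evidence: tuple[Evidence, ...] = ()


def _compile(patterns: Sequence[str]) -> list[re.Pattern]:
    return [re.compile(p, re.I) for p in patterns]


@dataclass
class RulePack:
    """Compiled detector knowledge, loaded from a YAML document."""

    version: str
    age_gender_exclusions: list[re.Pattern]
    temporal_quantity_unit: re.Pattern
    temporal_anchors: list[re.Pattern]
    lab_analytes: list[re.Pattern]
    lab_scores: list[re.Pattern]
    lab_units: list[re.Pattern]
    lab_numeric_context: list[re.Pattern]
    subpop_conditionals: list[re.Pattern]
    subpop_subgroup_headers: list[re.Pattern]
    patient_phrases: list[re.Pattern]

    @classmethod
    def from_dict(cls, doc: dict) -> "RulePack":
        return cls(
            version=str(doc["version"]),
            age_gender_exclusions=_compile(doc.get("age_gender_exclusions", [])),
            temporal_quantity_unit=re.compile(doc["temporal"]["quantity_unit"], re.I),
            temporal_anchors=_compile(doc["temporal"]["anchors"]),
            lab_analytes=_compile(doc["lab_or_score"]["analytes"]),
            lab_scores=_compile(doc["lab_or_score"]["scores"]),
            lab_units=_compile(doc["lab_or_score"]["units"]),
            lab_numeric_context=_compile(doc["lab_or_score"]["numeric_context"]),
            subpop_conditionals=_compile(doc["subpopulation"]["conditionals"]),
            subpop_subgroup_headers=_compile(doc["subpopulation"]["subgroup_headers"]),
            patient_phrases=_compile(doc["patient_dependent"]["phrases"]),
        )


def load_rule_pack(path: Optional[str | Path] = None) -> RulePack:
    """Load a rule pack; with no path, the packaged default pack."""
    if path is None:
        text = resources.files("ctgaudit").joinpath("data/rules.yaml").read_text()
    else:
        text = Path(path).read_text()
    return RulePack.from_dict(yaml.safe_load(text))


def _first_match(patterns: Sequence[re.Pattern], text: str) -> Optional[re.Match]:
    for pat in patterns:
        m = pat.search(text)
        if m:
            return m
    return None


def _evidence(category: str, original: str, m: re.Match) -> Evidence:
    return Evidence(category, original[m.start() : m.end()], m.start(), m.end())


def _is_age_gender(norm: str, rules: RulePack) -> bool:
    return _first_match(rules.age_gender_exclusions, norm) is not None


def detect_temporal(criterion: Criterion, rules: RulePack) -> CategoryHit:
    """Quantity+time-unit co-occurring with a temporal anchor."""
    norm = _normalize(criterion.text)
    if _is_age_gender(norm, rules):
        return CategoryHit(False)
    qty = rules.temporal_quantity_unit.search(norm)
    if not qty:
        return CategoryHit(False)
    anchor = _first_match(rules.temporal_anchors, norm)
    if not anchor:
        return CategoryHit(False)
    ev = [_evidence("temporal", criterion.text, qty)]
    if (anchor.start(), anchor.end()) != (qty.start(), qty.end()):
        ev.append(_evidence("temporal", criterion.text, anchor))
    return CategoryHit(True, tuple(ev))


def detect_lab_or_score(criterion: Criterion, rules: RulePack) -> CategoryHit:
    """Analyte or score term with a quantitative level, unit or comparator."""
    norm = _normalize(criterion.text)
    if _is_age_gender(norm, rules):
        return CategoryHit(False)
    term = _first_match(rules.lab_analytes, norm) or _first_match(
        rules.lab_scores, norm
    )
    if not term:
        return CategoryHit(False)
    ctx = _first_match(rules.lab_units, norm) or _first_match(
        rules.lab_numeric_context, norm
    )
    if not ctx:
        return CategoryHit(False)
    return CategoryHit(
        True,
        (
            _evidence("lab_or_score", criterion.text, term),
            _evidence("lab_or_score", criterion.text, ctx),
        ),
    )


def detect_patient_dependency(criterion: Criterion, rules: RulePack) -> CategoryHit:
    """Volition or ability phrase."""
    norm = _normalize(criterion.text)
    m = _first_match(rules.patient_phrases, norm)
    if not m:
        return CategoryHit(False)
    return CategoryHit(True, (_evidence("patient_dependent", criterion.text, m),))


def detect_subpopulation(
    criteria: Sequence[Criterion], rules: RulePack
) -> list[CategoryHit]:
    """Per-criterion sub-population hits over a whole segmented trial.

    A criterion is flagged when it carries a conditional marker, or when it
    names a condition subgroup and is followed by deeper-indented child
    criteria (the structural rule); the subgroup header is the trigger.
    """
    hits: list[CategoryHit] = []
    for i, c in enumerate(criteria):
        norm = _normalize(c.text)
        m = _first_match(rules.subpop_conditionals, norm)
        if m:
            hits.append(CategoryHit(True, (_evidence("subpopulation", c.text, m),)))
            continue
        header = _first_match(rules.subpop_subgroup_headers, norm)
        has_child = False
        if header:
            for nxt in criteria[i + 1 :]:
                if nxt.role is not c.role:
                    break
                if nxt.indent_depth <= c.indent_depth:
                    break
                has_child = True
                break
        if header and has_child:
            hits.append(
                CategoryHit(True, (_evidence("subpopulation", c.text, header),))
            )
        else:
            hits.append(CategoryHit(False))
    return hits


@dataclass(frozen=True)
class CriterionFlags:
    subpopulation: bool
    lab_or_score: bool
    temporal: bool
    patient_dependent: bool
    evidence: tuple[Evidence, ...] = ()

    def flag(self, category: str) -> bool:
        return getattr(self, category)


def annotate_criteria(
    criteria: Sequence[Criterion], rules: RulePack
) -> list[CriterionFlags]:
    """Run all four detectors over a segmented trial."""
    subpop = detect_subpopulation(criteria, rules)
    out = []
    for c, sp in zip(criteria, subpop):
        lab = detect_lab_or_score(c, rules)
        tmp = detect_temporal(c, rules)
        pat = detect_patient_dependency(c, rules)
        out.append(
            CriterionFlags(
                subpopulation=sp.flag,
                lab_or_score=lab.flag,
                temporal=tmp.flag,
                patient_dependent=pat.flag,
                evidence=sp.evidence + lab.evidence + tmp.evidence + pat.evidence,
            )
        )
    return out


@dataclass(frozen=True)
class BarrierFlags:
    """Per-trial aggregation: a category is true iff >=1 criterion trips it."""

    nct_id: str
    subpopulation: bool
    lab_or_score: bool
    temporal: bool
    patient_dependent: bool
    counts: dict
    degraded: bool
    rules_version: str

    @property
    def any(self) -> bool:
        return (
            self.subpopulation
            or self.lab_or_score
            or self.temporal
            or self.patient_dependent
        )


def _degraded_criteria(record: TrialRecord) -> list[Criterion]:
    """Pseudo-criteria from raw lines for unsegmentable eligibility blocks."""
    lines = [ln.strip() for ln in record.eligibility_text.splitlines() if ln.strip()]
    return [
        Criterion(text=ln, role=Role.INCLUSION, indent_depth=0, negated=False, ordinal=i)
        for i, ln in enumerate(lines)
    ]


def annotate_trial(
    record: TrialRecord,
    criteria: Optional[Sequence[Criterion]] = None,
    rules: Optional[RulePack] = None,
) -> BarrierFlags:
    """Annotate one trial; unsegmentable blocks are processed line-by-line
    in degraded mode (structural sub-population detection unavailable)."""
    if rules is None:
        rules = load_rule_pack()
    degraded = False
    if criteria is None:
        cls = classify_format(record.eligibility_text)
        if cls.either:
            criteria = segment_criteria(record.eligibility_text, cls)
        else:
            criteria = _degraded_criteria(record)
            degraded = True
    flags = annotate_criteria(criteria, rules)
    counts = {cat: sum(f.flag(cat) for f in flags) for cat in CATEGORIES}
    return BarrierFlags(
        nct_id=record.nct_id,
        subpopulation=counts["subpopulation"] > 0,
        lab_or_score=counts["lab_or_score"] > 0,
        temporal=counts["temporal"] > 0,
        patient_dependent=counts["patient_dependent"] > 0,
        counts=counts,
        degraded=degraded,
        rules_version=rules.version,
    )


def annotate_corpus(
    corpus: Corpus, rules: Optional[RulePack] = None
) -> list[BarrierFlags]:
    if rules is None:
        rules = load_rule_pack()
    return [annotate_trial(r, rules=rules) for r in corpus.records]


def barrier_table(
    corpus: Corpus,
    rules: Optional[RulePack] = None,
    flags: Optional[Sequence[BarrierFlags]] = None,
) -> pd.DataFrame:
    """Per-domain whole-percent prevalence of the four categories plus 'any'."""
    if flags is None:
        flags = annotate_corpus(corpus, rules)
    by_id = {f.nct_id: f for f in flags}
    cols = list(CATEGORIES) + ["any"]
    rows = []
    totals = {c: 0 for c in cols}
    total_n = 0
    for tag in corpus.domains:
        recs = corpus.by_domain(tag)
        n = len(recs)
        counts = {c: sum(getattr(by_id[r.nct_id], c) for r in recs) for c in cols}
        for c in cols:
            totals[c] += counts[c]
        total_n += n
        rows.append([tag, n] + [percent_round_half_away(counts[c], n) for c in cols])
    rows.append(
        ["overall", total_n]
        + [percent_round_half_away(totals[c], total_n) for c in cols]
    )
    return pd.DataFrame(rows, columns=["domain", "n_trials"] + cols).set_index("domain")
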