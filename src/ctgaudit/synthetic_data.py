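"""Synthetic registry corpora with planted ground truth.

The generator emits trial records in the classic registry XML dialect with
controllable, per-domain prevalences of status conflicts, eligibility-text
format variants, and the four barrier categories, plus last-update dates
whose staleness is coupled to conflict status and to the trial's true
(unlisted) recruitment state.  Every planted label is recorded in a
:class:`GroundTruth` object so each pipeline stage can be scored against
what was actually embedded.

Criteria texts are rendered from a template bank shipped as data (one file
per category plus distractors).  The templates are written against the
category *definitions*, the detectors against the rule pack — their
agreement is asserted by tests, not built in.

The default spec mirrors the structure of a four-domain audit snapshot
(trial counts 98/113/124/102; conflict rates 14/46/15/19%; per-domain
barrier prevalences and criteria-per-trial means matched to the published
tables) so that desk-scale runs produce comparable tables.
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .criteria_format import Role
from .followup_sampling import (
    FollowUpOutcome,
    SamplingPlan,
    build_contact_plan,
    classify_outcome,
    followup_eligible,
    followup_table,
    stratified_sample,
    AttemptResult,
    ResponseKind,
)
from .registry_io import (
    ContactInfo,
    Corpus,
    DatePrecision,
    FuzzyDate,
    Gender,
    OverallStatus,
    TrialLocation,
    TrialRecord,
    format_fuzzy_date,
    parse_fuzzy_date,
)

__all__ = [
    "DomainSpec",
    "DateModel",
    "ContactModel",
    "CorpusSpec",
    "SpecValidationError",
    "CriterionTruth",
    "TrialTruth",
    "GroundTruth",
    "FollowupParams",
    "default_corpus_spec",
    "generate_corpus",
    "render_criteria",
    "simulate_followup",
    "run_followup_study",
    "load_template_bank",
]

CATEGORIES = ("subpopulation", "lab_or_score", "temporal", "patient_dependent")


class SpecValidationError(ValueError):
    """Invalid generator spec; lists every offending field."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid corpus spec: " + "; ".join(problems))


@dataclass
class DateModel:
    """Log-normal last-update lag model, in days before the reference date.

    Records in the *stale* regime (conflicting, or truly closed) draw their
    lag around ``stale_median_days``; everything else draws around
    ``fresh_median_days``.  The separation is what plants the directional
    recency effects the audit statistics should detect.
    """

    fresh_median_days: float = 60.0
    stale_median_days: float = 600.0
    sigma: float = 0.6
    max_lag_days: int = 2400


@dataclass
class ContactModel:
    p_location_contact: float = 0.85
    p_overall_contact: float = 0.9
    p_backup_contact: float = 0.5
    n_locations_mean: float = 3.0
    p_us_location: float = 0.8


@dataclass
class DomainSpec:
    """Planted parameters for one clinical domain."""

    name: str
    n_trials: int
    reference_date: date
    conflict_prevalence: float
    p_suggested: float
    p_extended: float
    barrier_prevalences: dict
    criteria_mean: float
    criteria_dispersion: float = 4.0
    p_closed: float = 0.3

    @property
    def p_neither(self) -> float:
        return 1.0 - self.p_suggested - self.p_extended


@dataclass
class CorpusSpec:
    domains: list[DomainSpec]
    date_model: DateModel = field(default_factory=DateModel)
    contact_model: ContactModel = field(default_factory=ContactModel)
    seed: int = 0

    def validate(self) -> None:
        problems: list[str] = []
        if not self.domains:
            problems.append("domains: empty")
        for d in self.domains:
            prefix = f"domains[{d.name}]"
            if d.n_trials < 1:
                problems.append(f"{prefix}.n_trials: must be >= 1")
            for fname in ("conflict_prevalence", "p_suggested", "p_extended", "p_closed"):
                v = getattr(d, fname)
                if not 0.0 <= v <= 1.0:
                    problems.append(f"{prefix}.{fname}: {v} not in [0, 1]")
            if not -1e-9 <= d.p_neither <= 1.0:
                problems.append(f"{prefix}: p_suggested + p_extended exceeds 1")
            for cat in CATEGORIES:
                if cat not in d.barrier_prevalences:
                    problems.append(f"{prefix}.barrier_prevalences: missing {cat}")
                elif not 0.0 <= d.barrier_prevalences[cat] <= 1.0:
                    problems.append(f"{prefix}.barrier_prevalences[{cat}]: not in [0, 1]")
            if d.criteria_mean < 1:
                problems.append(f"{prefix}.criteria_mean: must be >= 1")
            if d.criteria_dispersion <= 0:
                problems.append(f"{prefix}.criteria_dispersion: must be > 0")
        cm = self.contact_model
        for fname in ("p_location_contact", "p_overall_contact", "p_backup_contact", "p_us_location"):
            v = getattr(cm, fname)
            if not 0.0 <= v <= 1.0:
                problems.append(f"contact_model.{fname}: {v} not in [0, 1]")
        dm = self.date_model
        if dm.fresh_median_days <= 0 or dm.stale_median_days <= 0 or dm.sigma <= 0:
            problems.append("date_model: medians and sigma must be > 0")
        if problems:
            raise SpecValidationError(problems)


def default_corpus_spec(seed: int = 0) -> CorpusSpec:
    """Four domains matching the published audit's structure.

    Trial counts, retrieval (reference) dates, conflict rates, format mixes,
    per-domain barrier prevalences and mean criteria per trial are the
    published per-domain values; those values constitute the planted ground
    truth the pipeline is scored against.
    """
    domains = [
        DomainSpec(
            name="gleevec",
            n_trials=98,
            reference_date=date(2013, 6, 6),
            conflict_prevalence=0.14,
            p_suggested=0.88,
            p_extended=0.09,
            barrier_prevalences={
                "subpopulation": 0.42,
                "lab_or_score": 0.70,
                "temporal": 0.78,
                "patient_dependent": 0.61,
            },
            criteria_mean=1641 / 98,
        ),
        DomainSpec(
            name="cataract",
            n_trials=113,
            reference_date=date(2013, 6, 12),
            conflict_prevalence=0.46,
            p_suggested=0.98,
            p_extended=0.01,
            barrier_prevalences={
                "subpopulation": 0.12,
                "lab_or_score": 0.48,
                "temporal": 0.32,
                "patient_dependent": 0.54,
            },
            criteria_mean=1163 / 113,
        ),
        DomainSpec(
            name="neuroblastoma",
            n_trials=124,
            reference_date=date(2013, 6, 20),
            conflict_prevalence=0.15,
            p_suggested=0.79,
            p_extended=0.18,
            barrier_prevalences={
                "subpopulation": 0.35,
                "lab_or_score": 0.73,
                "temporal": 0.65,
                "patient_dependent": 0.49,
            },
            criteria_mean=1979 / 124,
        ),
        DomainSpec(
            name="rheumatoid_arthritis",
            n_trials=102,
            reference_date=date(2013, 7, 5),
            conflict_prevalence=0.19,
            p_suggested=0.98,
            p_extended=0.0,
            barrier_prevalences={
                "subpopulation": 0.17,
                "lab_or_score": 0.45,
                "temporal": 0.64,
                "patient_dependent": 0.47,
            },
            criteria_mean=1167 / 102,
        ),
    ]
    return CorpusSpec(domains=domains, seed=seed)


# ---------------------------------------------------------------------------
# Ground truth containers


@dataclass(frozen=True)
class CriterionTruth:
    category: Optional[str]  # None = plain distractor
    role: str
    depth: int
    negated: bool
    template_id: str
    text: str


@dataclass
class TrialTruth:
    nct_id: str
    domain_tag: str
    true_status: str  # "open" | "closed"
    conflict: bool
    format_label: str  # "suggested" | "extended" | "neither"
    barrier_flags: dict
    criteria: list[CriterionTruth]


@dataclass
class GroundTruth:
    trials: dict  # nct_id -> TrialTruth
    seed: int

    def to_json(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "trials": {
                nid: {**asdict(t), "criteria": [asdict(c) for c in t.criteria]}
                for nid, t in self.trials.items()
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        doc = json.loads(Path(path).read_text())
        trials = {}
        for nid, t in doc["trials"].items():
            crits = [CriterionTruth(**c) for c in t.pop("criteria")]
            trials[nid] = TrialTruth(**t, criteria=crits)
        return cls(trials=trials, seed=doc["seed"])


# ---------------------------------------------------------------------------
# Template bank

_SLOT_VALUES = {
    "drug": (
        "imatinib", "methotrexate", "prednisone", "cyclophosphamide",
        "rituximab", "bevacizumab", "hydroxychloroquine", "dexamethasone",
    ),
    "disease": (
        "chronic myeloid leukemia", "neuroblastoma", "cataract",
        "rheumatoid arthritis", "gastrointestinal stromal tumor",
        "uveitis", "melanoma",
    ),
    "condition": (
        "hepatic impairment", "renal insufficiency", "diabetes mellitus",
        "congestive heart failure", "interstitial lung disease",
    ),
    "procedure": (
        "radiation safety procedures", "the imaging schedule",
        "pharmacokinetic sampling", "the dosing diary",
    ),
    "activity": (
        "walk on a treadmill", "cycle on a stationary bike",
        "swallow capsules whole", "complete the questionnaire unaided",
    ),
}

_TEMPLATE_FILES = {
    "temporal": "temporal.txt",
    "lab_or_score": "lab_or_score.txt",
    "patient_dependent": "patient_dependent.txt",
    "subpopulation": "subpopulation.txt",
    "subpopulation_parent": "subpopulation_parent.txt",
    "subpopulation_child": "subpopulation_child.txt",
    "distractor": "distractor.txt",
}


def load_template_bank() -> dict:
    """Load the shipped template bank: category -> list of (id, template)."""
    bank = {}
    base = resources.files("ctgaudit").joinpath("data/templates")
    for cat, fname in _TEMPLATE_FILES.items():
        lines = [
            ln.strip()
            for ln in base.joinpath(fname).read_text().splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
        bank[cat] = [(f"{cat}/{i}", ln) for i, ln in enumerate(lines)]
    return bank


def _fill_template(template: str, rng: np.random.Generator) -> str:
    fields = {f for _, f, _, _ in string.Formatter().parse(template) if f}
    values = {}
    for f in fields:
        if f in _SLOT_VALUES:
            choices = _SLOT_VALUES[f]
            values[f] = choices[int(rng.integers(len(choices)))]
        elif f == "n":
            values[f] = int(rng.integers(2, 13))
        elif f == "num":
            values[f] = f"{int(rng.integers(1, 200)) * 500:,}"
        elif f == "dec":
            values[f] = f"{rng.integers(10, 60) / 10:.1f}"
        elif f == "lo":
            values[f] = 0
        elif f == "hi":
            values[f] = int(rng.integers(1, 4))
        elif f == "pct":
            values[f] = int(rng.integers(5, 10)) * 10
        else:
            raise KeyError(f"unknown template slot {{{f}}} in {template!r}")
    return template.format(**values)


# ---------------------------------------------------------------------------
# Criteria planning and rendering

_TOPIC_HEADINGS = (
    "DISEASE CHARACTERISTICS:",
    "PATIENT CHARACTERISTICS:",
    "PRIOR CONCURRENT THERAPY:",
)

_NEGATABLE_PREFIXES = (
    "Known ", "Current ", "History of ", "Major ", "Evidence of ",
    "Concomitant ", "Prior ", "Presence of ",
)


def _plan_criteria(
    barrier_flags: dict,
    format_label: str,
    n_criteria: int,
    rng: np.random.Generator,
    bank: dict,
) -> list[CriterionTruth]:
    """Assign categories and templates to a trial's criteria, in render order."""
    units: list[str] = []
    for cat in CATEGORIES:
        if not barrier_flags.get(cat):
            continue
        count = 1 + int(rng.random() < 0.35)
        if cat == "subpopulation":
            structural = format_label != "neither" and rng.random() < 0.5
            units.extend(["subpopulation_nested" if structural else "subpopulation"])
            units.extend(["subpopulation"] * (count - 1))
        else:
            units.extend([cat] * count)

    def unit_size(u: str) -> int:
        return 2 if u == "subpopulation_nested" else 1

    planted_size = sum(unit_size(u) for u in units)
    n_criteria = max(n_criteria, planted_size, 1)
    units.extend(["distractor"] * (n_criteria - planted_size))
    # the extended layout needs >=2 top-level items so two topic headings can
    # each govern a list
    while format_label == "extended" and len(units) < 2:
        units.append("distractor")
    units = [units[i] for i in rng.permutation(len(units))]

    out: list[CriterionTruth] = []
    for u in units:
        if u == "subpopulation_nested":
            pid, ptpl = bank["subpopulation_parent"][
                int(rng.integers(len(bank["subpopulation_parent"])))
            ]
            cid, ctpl = bank["subpopulation_child"][
                int(rng.integers(len(bank["subpopulation_child"])))
            ]
            out.append(
                CriterionTruth(
                    category="subpopulation",
                    role=Role.INCLUSION.value,
                    depth=0,
                    negated=False,
                    template_id=pid,
                    text=_fill_template(ptpl, rng),
                )
            )
            out.append(
                CriterionTruth(
                    category=None,
                    role=Role.INCLUSION.value,
                    depth=1,
                    negated=False,
                    template_id=cid,
                    text=_fill_template(ctpl, rng),
                )
            )
            continue
        cat = None if u == "distractor" else u
        tid, tpl = bank[u][int(rng.integers(len(bank[u])))]
        text = _fill_template(tpl, rng)
        role = Role.INCLUSION
        if format_label == "suggested" and u == "distractor" and rng.random() < 0.35:
            role = Role.EXCLUSION
        if format_label == "extended" and u == "distractor" and rng.random() < 0.25:
            for prefix in _NEGATABLE_PREFIXES:
                if text.startswith(prefix):
                    text = "No " + text[0].lower() + text[1:]
                    break
        # the negation flag is an extended-format notion: suggested-format
        # sections make the polarity explicit, so only extended items carry it
        negated = format_label == "extended" and bool(re.match(r"no\b", text, re.I))
        out.append(
            CriterionTruth(
                category=cat,
                role=role.value,
                depth=0,
                negated=negated,
                template_id=tid,
                text=text,
            )
        )

    if format_label == "extended":
        out = [
            CriterionTruth(c.category, Role.INCLUSION.value, c.depth, c.negated,
                           c.template_id, c.text)
            for c in out
        ]
    if format_label == "suggested" and all(c.role == Role.EXCLUSION.value for c in out):
        first = out[0]
        out[0] = CriterionTruth(first.category, Role.INCLUSION.value, first.depth,
                                first.negated, first.template_id, first.text)
    # suggested format lists inclusion items first, then the exclusion section;
    # nested children must stay attached to their parent, so partition stably
    if format_label == "suggested":
        inc, exc = [], []
        for c in out:
            (inc if c.role == Role.INCLUSION.value else exc).append(c)
        out = inc + exc
    return out


def render_criteria(
    plan: Sequence[CriterionTruth], format_label: str, rng: Optional[np.random.Generator] = None
) -> str:
    """Render a criteria plan as eligibility text in the requested format.

    ``rng`` is accepted for symmetry with the planning step but the rendering
    itself is deterministic given the plan.
    """
    def bullet(c: CriterionTruth) -> str:
        return " " * (2 + 2 * c.depth) + "-  " + c.text

    if format_label == "suggested":
        inc = [c for c in plan if c.role == Role.INCLUSION.value]
        exc = [c for c in plan if c.role == Role.EXCLUSION.value]
        lines = ["Inclusion Criteria:", ""]
        lines += [bullet(c) for c in inc]
        if exc:
            lines += ["", "Exclusion Criteria:", ""]
            lines += [bullet(c) for c in exc]
        return "\n".join(lines)

    if format_label == "extended":
        # group the plan into top-level blocks (a criterion plus its deeper-
        # indented children), then deal blocks over 2-3 topic headings so each
        # used heading governs a non-empty list
        blocks: list[list[CriterionTruth]] = []
        for c in plan:
            if c.depth == 0 or not blocks:
                blocks.append([c])
            else:
                blocks[-1].append(c)
        n_topics = 3 if len(blocks) >= 3 else 2
        groups: list[list[CriterionTruth]] = [[] for _ in range(n_topics)]
        sizes = [len(blocks) // n_topics] * n_topics
        for i in range(len(blocks) % n_topics):
            sizes[i] += 1
        idx = 0
        for gi, s in enumerate(sizes):
            for blk in blocks[idx : idx + s]:
                groups[gi].extend(blk)
            idx += s
        lines: list[str] = []
        for heading, group in zip(_TOPIC_HEADINGS, groups):
            if not group:
                continue
            if lines:
                lines.append("")
            lines += [heading, ""]
            lines += [bullet(c) for c in group]
        return "\n".join(lines)

    # "neither": free prose lines, no headings, no bullet markers
    return "\n".join(c.text for c in plan)


# ---------------------------------------------------------------------------
# Record assembly

_CITIES = {
    "United States": (
        ("Boston", 42.36, -71.06), ("New York", 40.71, -74.01),
        ("Chicago", 41.88, -87.63), ("Houston", 29.76, -95.37),
        ("Los Angeles", 34.05, -118.24), ("Seattle", 47.61, -122.33),
        ("Denver", 39.74, -104.99), ("Atlanta", 33.75, -84.39),
        ("Philadelphia", 39.95, -75.17), ("Baltimore", 39.29, -76.61),
    ),
    "Canada": (("Toronto", 43.65, -79.38), ("Montreal", 45.50, -73.57)),
    "Germany": (("Berlin", 52.52, 13.40), ("Munich", 48.14, 11.58)),
    "United Kingdom": (("London", 51.51, -0.13), ("Manchester", 53.48, -2.24)),
    "France": (("Paris", 48.86, 2.35), ("Lyon", 45.76, 4.84)),
}
_NON_US = ("Canada", "Germany", "United Kingdom", "France")
_SURNAMES = (
    "Rivera", "Chen", "Okafor", "Schmidt", "Nakamura", "Jones",
    "Haddad", "Kowalski", "Osei", "Lindqvist",
)
_FACILITY_KINDS = ("Medical Center", "University Hospital", "Clinic", "Research Institute")


def _make_contact(rng: np.random.Generator, nct_id: str, tag: str) -> ContactInfo:
    name = f"{_SURNAMES[int(rng.integers(len(_SURNAMES)))]}, {'ABCDEFGHIJ'[int(rng.integers(10))]}."
    phone = f"+1-617-555-{int(rng.integers(10000)):04d}" if rng.random() < 0.9 else None
    email = f"{tag}.{nct_id.lower()}@example.org" if rng.random() < 0.7 else None
    if phone is None and email is None:
        phone = f"+1-617-555-{int(rng.integers(10000)):04d}"
    return ContactInfo(name=name, phone=phone, email=email)


def _make_locations(
    rng: np.random.Generator, nct_id: str, cm: ContactModel
) -> tuple[TrialLocation, ...]:
    n = int(rng.poisson(cm.n_locations_mean))
    locs = []
    for j in range(n):
        country = (
            "United States"
            if rng.random() < cm.p_us_location
            else _NON_US[int(rng.integers(len(_NON_US)))]
        )
        city, lat0, lon0 = _CITIES[country][int(rng.integers(len(_CITIES[country])))]
        lat = round(lat0 + rng.uniform(-0.3, 0.3), 4)
        lon = round(lon0 + rng.uniform(-0.3, 0.3), 4)
        contact = (
            _make_contact(rng, nct_id, f"site{j}")
            if rng.random() < cm.p_location_contact
            else None
        )
        kind = _FACILITY_KINDS[int(rng.integers(len(_FACILITY_KINDS)))]
        locs.append(
            TrialLocation(
                facility=f"{city} {kind} {j + 1}",
                city=city,
                country=country,
                latitude=lat,
                longitude=lon,
                contact=contact,
            )
        )
    return tuple(locs)


def _month_before(d: date, min_days: int, max_days: int, rng: np.random.Generator) -> FuzzyDate:
    """A month-precision date whose whole month lies strictly before ``d``."""
    back = int(rng.integers(max(min_days, 40), max(max_days, 41)))
    target = d - timedelta(days=back)
    return FuzzyDate(target.year, target.month, None, DatePrecision.MONTH)


def generate_corpus(spec: CorpusSpec) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus and its planted ground truth; pure function of the spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bank = load_template_bank()
    dm, cm = spec.date_model, spec.contact_model
    records: list[TrialRecord] = []
    truths: dict[str, TrialTruth] = {}
    reference_dates: dict[str, date] = {}
    counter = 1
    for dom in spec.domains:
        ref = dom.reference_date
        reference_dates[dom.name] = ref
        for _ in range(dom.n_trials):
            nct_id = f"NCT{counter:08d}"
            counter += 1
            conflict = bool(rng.random() < dom.conflict_prevalence)
            closed = bool(rng.random() < dom.p_closed)
            stale = conflict or closed
            median = dm.stale_median_days if stale else dm.fresh_median_days
            lag = int(min(dm.max_lag_days, rng.lognormal(np.log(median), dm.sigma)))
            last_update = ref - timedelta(days=lag)
            first_received = last_update - timedelta(days=int(rng.integers(60, 1200)))

            if conflict:
                completion = _month_before(ref, 40, max(41, lag + 200), rng)
            elif rng.random() < 0.25:
                completion = None
            else:
                fut = ref + timedelta(days=int(rng.integers(60, 720)))
                completion = FuzzyDate(fut.year, fut.month, None, DatePrecision.MONTH)

            status = (
                OverallStatus.RECRUITING
                if rng.random() < 0.85
                else OverallStatus.NOT_YET_RECRUITING
            )
            u = rng.random()
            if u < dom.p_suggested:
                fmt = "suggested"
            elif u < dom.p_suggested + dom.p_extended:
                fmt = "extended"
            else:
                fmt = "neither"

            flags = {
                cat: bool(rng.random() < dom.barrier_prevalences[cat])
                for cat in CATEGORIES
            }
            r = dom.criteria_dispersion
            p = r / (r + dom.criteria_mean)
            n_criteria = max(1, int(rng.negative_binomial(r, p)))
            plan = _plan_criteria(flags, fmt, n_criteria, rng, bank)
            eligibility_text = render_criteria(plan, fmt)

            record = TrialRecord(
                nct_id=nct_id,
                domain_tag=dom.name,
                overall_status=status,
                first_received=FuzzyDate.from_date(first_received),
                last_update=FuzzyDate.from_date(last_update),
                completion_date=completion,
                eligibility_text=eligibility_text,
                minimum_age=f"{int(rng.integers(18, 51))} Years",
                maximum_age=None if rng.random() < 0.5 else f"{int(rng.integers(60, 86))} Years",
                gender=Gender.ALL if rng.random() < 0.9 else Gender(
                    ("female", "male")[int(rng.integers(2))]
                ),
                healthy_volunteers=bool(rng.random() < 0.15),
                locations=_make_locations(rng, nct_id, cm),
                overall_contact=(
                    _make_contact(rng, nct_id, "overall")
                    if rng.random() < cm.p_overall_contact
                    else None
                ),
                backup_contact=None,
            )
            if record.overall_contact is not None and rng.random() < cm.p_backup_contact:
                record = TrialRecord(
                    **{**asdict_record(record), "backup_contact": _make_contact(rng, nct_id, "backup")}
                )
            records.append(record)
            truths[nct_id] = TrialTruth(
                nct_id=nct_id,
                domain_tag=dom.name,
                true_status="closed" if closed else "open",
                conflict=conflict,
                format_label=fmt,
                barrier_flags=flags,
                criteria=plan,
            )
    corpus = Corpus(
        records=records,
        reference_dates=reference_dates,
        provenance=f"ctgaudit synthetic corpus (seed={spec.seed})",
    )
    return corpus, GroundTruth(trials=truths, seed=spec.seed)


def asdict_record(record: TrialRecord) -> dict:
    """Shallow field dict of a TrialRecord (keeps nested objects intact)."""
    return {
        f: getattr(record, f)
        for f in (
            "nct_id", "domain_tag", "overall_status", "first_received",
            "last_update", "completion_date", "eligibility_text",
            "minimum_age", "maximum_age", "gender", "healthy_volunteers",
            "locations", "overall_contact", "backup_contact",
        )
    }


# ---------------------------------------------------------------------------
# Follow-up simulation


@dataclass
class FollowupParams:
    """Response model for the simulated outreach.

    ``p_contactable`` is the per-trial probability that any attempt gets
    through (its complement is the planted no-answer rate); given contact,
    ``p_refuse`` yields a refusal and ``p_knows`` an informative answer that
    reports the trial's true recruitment state.
    """

    p_contactable: float = 0.69
    p_refuse: float = 0.03
    p_knows: float = 0.97
    p_drop: float = 0.0


def simulate_followup(
    corpus: Corpus,
    truth: GroundTruth,
    params: Optional[FollowupParams] = None,
    seed: int = 0,
    nct_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Simulate phone/email outreach; returns one row per attempt.

    Columns: ``nct_id``, ``attempt_index``, ``result``, ``date``.  Trials
    with an empty contact plan contribute no rows (downstream classification
    turns that into ``no_answer``).  Deterministic under ``seed``.
    """
    params = params or FollowupParams()
    rng = np.random.default_rng(seed)
    by_id = {r.nct_id: r for r in corpus.records}
    if nct_ids is None:
        nct_ids = [r.nct_id for r in corpus.records]
    rows = []
    for nid in nct_ids:
        record = by_id[nid]
        plan = build_contact_plan(record)
        n_att = len(plan.attempts)
        if n_att == 0:
            continue
        ref = corpus.reference_dates[record.domain_tag]
        if rng.random() > params.p_contactable:
            for i in range(n_att):
                rows.append((nid, i, ResponseKind.UNREACHABLE.value, ""))
            continue
        reached = int(rng.integers(n_att))
        for i in range(reached):
            rows.append((nid, i, ResponseKind.UNREACHABLE.value, ""))
        if rng.random() < params.p_refuse or rng.random() > params.p_knows:
            rows.append((nid, reached, ResponseKind.REFUSED.value, ""))
            continue
        if truth.trials[nid].true_status == "open":
            rows.append((nid, reached, ResponseKind.CONFIRMED_OPEN.value, ""))
        else:
            close = _month_before(ref, 40, 400, rng)
            rows.append(
                (nid, reached, ResponseKind.CONFIRMED_CLOSED.value, format_fuzzy_date(close))
            )
    return pd.DataFrame(rows, columns=["nct_id", "attempt_index", "result", "date"])


def outcomes_from_responses(
    nct_ids: Sequence[str], responses: pd.DataFrame
) -> list[FollowUpOutcome]:
    """Classify every listed trial from its (possibly absent) response rows."""
    outcomes = []
    grouped = dict(tuple(responses.groupby("nct_id"))) if len(responses) else {}
    for nid in nct_ids:
        attempt_rows = grouped.get(nid)
        results: list[AttemptResult] = []
        if attempt_rows is not None:
            for _, row in attempt_rows.sort_values("attempt_index").iterrows():
                d = parse_fuzzy_date(row["date"]) if row["date"] else None
                results.append(AttemptResult(ResponseKind(row["result"]), date=d))
        outcomes.append(classify_outcome(nid, results))
    return outcomes


def run_followup_study(
    corpus: Corpus,
    truth: GroundTruth,
    seed: int = 0,
    per_segment: int = 10,
    segments: int = 4,
    params: Optional[FollowupParams] = None,
):
    """Full verification-study pipeline on a synthetic corpus.

    Per domain: filter to open US-located trials, draw the stratified
    sample, simulate outreach, classify outcomes.  Returns ``(plans,
    outcomes_by_domain, table)``.
    """
    params = params or FollowupParams()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * len(corpus.domains))
    plans: dict[str, SamplingPlan] = {}
    outcomes: dict[str, list[FollowUpOutcome]] = {}
    dropped: dict[str, int] = {}
    for k, tag in enumerate(corpus.domains):
        eligible = [r for r in corpus.by_domain(tag) if followup_eligible(r)]
        sample_seed = int(children[2 * k].generate_state(1)[0] % (2**31))
        sim_seed = int(children[2 * k + 1].generate_state(1)[0] % (2**31))
        plan = stratified_sample(
            eligible, per_segment=per_segment, segments=segments,
            seed=sample_seed, domain_tag=tag,
        )
        if params.p_drop > 0 and plan.sampled_ids:
            drop_rng = np.random.default_rng(sim_seed + 1)
            mask = drop_rng.random(len(plan.sampled_ids)) < params.p_drop
            plan = SamplingPlan(
                **{**asdict(plan), "dropped_ids": tuple(
                    nid for nid, m in zip(plan.sampled_ids, mask) if m
                )},
            )
        plans[tag] = plan
        responses = simulate_followup(
            corpus, truth, params=params, seed=sim_seed,
            nct_ids=plan.active_sampled_ids,
        )
        outcomes[tag] = outcomes_from_responses(plan.active_sampled_ids, responses)
        dropped[tag] = len(plan.dropped_ids)
    return plans, outcomes, followup_table(outcomes, dropped_by_domain=dropped)
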