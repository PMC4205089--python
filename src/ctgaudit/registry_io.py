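"""Registry record model and I/O for the classic ClinicalTrials.gov XML dialect.

The data model mirrors one ``clinical_study`` document per trial: identifiers,
overall recruitment status, partially specified ("fuzzy") dates, the free-text
eligibility block, recruitment locations with city-level coordinates, and
contact details.  Readers and writers target the classic public XML export
(``clinical_study`` root with ``eligibility/criteria/textblock``), not the
newer JSON API.  Coordinates are expected to be present on the record itself;
no geocoding service is ever contacted.
"""

from __future__ import annotations

import calendar
import csv
import re
from dataclasses import dataclass
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Optional

import pandas as pd
from lxml import etree

__all__ = [
    "DatePrecision",
    "FuzzyDate",
    "OverallStatus",
    "ContactInfo",
    "TrialLocation",
    "TrialRecord",
    "Corpus",
    "RegistryError",
    "DateParseError",
    "XmlParseError",
    "parse_fuzzy_date",
    "format_fuzzy_date",
    "read_trial_xml",
    "write_trial_xml",
    "read_corpus",
    "write_corpus",
    "corpus_to_frame",
]


class RegistryError(ValueError):
    """Base class for registry model and I/O errors."""


class DateParseError(RegistryError):
    """An unrecognized registry date string."""

    def __init__(self, text: str):
        self.text = text
        super().__init__(f"unrecognized registry date string: {text!r}")


class XmlParseError(RegistryError):
    """Malformed or incomplete trial XML."""


class DatePrecision(str, Enum):
    YEAR = "year"
    MONTH = "month"
    DAY = "day"


@dataclass(frozen=True, order=False)
class FuzzyDate:
    """A registry date known to year, month, or day precision.

    Registry exports print dates as ``"June 6, 2013"``, ``"June 2013"`` or
    ``"2013"``; the precision records how much of the date was actually given.
    """

    year: int
    month: Optional[int] = None
    day: Optional[int] = None
    precision: DatePrecision = DatePrecision.DAY

    def __post_init__(self):
        p = DatePrecision(self.precision)
        object.__setattr__(self, "precision", p)
        if p is DatePrecision.DAY:
            if self.month is None or self.day is None:
                raise RegistryError("day precision requires month and day")
            try:
                date(self.year, self.month, self.day)
            except ValueError as exc:
                raise RegistryError(f"invalid calendar date: {exc}") from None
        elif p is DatePrecision.MONTH:
            if self.month is None or self.day is not None:
                raise RegistryError("month precision requires month and no day")
            if not 1 <= self.month <= 12:
                raise RegistryError(f"month out of range: {self.month}")
        else:
            if self.month is not None or self.day is not None:
                raise RegistryError("year precision admits neither month nor day")

    @classmethod
    def from_date(cls, d: date) -> "FuzzyDate":
        return cls(d.year, d.month, d.day, DatePrecision.DAY)


_MONTH_NAMES = list(calendar.month_name)  # index 1..12
_MONTH_LOOKUP = {name.lower(): i for i, name in enumerate(_MONTH_NAMES) if name}

_DAY_RE = re.compile(r"^\s*([A-Za-z]+)\s+(\d{1,2}),\s*(\d{4})\s*$")
_MONTH_RE = re.compile(r"^\s*([A-Za-z]+)\s+(\d{4})\s*$")
_YEAR_RE = re.compile(r"^\s*(\d{4})\s*$")


def parse_fuzzy_date(text: str) -> FuzzyDate:
    """Parse a classic registry date string.

    Accepted shapes: ``"Month DD, YYYY"``, ``"Month YYYY"``, ``"YYYY"``.
    Raises :class:`DateParseError` for anything else.
    """
    m = _DAY_RE.match(text)
    if m:
        month = _MONTH_LOOKUP.get(m.group(1).lower())
        if month is None:
            raise DateParseError(text)
        try:
            return FuzzyDate(int(m.group(3)), month, int(m.group(2)), DatePrecision.DAY)
        except RegistryError:
            raise DateParseError(text) from None
    m = _MONTH_RE.match(text)
    if m:
        month = _MONTH_LOOKUP.get(m.group(1).lower())
        if month is None:
            raise DateParseError(text)
        return FuzzyDate(int(m.group(2)), month, None, DatePrecision.MONTH)
    m = _YEAR_RE.match(text)
    if m:
        return FuzzyDate(int(m.group(1)), None, None, DatePrecision.YEAR)
    raise DateParseError(text)


def format_fuzzy_date(d: FuzzyDate) -> str:
    if d.precision is DatePrecision.DAY:
        return f"{_MONTH_NAMES[d.month]} {d.day}, {d.year}"
    if d.precision is DatePrecision.MONTH:
        return f"{_MONTH_NAMES[d.month]} {d.year}"
    return str(d.year)


class OverallStatus(str, Enum):
    NOT_YET_RECRUITING = "not_yet_recruiting"
    RECRUITING = "recruiting"
    ACTIVE_NOT_RECRUITING = "active_not_recruiting"
    COMPLETED = "completed"
    TERMINATED = "terminated"
    WITHDRAWN = "withdrawn"
    SUSPENDED = "suspended"
    ENROLLING_BY_INVITATION = "enrolling_by_invitation"
    UNKNOWN = "unknown"

    @property
    def is_open(self) -> bool:
        """Open-for-recruitment statuses in the audit sense."""
        return self in (OverallStatus.RECRUITING, OverallStatus.NOT_YET_RECRUITING)


_STATUS_LABELS = {
    OverallStatus.NOT_YET_RECRUITING: "Not yet recruiting",
    OverallStatus.RECRUITING: "Recruiting",
    OverallStatus.ACTIVE_NOT_RECRUITING: "Active, not recruiting",
    OverallStatus.COMPLETED: "Completed",
    OverallStatus.TERMINATED: "Terminated",
    OverallStatus.WITHDRAWN: "Withdrawn",
    OverallStatus.SUSPENDED: "Suspended",
    OverallStatus.ENROLLING_BY_INVITATION: "Enrolling by invitation",
    OverallStatus.UNKNOWN: "Unknown status",
}
_STATUS_FROM_LABEL = {v.lower(): k for k, v in _STATUS_LABELS.items()}


def parse_status(text: str) -> OverallStatus:
    """Case-insensitive mapping of registry status strings.

    Unrecognized strings map to ``unknown`` rather than erroring, so an audit
    degrades gracefully on vocabulary drift.
    """
    return _STATUS_FROM_LABEL.get(text.strip().lower(), OverallStatus.UNKNOWN)


class Gender(str, Enum):
    ALL = "all"
    FEMALE = "female"
    MALE = "male"


@dataclass(frozen=True)
class ContactInfo:
    name: str
    phone: Optional[str] = None
    email: Optional[str] = None

    def __post_init__(self):
        if self.phone is None and self.email is None:
            raise RegistryError("a contact must carry a phone or an email")


@dataclass(frozen=True)
class TrialLocation:
    facility: str
    city: str
    country: str
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    contact: Optional[ContactInfo] = None

    def __post_init__(self):
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise RegistryError(f"latitude out of range: {self.latitude}")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise RegistryError(f"longitude out of range: {self.longitude}")


_NCT_RE = re.compile(r"^NCT\d{8}$")


@dataclass(frozen=True)
class TrialRecord:
    """One registry entry, restricted to the fields the audit consumes."""

    nct_id: str
    domain_tag: str
    overall_status: OverallStatus
    first_received: FuzzyDate
    last_update: FuzzyDate
    eligibility_text: str = ""
    completion_date: Optional[FuzzyDate] = None
    minimum_age: Optional[str] = None
    maximum_age: Optional[str] = None
    gender: Gender = Gender.ALL
    healthy_volunteers: bool = False
    locations: tuple[TrialLocation, ...] = ()
    overall_contact: Optional[ContactInfo] = None
    backup_contact: Optional[ContactInfo] = None

    def __post_init__(self):
        if not _NCT_RE.match(self.nct_id):
            raise RegistryError(f"invalid trial identifier: {self.nct_id!r}")
        object.__setattr__(self, "locations", tuple(self.locations))
        fr, lu = self.first_received, self.last_update
        if fr.precision is DatePrecision.DAY and lu.precision is DatePrecision.DAY:
            if date(lu.year, lu.month, lu.day) < date(fr.year, fr.month, fr.day):
                raise RegistryError(
                    f"{self.nct_id}: last_update precedes first_received"
                )


@dataclass
class Corpus:
    """A set of trial records plus the per-domain audit reference dates.

    ``reference_dates`` maps each domain tag to the day the set was retrieved
    from the registry; that day plays the role of "today" for every audit of
    that domain's records, keeping runs reproducible regardless of the wall
    clock.
    """

    records: list[TrialRecord]
    reference_dates: dict[str, date]
    provenance: str = ""

    def __post_init__(self):
        seen: set[str] = set()
        for r in self.records:
            if r.nct_id in seen:
                raise RegistryError(f"duplicate trial identifier {r.nct_id}")
            seen.add(r.nct_id)
            if r.domain_tag not in self.reference_dates:
                raise RegistryError(
                    f"{r.nct_id}: domain {r.domain_tag!r} has no reference date"
                )

    @property
    def domains(self) -> list[str]:
        return sorted(self.reference_dates)

    def by_domain(self, tag: str) -> list[TrialRecord]:
        return [r for r in self.records if r.domain_tag == tag]


# ---------------------------------------------------------------------------
# XML dialect


def _dedent_textblock(raw: str) -> str:
    """Strip the common leading indent of a textblock, keeping relative indent.

    Relative indentation is semantic (nested criteria mark sub-populations),
    so only the indent shared by every non-blank line is removed.  Leading and
    trailing blank lines go; interior blank lines stay.
    """
    lines = raw.splitlines()
    while lines and not lines[0].strip():
        lines.pop(0)
    while lines and not lines[-1].strip():
        lines.pop()
    nonblank = [ln for ln in lines if ln.strip()]
    if not nonblank:
        return ""
    common = min(len(ln) - len(ln.lstrip(" ")) for ln in nonblank)
    return "\n".join(ln[common:].rstrip() if ln.strip() else "" for ln in lines)


_TEXTBLOCK_INDENT = " " * 8


def _indent_textblock(text: str) -> str:
    if not text:
        return "\n    "
    body = "\n".join(
        _TEXTBLOCK_INDENT + ln if ln.strip() else "" for ln in text.splitlines()
    )
    return "\n" + body + "\n    "


def _contact_from_element(el: Optional[etree._Element]) -> Optional[ContactInfo]:
    if el is None:
        return None
    name = (el.findtext("last_name") or "").strip()
    phone = (el.findtext("phone") or "").strip() or None
    email = (el.findtext("email") or "").strip() or None
    if phone is None and email is None:
        return None
    return ContactInfo(name=name, phone=phone, email=email)


def _contact_to_element(parent: etree._Element, tag: str, c: Optional[ContactInfo]):
    if c is None:
        return
    el = etree.SubElement(parent, tag)
    etree.SubElement(el, "last_name").text = c.name
    if c.phone is not None:
        etree.SubElement(el, "phone").text = c.phone
    if c.email is not None:
        etree.SubElement(el, "email").text = c.email


def read_trial_xml(document: str, domain_tag: str = "") -> TrialRecord:
    """Parse one ``clinical_study`` XML document into a :class:`TrialRecord`.

    ``domain_tag`` is not part of the registry dialect; it is carried on the
    corpus manifest and supplied by the caller.
    """
    try:
        root = etree.fromstring(document.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise XmlParseError(f"malformed trial XML: {exc}") from exc
    if root.tag != "clinical_study":
        raise XmlParseError(f"expected <clinical_study> root, got <{root.tag}>")

    nct_id = (root.findtext("id_info/nct_id") or "").strip()
    if not nct_id:
        raise XmlParseError("record rejected: missing id_info/nct_id")

    def _date(tag: str) -> Optional[FuzzyDate]:
        text = root.findtext(tag)
        if text is None or not text.strip():
            return None
        return parse_fuzzy_date(text)

    first_received = _date("firstreceived_date")
    last_update = _date("lastchanged_date")
    if first_received is None or last_update is None:
        raise XmlParseError(f"{nct_id}: missing firstreceived/lastchanged dates")

    elig = root.find("eligibility")
    eligibility_text = ""
    minimum_age = maximum_age = None
    gender = Gender.ALL
    healthy = False
    if elig is not None:
        tb = elig.findtext("criteria/textblock")
        if tb is not None:
            eligibility_text = _dedent_textblock(tb)
        minimum_age = (elig.findtext("minimum_age") or "").strip() or None
        maximum_age = (elig.findtext("maximum_age") or "").strip() or None
        g = (elig.findtext("gender") or "").strip().lower()
        if g in ("female", "male"):
            gender = Gender(g)
        healthy = (elig.findtext("healthy_volunteers") or "").strip().lower() == "yes"

    locations = []
    for loc in root.findall("location"):
        fac = loc.find("facility")
        lat = loc.findtext("facility/address/latitude")
        lon = loc.findtext("facility/address/longitude")
        locations.append(
            TrialLocation(
                facility=(fac.findtext("name") or "").strip() if fac is not None else "",
                city=(loc.findtext("facility/address/city") or "").strip(),
                country=(loc.findtext("facility/address/country") or "").strip(),
                latitude=float(lat) if lat else None,
                longitude=float(lon) if lon else None,
                contact=_contact_from_element(loc.find("contact")),
            )
        )

    return TrialRecord(
        nct_id=nct_id,
        domain_tag=domain_tag,
        overall_status=parse_status(root.findtext("overall_status") or ""),
        first_received=first_received,
        last_update=last_update,
        completion_date=_date("completion_date"),
        eligibility_text=eligibility_text,
        minimum_age=minimum_age,
        maximum_age=maximum_age,
        gender=gender,
        healthy_volunteers=healthy,
        locations=tuple(locations),
        overall_contact=_contact_from_element(root.find("overall_contact")),
        backup_contact=_contact_from_element(root.find("overall_contact_backup")),
    )


def write_trial_xml(record: TrialRecord) -> str:
    """Serialize a record to the same dialect :func:`read_trial_xml` consumes."""
    root = etree.Element("clinical_study")
    id_info = etree.SubElement(root, "id_info")
    etree.SubElement(id_info, "nct_id").text = record.nct_id
    etree.SubElement(root, "overall_status").text = _STATUS_LABELS[record.overall_status]
    etree.SubElement(root, "firstreceived_date").text = format_fuzzy_date(
        record.first_received
    )
    etree.SubElement(root, "lastchanged_date").text = format_fuzzy_date(
        record.last_update
    )
    if record.completion_date is not None:
        etree.SubElement(root, "completion_date").text = format_fuzzy_date(
            record.completion_date
        )

    elig = etree.SubElement(root, "eligibility")
    criteria = etree.SubElement(elig, "criteria")
    etree.SubElement(criteria, "textblock").text = _indent_textblock(
        record.eligibility_text
    )
    if record.minimum_age is not None:
        etree.SubElement(elig, "minimum_age").text = record.minimum_age
    if record.maximum_age is not None:
        etree.SubElement(elig, "maximum_age").text = record.maximum_age
    etree.SubElement(elig, "gender").text = record.gender.value.capitalize() if record.gender is not Gender.ALL else "All"
    etree.SubElement(elig, "healthy_volunteers").text = (
        "Yes" if record.healthy_volunteers else "No"
    )

    _contact_to_element(root, "overall_contact", record.overall_contact)
    _contact_to_element(root, "overall_contact_backup", record.backup_contact)

    for loc in record.locations:
        loc_el = etree.SubElement(root, "location")
        fac = etree.SubElement(loc_el, "facility")
        etree.SubElement(fac, "name").text = loc.facility
        addr = etree.SubElement(fac, "address")
        etree.SubElement(addr, "city").text = loc.city
        etree.SubElement(addr, "country").text = loc.country
        if loc.latitude is not None:
            etree.SubElement(addr, "latitude").text = repr(loc.latitude)
        if loc.longitude is not None:
            etree.SubElement(addr, "longitude").text = repr(loc.longitude)
        _contact_to_element(loc_el, "contact", loc.contact)

    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ---------------------------------------------------------------------------
# Corpus directory layout: one XML file per trial + a manifest CSV

MANIFEST_COLUMNS = ["nct_id", "domain_tag", "file", "reference_date"]


def write_corpus(corpus: Corpus, out_dir: str | Path) -> Path:
    """Write one XML file per trial plus ``manifest.csv``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for r in corpus.records:
            fname = f"{r.nct_id}.xml"
            (out / fname).write_text(write_trial_xml(r))
            writer.writerow(
                [r.nct_id, r.domain_tag, fname,
                 corpus.reference_dates[r.domain_tag].isoformat()]
            )
    return manifest


def read_corpus(manifest_path: str | Path) -> Corpus:
    """Load a corpus from a manifest CSV plus the trial XML files beside it."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    records: list[TrialRecord] = []
    reference_dates: dict[str, date] = {}
    with manifest_path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            ref = date.fromisoformat(row["reference_date"])
            tag = row["domain_tag"]
            prev = reference_dates.setdefault(tag, ref)
            if prev != ref:
                raise RegistryError(
                    f"conflicting reference dates for domain {tag!r}"
                )
            doc = (base / row["file"]).read_text()
            rec = read_trial_xml(doc, domain_tag=tag)
            if rec.nct_id != row["nct_id"]:
                raise RegistryError(
                    f"manifest id {row['nct_id']} != document id {rec.nct_id}"
                )
            records.append(rec)
    return Corpus(records=records, reference_dates=reference_dates,
                  provenance=str(manifest_path))


def corpus_to_frame(corpus: Corpus) -> pd.DataFrame:
    """Flat tabular export of all scalar record fields."""
    rows = []
    for r in corpus.records:
        rows.append(
            {
                "nct_id": r.nct_id,
                "domain_tag": r.domain_tag,
                "overall_status": r.overall_status.value,
                "first_received": format_fuzzy_date(r.first_received),
                "last_update": format_fuzzy_date(r.last_update),
                "completion_date": (
                    format_fuzzy_date(r.completion_date)
                    if r.completion_date is not None
                    else ""
                ),
                "minimum_age": r.minimum_age or "",
                "maximum_age": r.maximum_age or "",
                "gender": r.gender.value,
                "healthy_volunteers": r.healthy_volunteers,
                "n_locations": len(r.locations),
                "has_overall_contact": r.overall_contact is not None,
                "has_backup_contact": r.backup_contact is not None,
                "reference_date": corpus.reference_dates[r.domain_tag].isoformat(),
            }
        )
    return pd.DataFrame(rows)
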