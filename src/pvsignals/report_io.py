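"""Reading spontaneous-report tables into one normalized case model.

Two file dialects are supported:

* **FAERS-style** quarterly ASCII tables — ``$``-delimited ``DEMO`` / ``DRUG`` /
  ``REAC`` / ``INDI`` / ``THER`` / ``OUTC`` files keyed by ``PRIMARYID``.
* **JADER-style** comma-delimited ``demo`` / ``drug`` / ``reac`` files keyed by
  case id + row sequence, with decade age bands and a fixed reporting country
  (Japan).

Both readers emit :class:`NormalizedReport` — one record per raw case row —
which downstream stages deduplicate (:func:`deduplicate`), restrict to a
suspect drug (:func:`filter_suspect`) and count.  The counting unit everywhere
in this package is the *report* (case), not the drug–event row.

Dates are parsed leniently (``YYYYMMDD``, ``YYYYMM``, ``YYYY``, with ``/`` or
``-`` separators tolerated) into :class:`PartialDate`; partial dates keep their
year for annual tallies but read as absent wherever day-level arithmetic is
required (time-to-onset analysis).  Unparseable fields become absent and are
counted, never fatal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .vocab import DrugLexicon

logger = logging.getLogger(__name__)

SOURCE_FAERS = "FAERS"
SOURCE_JADER = "JADER"

SEX_VALUES = ("male", "female", "unknown")
ROLE_VALUES = ("primary_suspect", "secondary_suspect", "concomitant", "interacting", "unknown")
REPORTER_VALUES = ("health_professional", "non_health_professional", "unknown")
AGE_GROUPS = ("<18", "18-65", ">65", "unknown")

# FAERS role codes <-> normalized roles
_ROLE_FROM_FAERS = {"PS": "primary_suspect", "SS": "secondary_suspect",
                    "C": "concomitant", "I": "interacting"}
_ROLE_TO_FAERS = {v: k for k, v in _ROLE_FROM_FAERS.items()}
_ROLE_FROM_JADER = {"suspect": "primary_suspect", "concomitant": "concomitant",
                    "interacting": "interacting"}
_ROLE_TO_JADER = {"primary_suspect": "suspect", "secondary_suspect": "suspect",
                  "concomitant": "concomitant", "interacting": "interacting",
                  "unknown": ""}

_SEX_FROM_CODE = {"M": "male", "F": "female", "UNK": "unknown", "": "unknown"}
_SEX_TO_CODE = {"male": "M", "female": "F", "unknown": ""}

# FAERS OCCP_COD reporter codes
_REPORTER_FROM_FAERS = {"MD": "health_professional", "PH": "health_professional",
                        "RN": "health_professional", "OT": "health_professional",
                        "HP": "health_professional",
                        "CN": "non_health_professional", "LW": "non_health_professional",
                        "": "unknown"}
_REPORTER_TO_FAERS = {"health_professional": "MD", "non_health_professional": "CN",
                      "unknown": ""}

# years per unit of each FAERS AGE_COD
_AGE_UNIT_YEARS = {"YR": 1.0, "DEC": 10.0, "MON": 1.0 / 12.0, "WK": 7.0 / 365.25,
                   "DY": 1.0 / 365.25, "HR": 1.0 / 8766.0, "": 1.0}

FAERS_FILES = ("DEMO", "DRUG", "REAC", "INDI", "THER", "OUTC")
JADER_FILES = ("demo", "drug", "reac")


class IngestionError(RuntimeError):
    """A mandatory input table is missing or unreadable."""


@dataclass(frozen=True, order=True)
class PartialDate:
    """A calendar date of day, month or year precision.

    ``to_date()`` is ``None`` unless the date is full precision, which is how
    partial dates are excluded from day-level arithmetic while keeping their
    year available for annual tallies.
    """

    year: int
    month: int | None = None
    day: int | None = None

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        return "month" if self.month is not None else "year"

    def to_date(self) -> date | None:
        if self.day is None or self.month is None:
            return None
        return date(self.year, self.month, self.day)

    @classmethod
    def from_date(cls, d: date) -> "PartialDate":
        return cls(d.year, d.month, d.day)

    def compact(self) -> str:
        """Render as YYYY[MM[DD]] (the FAERS wire format)."""
        out = f"{self.year:04d}"
        if self.month is not None:
            out += f"{self.month:02d}"
            if self.day is not None:
                out += f"{self.day:02d}"
        return out

    def sort_key(self) -> tuple[int, int, int]:
        return (self.year, self.month or 0, self.day or 0)


def parse_partial_date(text: str | None) -> PartialDate | None:
    """Parse YYYYMMDD / YYYYMM / YYYY (separators tolerated); None if hopeless."""
    if text is None:
        return None
    digits = "".join(ch for ch in str(text).strip() if ch.isdigit())
    try:
        if len(digits) == 8:
            return PartialDate.from_date(date(int(digits[:4]), int(digits[4:6]), int(digits[6:8])))
        if len(digits) == 6:
            d = PartialDate(int(digits[:4]), int(digits[4:6]))
            if not 1 <= d.month <= 12:
                return None
            return d
        if len(digits) == 4:
            year = int(digits)
            return PartialDate(year) if 1900 <= year <= 2100 else None
    except ValueError:
        return None
    return None


@dataclass(frozen=True)
class DrugUse:
    """One drug mention on a report."""

    name_raw: str
    name_canonical: str
    role: str = "unknown"


@dataclass(frozen=True)
class NormalizedReport:
    """One spontaneous adverse-event case in source-independent form."""

    report_id: str
    case_id: str
    case_version: int
    source: str
    receipt_date: PartialDate | None
    sex: str
    age_years: float | None
    country: str
    reporter_type: str
    outcomes: tuple[str, ...]
    drugs: tuple[DrugUse, ...]
    events: tuple[str, ...]
    indications: tuple[str, ...] = ()
    therapy_start_date: PartialDate | None = None
    event_onset_date: PartialDate | None = None

    @property
    def age_group(self) -> str:
        """Age band used in demographic tables: <18, 18-65 (inclusive), >65."""
        if self.age_years is None:
            return "unknown"
        if self.age_years < 18:
            return "<18"
        if self.age_years <= 65:
            return "18-65"
        return ">65"

    def has_drug(self, canonical: str, roles: Sequence[str]) -> bool:
        return any(d.name_canonical == canonical and d.role in roles for d in self.drugs)


@dataclass(frozen=True)
class DedupPolicy:
    """Which version of a duplicated case survives deduplication.

    The total order is: highest case version, then latest receipt date, then
    lexicographically largest report id — the standard "keep the most recent
    version" rule for spontaneous-report case series.
    """

    keep: tuple[str, ...] = ("highest_case_version", "latest_receipt_date", "largest_report_id")

    def sort_key(self, report: NormalizedReport):
        receipt = report.receipt_date.sort_key() if report.receipt_date else (0, 0, 0)
        parts = {"highest_case_version": report.case_version,
                 "latest_receipt_date": receipt,
                 "largest_report_id": report.report_id}
        return tuple(parts[name] for name in self.keep)


@dataclass
class IngestStats:
    """Row-level counters produced by the dialect readers."""

    demo_rows: int = 0
    reports: int = 0
    orphan_rows: int = 0
    malformed_rows: int = 0
    unparseable_dates: int = 0
    unmatched_drug_names: int = 0


# ---------------------------------------------------------------------------
# FAERS dialect
# ---------------------------------------------------------------------------

def _read_table(path: Path, sep: str, stats: IngestStats) -> pd.DataFrame:
    bad = {"n": 0}

    def _on_bad(line):  # pragma: no cover - exercised via malformed fixtures
        bad["n"] += 1
        return None

    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                        engine="python", on_bad_lines=_on_bad)
    if bad["n"]:
        logger.warning("%s: skipped %d malformed line(s)", path.name, bad["n"])
        stats.malformed_rows += bad["n"]
    return frame


def _faers_path(directory: Path, name: str) -> Path | None:
    for candidate in (directory / f"{name}.txt", directory / f"{name.lower()}.txt"):
        if candidate.exists():
            return candidate
    return None


def _group_rows(frame: pd.DataFrame, key: str) -> dict[str, list[dict]]:
    grouped: dict[str, list[dict]] = {}
    for row in frame.to_dict("records"):
        grouped.setdefault(str(row.get(key, "")), []).append(row)
    return grouped


def _parse_age(age_text: str, age_cod: str, stats: IngestStats) -> float | None:
    age_text = age_text.strip()
    if not age_text:
        return None
    try:
        value = float(age_text)
    except ValueError:
        return None
    unit = _AGE_UNIT_YEARS.get(age_cod.strip().upper())
    if unit is None:
        logger.warning("unknown AGE_COD %r; treating age as absent", age_cod)
        return None
    years = value * unit
    return years if years >= 0 else None


def read_faers_quarter(directory: str | Path,
                       lexicon: DrugLexicon | None = None,
                       stats: IngestStats | None = None) -> list[NormalizedReport]:
    """Read a FAERS-style ``$``-delimited quarter directory.

    DEMO and REAC are mandatory; DRUG/INDI/THER/OUTC enrich the record when
    present.  Child rows whose PRIMARYID has no DEMO row are skipped and
    counted in ``stats.orphan_rows``.
    """
    directory = Path(directory)
    stats = stats if stats is not None else IngestStats()
    lexicon = lexicon if lexicon is not None else DrugLexicon.default()

    paths = {name: _faers_path(directory, name) for name in FAERS_FILES}
    for mandatory in ("DEMO", "REAC"):
        if paths[mandatory] is None:
            raise IngestionError(f"missing mandatory FAERS table {mandatory} in {directory}")
    if paths["DRUG"] is None:
        logger.warning("DRUG table absent in %s; drug-level analysis will be empty", directory)

    demo = _read_table(paths["DEMO"], "$", stats)
    stats.demo_rows += len(demo)
    children = {name: (_group_rows(_read_table(paths[name], "$", stats), "PRIMARYID")
                       if paths[name] is not None else {})
                for name in ("DRUG", "REAC", "INDI", "THER", "OUTC")}

    known_ids = {str(r) for r in demo.get("PRIMARYID", pd.Series(dtype=str))}
    for name, grouped in children.items():
        orphans = sum(len(rows) for rid, rows in grouped.items() if rid not in known_ids)
        if orphans:
            logger.warning("%s: %d row(s) without a DEMO row skipped", name, orphans)
            stats.orphan_rows += orphans

    def _parse_date_counted(text: str) -> PartialDate | None:
        parsed = parse_partial_date(text)
        if parsed is None and str(text).strip():
            stats.unparseable_dates += 1
        return parsed

    reports: list[NormalizedReport] = []
    for row in demo.to_dict("records"):
        rid = str(row.get("PRIMARYID", ""))
        drugs = []
        for drow in children["DRUG"].get(rid, ()):
            raw = drow.get("DRUGNAME", "")
            canonical, matched = lexicon.normalize(raw)
            if not matched:
                stats.unmatched_drug_names += 1
            drugs.append(DrugUse(name_raw=raw, name_canonical=canonical,
                                 role=_ROLE_FROM_FAERS.get(drow.get("ROLE_COD", "").strip(), "unknown")))
        events = tuple(r.get("PT", "") for r in children["REAC"].get(rid, ()) if r.get("PT", ""))
        indications = tuple(r.get("INDI_PT", "") for r in children["INDI"].get(rid, ())
                            if r.get("INDI_PT", ""))
        outcomes = tuple(sorted(r.get("OUTC_COD", "") for r in children["OUTC"].get(rid, ())
                                if r.get("OUTC_COD", "")))
        ther_rows = children["THER"].get(rid, ())
        start = next((d for d in (_parse_date_counted(r.get("START_DT", "")) for r in ther_rows)
                      if d is not None), None)
        try:
            version = int(float(row.get("CASEVERSION", "1") or 1))
        except ValueError:
            version = 1
        reports.append(NormalizedReport(
            report_id=rid,
            case_id=str(row.get("CASEID", rid)),
            case_version=max(version, 1),
            source=SOURCE_FAERS,
            receipt_date=_parse_date_counted(row.get("FDA_DT", "")),
            sex=_SEX_FROM_CODE.get(row.get("SEX", "").strip().upper(), "unknown"),
            age_years=_parse_age(row.get("AGE", ""), row.get("AGE_COD", ""), stats),
            country=row.get("OCCR_COUNTRY", "").strip() or "unknown",
            reporter_type=_REPORTER_FROM_FAERS.get(row.get("OCCP_COD", "").strip().upper(), "unknown"),
            outcomes=outcomes,
            drugs=tuple(drugs),
            events=events,
            indications=indications,
            therapy_start_date=start,
            event_onset_date=_parse_date_counted(row.get("EVENT_DT", "")),
        ))
    stats.reports += len(reports)
    return reports


# ---------------------------------------------------------------------------
# JADER dialect
# ---------------------------------------------------------------------------

def parse_age_band(band: str) -> float | None:
    """Decade age band ("60s", "60代", "60歳代") → band midpoint in years."""
    band = band.strip()
    if not band:
        return None
    digits = "".join(ch for ch in band if ch.isdigit())
    if not digits:
        return None
    try:
        decade = (int(digits) // 10) * 10
    except ValueError:
        return None
    return float(decade + 5)


def age_to_band(age_years: float | None) -> str:
    if age_years is None:
        return ""
    return f"{(int(age_years) // 10) * 10}s"


def read_jader(directory: str | Path,
               lexicon: DrugLexicon | None = None,
               stats: IngestStats | None = None) -> list[NormalizedReport]:
    """Read a JADER-style comma-delimited directory (demo/drug/reac tables).

    The reporting country is fixed to Japan and ages arrive as decade bands
    mapped to their midpoints.  Case versions are assigned by occurrence order
    within each case id (the dialect carries no explicit version column).
    """
    directory = Path(directory)
    stats = stats if stats is not None else IngestStats()
    lexicon = lexicon if lexicon is not None else DrugLexicon.default()

    paths = {name: directory / f"{name}.csv" for name in JADER_FILES}
    for mandatory in ("demo", "reac"):
        if not paths[mandatory].exists():
            raise IngestionError(f"missing mandatory JADER table {mandatory}.csv in {directory}")

    demo = _read_table(paths["demo"], ",", stats)
    stats.demo_rows += len(demo)
    drug_rows = (_group_rows(_read_table(paths["drug"], ",", stats), "case_id")
                 if paths["drug"].exists() else {})
    reac_rows = _group_rows(_read_table(paths["reac"], ",", stats), "case_id")

    known = {str(c) for c in demo.get("case_id", pd.Series(dtype=str))}
    # JADER demo rows repeat per case version; count versions as we stream
    for grouped in (drug_rows, reac_rows):
        orphans = sum(len(rows) for cid, rows in grouped.items() if cid not in known)
        if orphans:
            stats.orphan_rows += orphans
            logger.warning("JADER child rows without demo row: %d skipped", orphans)

    def _chunks(rows: list[dict], seq_col: str) -> list[list[dict]]:
        # child rows for successive versions of one case are written back to
        # back with the sequence restarting at 1; split on those restarts
        chunks: list[list[dict]] = []
        for row in rows:
            try:
                seq = int(float(row.get(seq_col, "") or 0))
            except ValueError:
                seq = 0
            if seq == 1 or not chunks:
                chunks.append([])
            chunks[-1].append(row)
        return chunks

    drug_chunks = {cid: _chunks(rows, "drug_seq") for cid, rows in drug_rows.items()}
    reac_chunks = {cid: _chunks(rows, "reac_seq") for cid, rows in reac_rows.items()}

    version_counter: dict[str, int] = {}
    reports: list[NormalizedReport] = []
    for row in demo.to_dict("records"):
        cid = str(row.get("case_id", ""))
        version = version_counter.get(cid, 0) + 1
        version_counter[cid] = version
        case_drugs = drug_chunks.get(cid, [])
        case_reacs = reac_chunks.get(cid, [])
        my_drugs = case_drugs[version - 1] if version <= len(case_drugs) else \
            (case_drugs[-1] if case_drugs else [])
        my_reacs = case_reacs[version - 1] if version <= len(case_reacs) else \
            (case_reacs[-1] if case_reacs else [])
        drugs = []
        indications: list[str] = []
        start = None
        for drow in my_drugs:
            raw = drow.get("drug_name", "")
            canonical, matched = lexicon.normalize(raw)
            if not matched:
                stats.unmatched_drug_names += 1
            drugs.append(DrugUse(name_raw=raw, name_canonical=canonical,
                                 role=_ROLE_FROM_JADER.get(drow.get("involvement", "").strip(), "unknown")))
            for ind in str(drow.get("indication", "")).split(";"):
                if ind and ind not in indications:
                    indications.append(ind)
            if start is None:
                start = parse_partial_date(drow.get("start_date", ""))
        events = []
        onset = None
        for rrow in my_reacs:
            pt = rrow.get("pt", "")
            if pt:
                events.append(pt)
            if onset is None:
                onset = parse_partial_date(rrow.get("onset_date", ""))
        outcomes = tuple(sorted(o for o in str(row.get("outcome", "")).split(";") if o))
        reports.append(NormalizedReport(
            report_id=f"{cid}-{version}",
            case_id=cid,
            case_version=version,
            source=SOURCE_JADER,
            receipt_date=parse_partial_date(row.get("receipt_date", "")),
            sex=_SEX_FROM_CODE.get(row.get("sex", "").strip().upper(), "unknown"),
            age_years=parse_age_band(row.get("age_band", "")),
            country="Japan",
            reporter_type=row.get("reporter", "").strip() or "unknown",
            outcomes=outcomes,
            drugs=tuple(drugs),
            events=tuple(events),
            indications=tuple(indications),
            therapy_start_date=start,
            event_onset_date=onset,
        ))
    stats.reports += len(reports)
    return reports


# ---------------------------------------------------------------------------
# Case-level transformations
# ---------------------------------------------------------------------------

def deduplicate(reports: Iterable[NormalizedReport],
                policy: DedupPolicy | None = None) -> list[NormalizedReport]:
    """Keep exactly one report per (source, case id) under the policy's order.

    Idempotent and pure: the input collection is never mutated, and survivors
    keep their first-appearance order.
    """
    policy = policy or DedupPolicy()
    best: dict[tuple[str, str], NormalizedReport] = {}
    order: list[tuple[str, str]] = []
    for report in reports:
        key = (report.source, report.case_id)
        if key not in best:
            best[key] = report
            order.append(key)
        elif policy.sort_key(report) > policy.sort_key(best[key]):
            best[key] = report
    return [best[key] for key in order]


def filter_suspect(reports: Iterable[NormalizedReport],
                   canonical_drug: str,
                   roles: Sequence[str] = ("primary_suspect",)) -> list[NormalizedReport]:
    """Reports naming ``canonical_drug`` in one of the given suspect roles.

    Default is primary suspect only; widen ``roles`` to include
    ``"secondary_suspect"`` for the broader reading of "suspected drug".
    """
    reports = list(reports)
    selected = [r for r in reports if r.has_drug(canonical_drug, roles)]
    if not selected:
        seen_anywhere = any(d.name_canonical == canonical_drug
                            for r in reports for d in r.drugs)
        if not seen_anywhere:
            logger.warning("drug %r not present in corpus under any role", canonical_drug)
    return selected
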