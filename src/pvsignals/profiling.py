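"""Descriptive surfaces over a deduplicated report corpus.

Covers the standard reporting profile of a pharmacovigilance case series:

* demographic summary (sex, age group, indications, countries, outcomes,
  reporter type) with per-source and pooled counts, recomputed percentages and
  the male-to-female ratio;
* annual distribution of reports by receipt year;
* SOC-level distribution of reaction mentions (report-level counting);
* time-to-onset from therapy start to event onset, with the early-onset bins
  0–7 / 8–30 / 31–60 / 61–90 / 91–180 / >180 days;
* tumor vs non-tumor indication stratification of the signal pipeline.

All percentages are recomputed from counts (rounded half-up to two decimals)
and audited for self-consistency before a summary is returned.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contingency import DEFAULT_SUSPECT_ROLES, build_tables
from .report_io import AGE_GROUPS, NormalizedReport
from .signal_stats import (BcpnnPriors, SignalCriteria, SignalRecord,
                           rank_signals, score_tables)
from .vocab import MeddraDictionary, fold

logger = logging.getLogger(__name__)

TOTAL_COLUMN = "Total"
DEFAULT_ONSET_EDGES = (7, 30, 60, 90, 180)


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal round-half-up (table conventions round 0.005 upward)."""
    exp = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(exp, rounding=ROUND_HALF_UP))


def percentage(count: int, denominator: int) -> float | None:
    if denominator == 0:
        return None
    return round_half_up(100.0 * count / denominator)


# ---------------------------------------------------------------------------
# Demographics
# ---------------------------------------------------------------------------

@dataclass
class DemographicSummary:
    """Per-category counts and recomputed percentages, per source and pooled."""

    table: pd.DataFrame                 # variable, category, <src> count/pct ...
    n_reports: dict[str, int]           # per source + Total
    male_female_ratio: dict[str, float | None]

    def audit(self) -> None:
        """Every percentage must equal its count over the column denominator."""
        for _, row in self.table.iterrows():
            for column, denom in self.n_reports.items():
                expected = percentage(int(row[f"{column}_n"]), denom)
                got = row[f"{column}_pct"]
                if expected is None or (got is None or pd.isna(got)):
                    consistent = expected is None and (got is None or pd.isna(got))
                else:
                    consistent = abs(expected - got) < 1e-12
                if not consistent:
                    raise AssertionError(
                        f"inconsistent percentage for {row['variable']}/{row['category']}"
                        f" in {column}: {got} != {expected}")


def _category_counts(reports: Sequence[NormalizedReport], top_indications: int = 20
                     ) -> dict[str, list[tuple[str, Counter]]]:
    sex: Counter = Counter()
    age: Counter = Counter()
    country: Counter = Counter()
    reporter: Counter = Counter()
    outcome: Counter = Counter()
    indication: Counter = Counter()
    for r in reports:
        sex[r.sex] += 1
        age[r.age_group] += 1
        country[r.country] += 1
        reporter[r.reporter_type] += 1
        if r.outcomes:
            for code in r.outcomes:
                outcome[code] += 1
        else:
            outcome["unknown"] += 1
        if r.indications:
            for ind in r.indications:
                indication[ind] += 1
        else:
            indication["unknown"] += 1
    return {"sex": sex, "age_group": age, "indication": indication,
            "country": country, "outcome": outcome, "reporter_type": reporter}


def demographic_summary(reports: Iterable[NormalizedReport],
                        top_indications: int = 20) -> DemographicSummary:
    """Demographic/clinical characteristics table for a deduplicated corpus.

    Indications beyond the pooled top ``top_indications`` collapse into
    "Other".  The male-to-female ratio is reported to two decimals per column
    and is undefined (None) when a column has no female reports.
    """
    reports = list(reports)
    sources = sorted({r.source for r in reports})
    columns = sources + [TOTAL_COLUMN]
    per_source = {src: [r for r in reports if r.source == src] for src in sources}
    per_source[TOTAL_COLUMN] = reports
    n_reports = {col: len(per_source[col]) for col in columns}

    counts = {col: _category_counts(per_source[col]) for col in columns}

    pooled_ind = counts[TOTAL_COLUMN]["indication"]
    top = [name for name, _ in pooled_ind.most_common() if name != "unknown"][:top_indications]

    rows = []

    def add_row(variable: str, category: str, getter) -> None:
        row = {"variable": variable, "category": category}
        for col in columns:
            n = getter(counts[col])
            row[f"{col}_n"] = n
            row[f"{col}_pct"] = percentage(n, n_reports[col])
        rows.append(row)

    for category in ("female", "male", "unknown"):
        add_row("sex", category, lambda c, k=category: c["sex"].get(k, 0))
    for category in AGE_GROUPS:
        add_row("age_group", category, lambda c, k=category: c["age_group"].get(k, 0))
    for category in top:
        add_row("indication", category, lambda c, k=category: c["indication"].get(k, 0))
    add_row("indication", "Other",
            lambda c: sum(n for k, n in c["indication"].items()
                          if k not in top and k != "unknown"))
    add_row("indication", "unknown", lambda c: c["indication"].get("unknown", 0))
    for category in sorted(counts[TOTAL_COLUMN]["country"]):
        add_row("country", category, lambda c, k=category: c["country"].get(k, 0))
    for category in sorted(counts[TOTAL_COLUMN]["outcome"]):
        add_row("outcome", category, lambda c, k=category: c["outcome"].get(k, 0))
    for category in sorted(counts[TOTAL_COLUMN]["reporter_type"]):
        add_row("reporter_type", category,
                lambda c, k=category: c["reporter_type"].get(k, 0))

    ratios = {}
    for col in columns:
        males = counts[col]["sex"].get("male", 0)
        females = counts[col]["sex"].get("female", 0)
        ratios[col] = round_half_up(males / females) if females else None

    summary = DemographicSummary(pd.DataFrame(rows), n_reports, ratios)
    summary.audit()
    return summary


# ---------------------------------------------------------------------------
# Annual and SOC distributions
# ---------------------------------------------------------------------------

def annual_distribution(reports: Iterable[NormalizedReport]
                        ) -> dict[str, dict[str | int, int]]:
    """Report counts by receipt year, per source and pooled.

    Reports without a parseable receipt year tally under ``"unknown"``.
    """
    out: dict[str, Counter] = {TOTAL_COLUMN: Counter()}
    for r in reports:
        key: str | int = r.receipt_date.year if r.receipt_date else "unknown"
        out.setdefault(r.source, Counter())[key] += 1
        out[TOTAL_COLUMN][key] += 1
    return {src: dict(counter) for src, counter in out.items()}


def soc_distribution(reports: Iterable[NormalizedReport],
                     dictionary: MeddraDictionary) -> pd.DataFrame:
    """Report-level SOC mention counts with proportions, sorted descending.

    A report contributes once per SOC regardless of how many of its PTs map
    there; proportions are over total SOC mentions (so they sum to 1).
    Unknown PTs accumulate under the "Unmapped" sentinel.
    """
    counter: Counter = Counter()
    for r in reports:
        counter.update({dictionary.map(pt) for pt in r.events})
    total = sum(counter.values())
    rows = [{"soc": soc, "count": n, "proportion": n / total if total else np.nan}
            for soc, n in counter.most_common()]
    return pd.DataFrame(rows, columns=["soc", "count", "proportion"])


# ---------------------------------------------------------------------------
# Time to onset
# ---------------------------------------------------------------------------

@dataclass
class OnsetSummary:
    """Time from therapy start to event onset over the evaluable reports."""

    n_reports: int
    n_evaluable: int
    n_excluded: int
    median_days: float | None
    bin_counts: dict[str, int]
    cumulative: dict[str, float]

    def __post_init__(self) -> None:
        assert self.n_evaluable + self.n_excluded == self.n_reports
        assert sum(self.bin_counts.values()) == self.n_evaluable


def _bin_labels(edges: Sequence[int]) -> list[str]:
    labels = [f"0-{edges[0]}"]
    labels += [f"{lo + 1}-{hi}" for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append(f">{edges[-1]}")
    return labels


def time_to_onset(reports: Iterable[NormalizedReport],
                  bin_edges: Sequence[int] = DEFAULT_ONSET_EDGES) -> OnsetSummary:
    """Onset-delay summary over reports providing both day-precision dates.

    A report is evaluable when therapy start and event onset are both full
    dates and onset is not before start; everything else (partial or missing
    dates, negative delays) is excluded and counted.
    """
    reports = list(reports)
    delays = []
    for r in reports:
        start = r.therapy_start_date.to_date() if r.therapy_start_date else None
        onset = r.event_onset_date.to_date() if r.event_onset_date else None
        if start is None or onset is None or onset < start:
            continue
        delays.append((onset - start).days)

    labels = _bin_labels(bin_edges)
    bins: dict[str, int] = {label: 0 for label in labels}
    for days in delays:
        for edge, label in zip(bin_edges, labels):
            if days <= edge:
                bins[label] += 1
                break
        else:
            bins[labels[-1]] += 1

    n_eval = len(delays)
    cumulative: dict[str, float] = {}
    running = 0
    for label in labels:
        running += bins[label]
        cumulative[label] = running / n_eval if n_eval else float("nan")
    return OnsetSummary(
        n_reports=len(reports),
        n_evaluable=n_eval,
        n_excluded=len(reports) - n_eval,
        median_days=float(np.median(delays)) if delays else None,
        bin_counts=bins,
        cumulative=cumulative,
    )


# ---------------------------------------------------------------------------
# Tumor vs non-tumor stratification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndicationLexicon:
    """Keyword lists classifying indication text as tumor or non-tumor.

    Matching is folded-substring containment; the two lists must be disjoint.
    A report matching a tumor keyword is tumor even if a non-tumor keyword
    also matches elsewhere on the report (malignancy dominates).
    """

    tumor_keywords: tuple[str, ...] = ("lymphoma", "leukaemia", "leukemia",
                                       "macroglobulinaemia", "macroglobulinemia",
                                       "neoplasm")
    non_tumor_keywords: tuple[str, ...] = ("nephritis", "nephrotic", "lupus",
                                           "glomerulonephritis")

    def __post_init__(self) -> None:
        if set(self.tumor_keywords) & set(self.non_tumor_keywords):
            raise ValueError("tumor and non-tumor keyword lists must be disjoint")

    def classify(self, text: str) -> str:
        key = fold(text)
        if not key:
            return "unknown"
        if any(word in key for word in self.tumor_keywords):
            return "tumor"
        if any(word in key for word in self.non_tumor_keywords):
            return "non_tumor"
        return "unknown"


def classify_indication(text: str,
                        lexicon: IndicationLexicon = IndicationLexicon()) -> str:
    """Classify one indication text as tumor / non_tumor / unknown."""
    return lexicon.classify(text)


def classify_report(report: NormalizedReport,
                    lexicon: IndicationLexicon = IndicationLexicon()) -> str:
    """Report-level stratum: tumor beats non-tumor beats unknown."""
    labels = {lexicon.classify(ind) for ind in report.indications}
    if "tumor" in labels:
        return "tumor"
    if "non_tumor" in labels:
        return "non_tumor"
    return "unknown"


@dataclass
class StratifiedResult:
    stratum: str
    records: list[SignalRecord]
    top_by_count: list[SignalRecord]
    top_by_ror: list[SignalRecord]


def stratified_signals(reports: Iterable[NormalizedReport],
                       focal_drug: str,
                       stratum: str,
                       lexicon: IndicationLexicon = IndicationLexicon(),
                       suspect_roles: Sequence[str] = DEFAULT_SUSPECT_ROLES,
                       restrict_background: bool = False,
                       top_n: int = 20,
                       priors: BcpnnPriors = BcpnnPriors(),
                       criteria: SignalCriteria = SignalCriteria(),
                       continuity_correction: bool = False,
                       exclude_indications: Sequence[str] | None = None,
                       ) -> StratifiedResult:
    """Run the full signal pipeline with the focal cohort restricted to one
    indication stratum.

    The comparator cells keep the full non-focal corpus by default; set
    ``restrict_background`` to restrict the background to the stratum too.
    Returns the scored records plus the top-N rankings by report count and by
    ROR (the published comparison surface).
    """
    if stratum not in ("tumor", "non_tumor", "unknown"):
        raise ValueError(f"unknown stratum {stratum!r}")
    reports = list(reports)
    focal = [r for r in reports if r.has_drug(focal_drug, suspect_roles)]
    background = [r for r in reports if not r.has_drug(focal_drug, suspect_roles)]

    focal_stratum = [r for r in focal if classify_report(r, lexicon) == stratum]
    if restrict_background:
        background = [r for r in background if classify_report(r, lexicon) == stratum]
    if not focal_stratum:
        logger.warning("stratum %r has no focal reports; empty result", stratum)
        return StratifiedResult(stratum, [], [], [])
    if len(focal_stratum) < 10:
        logger.warning("stratum %r has only %d focal reports; estimates unstable",
                       stratum, len(focal_stratum))

    corpus = focal_stratum + background
    tables = build_tables(corpus, focal_drug, suspect_roles=suspect_roles)
    records = score_tables(tables, priors=priors, criteria=criteria,
                           continuity_correction=continuity_correction)
    if exclude_indications is None:
        exclude_indications = sorted({ind for r in focal for ind in r.indications})
    kwargs = dict(top_n=top_n, exclude_indications=exclude_indications)
    return StratifiedResult(
        stratum=stratum,
        records=records,
        top_by_count=rank_signals(records, by="count", **kwargs),
        top_by_ror=rank_signals(records, by="ror", **kwargs),
    )
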