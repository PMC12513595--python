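"""2×2 contingency tables for drug–event disproportionality.

For each event observed in the corpus, the four cells count *reports* (a report
contributes once per event, however many times the event is listed):

====================  ================  =============
\                     target event      other events
====================  ================  =============
focal drug            a                 b
all other drugs       c                 d
====================  ================  =============

The denominator universe is the full deduplicated corpus handed in, one source
at a time.  Margins are pair-based by default — ``a + b`` is the number of
distinct (focal report, event) pairs, matching the convention in which
``n = a + b + c + d`` sums every distinct report–event pair in the corpus —
with a report-based alternative (``a + b`` = number of focal reports)
available via ``margins="reports"``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .report_io import NormalizedReport
from .vocab import MeddraDictionary

logger = logging.getLogger(__name__)

LEVEL_PT = "PT"
LEVEL_SOC = "SOC"

DEFAULT_SUSPECT_ROLES = ("primary_suspect",)


@dataclass(frozen=True)
class ContingencyTable:
    """Four-cell table for one (drug, event) pair at PT or SOC level."""

    drug: str
    event: str
    level: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n <= 0:
            raise ValueError("table total must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        """Expected count under independence, E = (a+b)(a+c)/n."""
        return (self.a + self.b) * (self.a + self.c) / self.n


def _event_sets(report: NormalizedReport, level: str,
                dictionary: MeddraDictionary | None) -> set[str]:
    if level == LEVEL_PT:
        return set(report.events)
    if dictionary is None:
        raise ValueError("SOC-level tables require a PT->SOC dictionary")
    return {dictionary.map(pt) for pt in report.events}


def build_tables(reports: Iterable[NormalizedReport],
                 focal_drug: str,
                 level: str = LEVEL_PT,
                 dictionary: MeddraDictionary | None = None,
                 suspect_roles: Sequence[str] = DEFAULT_SUSPECT_ROLES,
                 margins: str = "pairs") -> list[ContingencyTable]:
    """Build one table per event observed at least once in the corpus.

    ``reports`` must already be deduplicated; focal membership means the focal
    drug appears on the report in one of ``suspect_roles``.
    """
    if level not in (LEVEL_PT, LEVEL_SOC):
        raise ValueError(f"unknown level {level!r}")
    if margins not in ("pairs", "reports"):
        raise ValueError(f"unknown margins convention {margins!r}")

    focal_counts: Counter[str] = Counter()
    other_counts: Counter[str] = Counter()
    n_focal_reports = 0
    n_other_reports = 0
    focal_pairs = 0
    other_pairs = 0
    for report in reports:
        events = _event_sets(report, level, dictionary)
        if report.has_drug(focal_drug, suspect_roles):
            n_focal_reports += 1
            focal_pairs += len(events)
            focal_counts.update(events)
        else:
            n_other_reports += 1
            other_pairs += len(events)
            other_counts.update(events)

    if n_focal_reports == 0:
        logger.warning("no reports name %r in roles %s; no tables built",
                       focal_drug, list(suspect_roles))
        return []

    if margins == "pairs":
        focal_margin, other_margin = focal_pairs, other_pairs
    else:
        focal_margin, other_margin = n_focal_reports, n_other_reports

    tables = []
    for event in sorted(set(focal_counts) | set(other_counts)):
        a = focal_counts.get(event, 0)
        c = other_counts.get(event, 0)
        tables.append(ContingencyTable(drug=focal_drug, event=event, level=level,
                                       a=a, b=focal_margin - a,
                                       c=c, d=other_margin - c))
    return tables


def aggregate_to_soc(reports: Iterable[NormalizedReport],
                     focal_drug: str,
                     dictionary: MeddraDictionary,
                     suspect_roles: Sequence[str] = DEFAULT_SUSPECT_ROLES,
                     margins: str = "pairs") -> list[ContingencyTable]:
    """SOC-level tables with report-level counting.

    A report mentioning two PTs of one SOC contributes a single count to that
    SOC, so SOC cells are recounted from the reports rather than summed over
    the member PT tables.
    """
    return build_tables(reports, focal_drug, level=LEVEL_SOC,
                        dictionary=dictionary, suspect_roles=suspect_roles,
                        margins=margins)


def tables_to_frame(tables: Sequence[ContingencyTable]):
    """Tidy frame (drug, event, level, a, b, c, d) for export."""
    import pandas as pd

    return pd.DataFrame([{"drug": t.drug, "event": t.event, "level": t.level,
                          "a": t.a, "b": t.b, "c": t.c, "d": t.d}
                         for t in tables])
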