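"""Synthetic spontaneous-report universes with known ground truth.

The generator emulates the statistical structure that disproportionality
analysis assumes: a large background population of reports drawn over a PT
catalogue with baseline reporting probabilities, plus a focal-drug cohort in
which chosen PTs are injected at a known relative reporting rate.  Duplicate
case versions, partially missing therapy/onset dates, demographic mixes and a
Weibull time-to-onset process are layered on so every downstream stage
(ingestion, deduplication, 2×2 tables, the four statistics, profiling) can be
exercised offline against an exact expectation.

Event sampling
    Each report draws ``K ~ max(1, Poisson(mean_pts_per_report))`` PT slots;
    slots are filled by weighted draws from the catalogue and the *distinct*
    set is kept (reports list several reactions; counting downstream is
    report-level).  Keeping the distinct set of with-replacement draws gives
    the exact per-report inclusion probability

        q_j = E_K[1 - (1 - w_j)^K],

    which is what :class:`GroundTruth` uses for its expected 2×2 cell counts —
    an expectation that would be intractable under weighted sampling without
    replacement.

Injection
    Within the focal cohort the injected PTs' weights are multiplied by their
    ``relative_rate`` and the whole weight vector is renormalized, so the
    per-report PT-count distribution is unchanged and only the composition of
    events shifts.

Duplicates are exact copies of sampled cases with case version incremented and
a later receipt date, which makes the "keep the latest version" deduplication
rule the unique correct behaviour.  Identical configuration (including seed)
yields byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .report_io import (
    DrugUse, NormalizedReport, PartialDate,
    SOURCE_FAERS, SOURCE_JADER, age_to_band,
    _ROLE_TO_FAERS, _ROLE_TO_JADER, _SEX_TO_CODE, _REPORTER_TO_FAERS,
)
from .vocab import DrugLexicon, MeddraDictionary


class ConfigurationError(ValueError):
    """The generator configuration violates one of its invariants."""


DEFAULT_BACKGROUND_DRUGS = (
    "rituximab", "ibrutinib", "venetoclax", "bendamustine", "cyclophosphamide",
    "lenalidomide", "acalabrutinib", "chlorambucil", "prednisone", "methotrexate",
    "cisplatin", "paclitaxel", "pembrolizumab", "nivolumab", "trastuzumab",
    "infliximab", "adalimumab", "tocilizumab", "mycophenolate mofetil", "azathioprine",
)

# raw spellings for the focal drug, exercising lexicon standardization in-pipeline
DEFAULT_FOCAL_RAW_NAMES = ("obinutuzumab", "OBINUTUZUMAB", "Gazyva", "GAZYVARO")

DEFAULT_SEX_MIX = {"male": 0.50, "female": 0.37, "unknown": 0.13}
DEFAULT_AGE_MIX = {"<18": 0.005, "18-65": 0.35, ">65": 0.40, "unknown": 0.245}
DEFAULT_COUNTRY_MIX = {"United States": 0.29, "Japan": 0.29, "China": 0.08,
                       "France": 0.06, "Germany": 0.05, "Other": 0.23}
DEFAULT_REPORTER_MIX = {"health_professional": 0.94, "non_health_professional": 0.05,
                        "unknown": 0.01}
DEFAULT_OUTCOME_MIX = {"HO": 0.25, "DE": 0.10, "LT": 0.03, "DS": 0.01,
                       "OT": 0.25, "": 0.36}
DEFAULT_JADER_OUTCOME_MIX = {"Healed": 0.52, "Not healed": 0.07, "Death": 0.08,
                             "Unknown": 0.33}
DEFAULT_INDICATION_MIX = (
    ("Follicular lymphoma", 0.30),
    ("Chronic lymphocytic leukaemia", 0.27),
    ("B-cell lymphoma", 0.07),
    ("Diffuse large B-cell lymphoma", 0.045),
    ("Non-Hodgkin's lymphoma", 0.02),
    ("Mantle cell lymphoma", 0.013),
    ("Marginal zone lymphoma", 0.004),
    ("Waldenstrom's macroglobulinaemia", 0.004),
    ("Glomerulonephritis membranous", 0.006),
    ("Lupus nephritis", 0.007),
    ("Nephrotic syndrome", 0.004),
    ("Systemic lupus erythematosus", 0.003),
    ("", 0.254),  # unknown indication
)


@dataclass(frozen=True)
class SignalSpec:
    """One injected drug–event association: the PT's baseline reporting
    probability is multiplied by ``relative_rate`` within the focal cohort."""

    pt_name: str
    relative_rate: float


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic reporting universe."""

    n_background_reports: int
    n_drug_reports: int
    pt_catalog: tuple[tuple[str, str, float], ...]
    signals: tuple[SignalSpec, ...] = ()
    focal_drug: str = "obinutuzumab"
    source: str = SOURCE_FAERS
    mean_pts_per_report: float = 3.0
    duplicate_fraction: float = 0.0
    missing_date_fraction: float = 0.0
    sex_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_MIX))
    age_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_MIX))
    country_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COUNTRY_MIX))
    reporter_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REPORTER_MIX))
    outcome_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OUTCOME_MIX))
    indication_mix: tuple[tuple[str, float], ...] = DEFAULT_INDICATION_MIX
    tto_shape: float = 1.2
    tto_scale: float = 20.0
    year_range: tuple[int, int] = (2013, 2025)
    background_drugs: tuple[str, ...] = DEFAULT_BACKGROUND_DRUGS
    focal_raw_names: tuple[str, ...] = DEFAULT_FOCAL_RAW_NAMES
    case_id_offset: int = 0
    seed: int = 0

    def validate(self) -> None:
        if not self.pt_catalog:
            raise ConfigurationError("PT catalogue is empty")
        if self.n_background_reports < 0 or self.n_drug_reports < 0:
            raise ConfigurationError("report counts must be non-negative")
        if not 0 <= self.duplicate_fraction < 1:
            raise ConfigurationError("duplicate_fraction must be in [0, 1)")
        if not 0 <= self.missing_date_fraction <= 1:
            raise ConfigurationError("missing_date_fraction must be in [0, 1]")
        if self.mean_pts_per_report <= 0 or self.tto_shape <= 0 or self.tto_scale <= 0:
            raise ConfigurationError("mean_pts_per_report, tto_shape, tto_scale must be positive")
        catalog_pts = {pt for pt, _, _ in self.pt_catalog}
        baselines = {pt: p for pt, _, p in self.pt_catalog}
        for pt, _, p in self.pt_catalog:
            if not 0 < p < 1:
                raise ConfigurationError(f"baseline probability for {pt!r} must be in (0, 1)")
        for spec in self.signals:
            if spec.pt_name not in catalog_pts:
                raise ConfigurationError(f"signal PT {spec.pt_name!r} not in catalogue")
            if spec.relative_rate <= 0:
                raise ConfigurationError(f"relative_rate for {spec.pt_name!r} must be positive")
            if spec.relative_rate * baselines[spec.pt_name] > 1:
                raise ConfigurationError(
                    f"relative_rate for {spec.pt_name!r} pushes probability above 1")
        for name, mix in (("sex_mix", self.sex_mix), ("age_mix", self.age_mix),
                          ("country_mix", self.country_mix),
                          ("reporter_mix", self.reporter_mix),
                          ("outcome_mix", self.outcome_mix),
                          ("indication_mix", dict(self.indication_mix))):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1 (got {total!r})")


@dataclass
class GroundTruth:
    """Exact expectations implied by a :class:`GeneratorConfig`.

    ``expected_a[pt]`` / ``expected_c[pt]`` are the expected number of focal /
    background reports mentioning the PT (report-level counting), with
    binomial variances ``var_a`` / ``var_c``.  ``signalled_pts`` lists PTs
    whose injected relative rate exceeds 1.
    """

    pts: list[str]
    expected_a: dict[str, float]
    expected_c: dict[str, float]
    var_a: dict[str, float]
    var_c: dict[str, float]
    expected_focal_pairs: float
    expected_background_pairs: float
    signalled_pts: list[str]
    n_unique_cases: int
    n_duplicates: int

    def expected_table(self, pt: str) -> tuple[float, float, float, float]:
        a = self.expected_a[pt]
        c = self.expected_c[pt]
        return (a, self.expected_focal_pairs - a, c, self.expected_background_pairs - c)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def default_pt_catalog(n_pts: int = 100,
                       baseline: float | None = None) -> tuple[tuple[str, str, float], ...]:
    """A PT catalogue drawn from the bundled dictionary, uniform baselines.

    With the defaults this yields 100 PTs at baseline probability 0.01 each.
    """
    dictionary = MeddraDictionary.default()
    entries = list(dictionary.pt_to_soc.values())
    if n_pts > len(entries):
        raise ConfigurationError(f"catalogue supports at most {len(entries)} PTs")
    p = baseline if baseline is not None else 1.0 / n_pts
    return tuple((pt, soc, p) for pt, soc in entries[:n_pts])


def demo_config(seed: int = 0, source: str = SOURCE_FAERS) -> GeneratorConfig:
    """A small, fully-featured demonstration universe (runs in seconds)."""
    outcome_mix = DEFAULT_JADER_OUTCOME_MIX if source == SOURCE_JADER else DEFAULT_OUTCOME_MIX
    return GeneratorConfig(
        n_background_reports=8000,
        n_drug_reports=600,
        pt_catalog=default_pt_catalog(100),
        signals=(
            SignalSpec("Infusion related reaction", 25.0),
            SignalSpec("Tumour lysis syndrome", 40.0),
            SignalSpec("Myelosuppression", 20.0),
            SignalSpec("Neutropenia", 8.0),
            SignalSpec("Cytomegalovirus infection", 10.0),
        ),
        source=source,
        duplicate_fraction=0.03,
        missing_date_fraction=0.3,
        outcome_mix=dict(outcome_mix),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Report synthesis
# ---------------------------------------------------------------------------

_AGE_RANGES = {"<18": (1, 18), "18-65": (18, 66), ">65": (66, 91)}


def _truncated_poisson_pmf(lam: float, kmax: int) -> np.ndarray:
    """pmf of K = max(1, Poisson(lam)) on 1..kmax (tail mass folded into kmax)."""
    ks = np.arange(0, kmax + 1)
    log_pmf = ks * math.log(lam) - lam - np.array([math.lgamma(k + 1) for k in ks])
    pmf = np.exp(log_pmf)
    out = pmf[1:].copy()
    out[0] += pmf[0]              # K = max(1, .): zero folds into one
    out[-1] += max(0.0, 1.0 - pmf.sum())
    return out


def _inclusion_probability(weights: np.ndarray, lam: float, n_catalog: int) -> np.ndarray:
    """Exact per-report probability that each PT appears at least once."""
    kmax = max(20, int(math.ceil(lam + 10 * math.sqrt(lam))))
    kmax = min(kmax, max(n_catalog * 4, 20))
    pk = _truncated_poisson_pmf(lam, kmax)
    ks = np.arange(1, kmax + 1)
    # q_j = sum_k P(K=k) (1 - (1-w_j)^k)
    miss = (1.0 - weights)[:, None] ** ks[None, :]
    return np.asarray(1.0 - miss @ pk)


def _sample_events(rng: np.random.Generator, n_reports: int,
                   weights: np.ndarray, lam: float) -> list[np.ndarray]:
    if n_reports == 0:
        return []
    k = np.maximum(rng.poisson(lam, size=n_reports), 1)
    draws = rng.choice(len(weights), size=int(k.sum()), p=weights)
    out: list[np.ndarray] = []
    pos = 0
    for ki in k:
        out.append(np.unique(draws[pos:pos + ki]))
        pos += ki
    return out


def _sample_mix(rng: np.random.Generator, mix: dict[str, float], n: int) -> np.ndarray:
    keys = np.array(list(mix.keys()), dtype=object)
    probs = np.array(list(mix.values()), dtype=float)
    return rng.choice(keys, size=n, p=probs / probs.sum())


def generate_reports(config: GeneratorConfig,
                     lexicon: DrugLexicon | None = None
                     ) -> tuple[list[NormalizedReport], GroundTruth]:
    """Generate a synthetic reporting universe and its exact ground truth.

    Returns the emitted reports (unique cases followed by injected duplicate
    versions) and the :class:`GroundTruth` expectations implied by the
    configuration.
    """
    config.validate()
    lexicon = lexicon if lexicon is not None else DrugLexicon.default()
    rng = np.random.default_rng(config.seed)
    jader = config.source == SOURCE_JADER

    pts = [pt for pt, _, _ in config.pt_catalog]
    baselines = np.array([p for _, _, p in config.pt_catalog], dtype=float)
    base_w = baselines / baselines.sum()
    rr = np.ones(len(pts))
    for spec in config.signals:
        rr[pts.index(spec.pt_name)] = spec.relative_rate
    focal_w = base_w * rr
    focal_w = focal_w / focal_w.sum()

    n_bg, n_drug = config.n_background_reports, config.n_drug_reports
    n_total = n_bg + n_drug
    lam = config.mean_pts_per_report

    bg_events = _sample_events(rng, n_bg, base_w, lam)
    focal_events = _sample_events(rng, n_drug, focal_w, lam)
    event_sets = bg_events + focal_events

    sexes = _sample_mix(rng, config.sex_mix, n_total)
    age_groups = _sample_mix(rng, config.age_mix, n_total)
    ages: list[float | None] = []
    for grp in age_groups:
        if grp == "unknown":
            ages.append(None)
        else:
            lo, hi = _AGE_RANGES[grp]
            value = float(rng.integers(lo, hi))
            if jader:
                value = float((int(value) // 10) * 10 + 5)  # decade-band midpoint
            ages.append(value)
    countries = _sample_mix(rng, config.country_mix, n_total)
    reporters = _sample_mix(rng, config.reporter_mix, n_total)
    outcomes = _sample_mix(rng, config.outcome_mix, n_total)
    ind_texts = [t for t, _ in config.indication_mix]
    ind_probs = np.array([p for _, p in config.indication_mix])
    indications = rng.choice(np.array(ind_texts, dtype=object), size=n_total,
                             p=ind_probs / ind_probs.sum())

    y0, y1 = config.year_range
    first_day = date(y0, 1, 1)
    span = (date(y1, 12, 31) - first_day).days + 1
    receipt_offsets = rng.integers(0, span, size=n_total)
    tto_days = np.rint(rng.weibull(config.tto_shape, size=n_total) * config.tto_scale).astype(int)
    report_delays = rng.integers(0, 91, size=n_total)
    missing_mask = rng.random(n_total) < config.missing_date_fraction
    missing_which = rng.integers(0, 2, size=n_total)  # 0: drop start, 1: drop event

    n_focal_drugs = rng.integers(0, 3, size=n_total)  # concomitants per report
    focal_raw_idx = rng.integers(0, len(config.focal_raw_names), size=n_drug)
    pool = np.array(config.background_drugs, dtype=object)

    reports: list[NormalizedReport] = []
    for i in range(n_total):
        is_focal = i >= n_bg
        cid = str(10_000_000 + config.case_id_offset + i)
        version = 1
        report_id = f"{cid}-{version}" if jader else f"{cid}{version}"

        receipt = first_day + timedelta(days=int(receipt_offsets[i]))
        event_d = receipt - timedelta(days=int(report_delays[i]))
        start_d = event_d - timedelta(days=int(tto_days[i]))
        start_pd: PartialDate | None = PartialDate.from_date(start_d)
        event_pd: PartialDate | None = PartialDate.from_date(event_d)
        if missing_mask[i]:
            if missing_which[i] == 0:
                start_pd = None
            else:
                event_pd = None

        drugs: list[DrugUse] = []
        if is_focal:
            raw = config.focal_raw_names[focal_raw_idx[i - n_bg]]
            canonical, _ = lexicon.normalize(raw)
            drugs.append(DrugUse(raw, canonical, "primary_suspect"))
        else:
            raw = str(rng.choice(pool))
            canonical, _ = lexicon.normalize(raw)
            drugs.append(DrugUse(raw, canonical, "primary_suspect"))
        for _ in range(int(n_focal_drugs[i])):
            raw = str(rng.choice(pool))
            canonical, _ = lexicon.normalize(raw)
            if any(d.name_canonical == canonical for d in drugs):
                continue
            drugs.append(DrugUse(raw, canonical, "concomitant"))

        outcome = str(outcomes[i])
        indication = str(indications[i])
        reports.append(NormalizedReport(
            report_id=report_id,
            case_id=cid,
            case_version=version,
            source=config.source,
            receipt_date=PartialDate.from_date(receipt),
            sex=str(sexes[i]),
            age_years=ages[i],
            country="Japan" if jader else str(countries[i]),
            reporter_type=str(reporters[i]),
            outcomes=(outcome,) if outcome else (),
            drugs=tuple(drugs),
            events=tuple(pts[j] for j in event_sets[i]),
            indications=(indication,) if indication else (),
            therapy_start_date=start_pd,
            event_onset_date=event_pd,
        ))

    n_dup = int(round(config.duplicate_fraction * n_total))
    if n_dup:
        dup_idx = np.sort(rng.choice(n_total, size=n_dup, replace=False))
        dup_delays = rng.integers(7, 61, size=n_dup)
        for j, idx in enumerate(dup_idx):
            original = reports[int(idx)]
            new_receipt = PartialDate.from_date(
                original.receipt_date.to_date() + timedelta(days=int(dup_delays[j])))
            version = original.case_version + 1
            rid = (f"{original.case_id}-{version}" if jader
                   else f"{original.case_id}{version}")
            reports.append(replace(original, case_version=version,
                                   receipt_date=new_receipt, report_id=rid))

    q_focal = _inclusion_probability(focal_w, lam, len(pts))
    q_bg = _inclusion_probability(base_w, lam, len(pts))
    truth = GroundTruth(
        pts=list(pts),
        expected_a={pt: float(n_drug * q) for pt, q in zip(pts, q_focal)},
        expected_c={pt: float(n_bg * q) for pt, q in zip(pts, q_bg)},
        var_a={pt: float(n_drug * q * (1 - q)) for pt, q in zip(pts, q_focal)},
        var_c={pt: float(n_bg * q * (1 - q)) for pt, q in zip(pts, q_bg)},
        expected_focal_pairs=float(n_drug * q_focal.sum()),
        expected_background_pairs=float(n_bg * q_bg.sum()),
        signalled_pts=[s.pt_name for s in config.signals if s.relative_rate > 1],
        n_unique_cases=n_total,
        n_duplicates=n_dup,
    )
    return reports, truth


# ---------------------------------------------------------------------------
# Dialect writers
# ---------------------------------------------------------------------------

def _fmt_date(d: PartialDate | None) -> str:
    return d.compact() if d is not None else ""


def _fmt_age(age: float | None) -> tuple[str, str]:
    if age is None:
        return "", ""
    if float(age).is_integer():
        return str(int(age)), "YR"
    return repr(float(age)), "YR"


def write_faers_tables(reports: Sequence[NormalizedReport],
                       directory: str | Path) -> dict[str, Path]:
    """Write reports as ``$``-delimited FAERS-style DEMO/DRUG/REAC/INDI/THER/OUTC.

    Round-trips exactly through :func:`pvsignals.report_io.read_faers_quarter`.
    """
    if not reports:
        raise ValueError("no reports to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    demo, drug, reac, indi, ther, outc = [], [], [], [], [], []
    for r in reports:
        age_text, age_cod = _fmt_age(r.age_years)
        demo.append({"PRIMARYID": r.report_id, "CASEID": r.case_id,
                     "CASEVERSION": r.case_version, "FDA_DT": _fmt_date(r.receipt_date),
                     "EVENT_DT": _fmt_date(r.event_onset_date),
                     "SEX": _SEX_TO_CODE[r.sex], "AGE": age_text, "AGE_COD": age_cod,
                     "OCCR_COUNTRY": "" if r.country == "unknown" else r.country,
                     "OCCP_COD": _REPORTER_TO_FAERS[r.reporter_type]})
        for seq, d in enumerate(r.drugs, start=1):
            drug.append({"PRIMARYID": r.report_id, "CASEID": r.case_id, "DRUG_SEQ": seq,
                         "ROLE_COD": _ROLE_TO_FAERS.get(d.role, ""), "DRUGNAME": d.name_raw})
        for pt in r.events:
            reac.append({"PRIMARYID": r.report_id, "CASEID": r.case_id, "PT": pt})
        for seq, ind in enumerate(r.indications, start=1):
            indi.append({"PRIMARYID": r.report_id, "CASEID": r.case_id,
                         "INDI_DRUG_SEQ": seq, "INDI_PT": ind})
        if r.therapy_start_date is not None:
            ther.append({"PRIMARYID": r.report_id, "CASEID": r.case_id,
                         "DSG_DRUG_SEQ": 1, "START_DT": _fmt_date(r.therapy_start_date)})
        for code in r.outcomes:
            outc.append({"PRIMARYID": r.report_id, "CASEID": r.case_id, "OUTC_COD": code})

    columns = {
        "DEMO": (demo, ["PRIMARYID", "CASEID", "CASEVERSION", "FDA_DT", "EVENT_DT",
                        "SEX", "AGE", "AGE_COD", "OCCR_COUNTRY", "OCCP_COD"]),
        "DRUG": (drug, ["PRIMARYID", "CASEID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"]),
        "REAC": (reac, ["PRIMARYID", "CASEID", "PT"]),
        "INDI": (indi, ["PRIMARYID", "CASEID", "INDI_DRUG_SEQ", "INDI_PT"]),
        "THER": (ther, ["PRIMARYID", "CASEID", "DSG_DRUG_SEQ", "START_DT"]),
        "OUTC": (outc, ["PRIMARYID", "CASEID", "OUTC_COD"]),
    }
    paths: dict[str, Path] = {}
    for name, (rows, cols) in columns.items():
        path = directory / f"{name}.txt"
        frame = pd.DataFrame(rows, columns=cols)
        frame.to_csv(path, sep="$", index=False, lineterminator="\n")
        paths[name] = path
    return paths


def write_jader_tables(reports: Sequence[NormalizedReport],
                       directory: str | Path) -> dict[str, Path]:
    """Write reports as comma-delimited JADER-style demo/drug/reac tables.

    Round-trips exactly through :func:`pvsignals.report_io.read_jader` provided
    ages sit on decade-band midpoints (which JADER-mode generation guarantees).
    """
    if not reports:
        raise ValueError("no reports to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    demo, drug, reac = [], [], []
    for r in reports:
        demo.append({"case_id": r.case_id, "sex": _SEX_TO_CODE[r.sex],
                     "age_band": age_to_band(r.age_years),
                     "outcome": ";".join(r.outcomes),
                     "reporter": "" if r.reporter_type == "unknown" else r.reporter_type,
                     "receipt_date": _fmt_date(r.receipt_date)})
        for seq, d in enumerate(r.drugs, start=1):
            drug.append({"case_id": r.case_id, "drug_seq": seq,
                         "involvement": _ROLE_TO_JADER.get(d.role, ""),
                         "drug_name": d.name_raw,
                         "indication": ";".join(r.indications) if seq == 1 else "",
                         "start_date": _fmt_date(r.therapy_start_date) if seq == 1 else ""})
        for seq, pt in enumerate(r.events, start=1):
            reac.append({"case_id": r.case_id, "reac_seq": seq, "pt": pt,
                         "onset_date": _fmt_date(r.event_onset_date) if seq == 1 else ""})

    columns = {
        "demo": (demo, ["case_id", "sex", "age_band", "outcome", "reporter", "receipt_date"]),
        "drug": (drug, ["case_id", "drug_seq", "involvement", "drug_name",
                        "indication", "start_date"]),
        "reac": (reac, ["case_id", "reac_seq", "pt", "onset_date"]),
    }
    paths: dict[str, Path] = {}
    for name, (rows, cols) in columns.items():
        path = directory / f"{name}.csv"
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Write the ground-truth sidecar as JSON next to a generated dataset."""
    path = Path(path)
    path.write_text(truth.to_json(), encoding="utf-8")
    return path
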