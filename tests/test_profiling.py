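"""Descriptive surfaces: demographics, annual/SOC distributions, onset delays
and indication stratification."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import pvsignals as pv
from pvsignals.profiling import TOTAL_COLUMN, round_half_up

from conftest import make_report


# ---------------------------------------------------------------------------
# Demographics
# ---------------------------------------------------------------------------

def test_rounding_is_half_up():
    assert round_half_up(49.845) == 49.85
    assert round_half_up(1.345) == 1.35
    assert round_half_up(36.8490) == 36.85


def test_demographic_counts_and_ratio():
    reports = ([make_report(f"m{i}", sex="male") for i in range(27)]
               + [make_report(f"f{i}", sex="female") for i in range(20)]
               + [make_report("u0", sex="unknown")])
    summary = pv.demographic_summary(reports)
    sex_rows = summary.table[summary.table["variable"] == "sex"]
    male = sex_rows[sex_rows["category"] == "male"].iloc[0]
    assert male[f"{TOTAL_COLUMN}_n"] == 27
    assert male[f"{TOTAL_COLUMN}_pct"] == round_half_up(100 * 27 / 48)
    assert summary.male_female_ratio[TOTAL_COLUMN] == 1.35  # 27/20
    summary.audit()  # self-consistency of every printed percentage


def test_ratio_undefined_without_female_reports():
    reports = [make_report(f"r{i}", sex="unknown") for i in range(5)]
    summary = pv.demographic_summary(reports)
    assert summary.male_female_ratio[TOTAL_COLUMN] is None


def test_per_source_columns_sum_to_source_totals(deduped_universe):
    reports, _ = deduped_universe
    summary = pv.demographic_summary(reports)
    sex_rows = summary.table[summary.table["variable"] == "sex"]
    for column, n in summary.n_reports.items():
        assert sex_rows[f"{column}_n"].sum() == n


# ---------------------------------------------------------------------------
# Annual distribution
# ---------------------------------------------------------------------------

def test_annual_counts():
    reports = [make_report(f"r{i}", receipt="20190501") for i in range(3)]
    reports.append(make_report("r4", receipt="20200501"))
    reports.append(make_report("r5", receipt=None))
    annual = pv.annual_distribution(reports)
    assert annual[TOTAL_COLUMN] == {2019: 3, 2020: 1, "unknown": 1}
    known = sum(v for k, v in annual[TOTAL_COLUMN].items() if k != "unknown")
    assert known == len(reports) - 1


def test_annual_distribution_roughly_uniform(small_config):
    """Receipt years are uniform over the configured range by construction.

    Duplicate versions carry a pushed-back receipt date and can spill past the
    range end, so the uniformity check runs on a duplicate-free universe.
    """
    reports, _ = pv.generate_reports(replace(small_config, duplicate_fraction=0.0))
    annual = pv.annual_distribution(reports)[TOTAL_COLUMN]
    years = sorted(k for k in annual if k != "unknown")
    assert years == list(range(2013, 2026))
    counts = np.array([annual[y] for y in years])
    # expectation proportional to days per calendar year
    days = np.array([366 if y % 4 == 0 else 365 for y in years], dtype=float)
    expected = counts.sum() * days / days.sum()
    _, p_value = stats.chisquare(counts, expected)
    assert p_value > 0.001


# ---------------------------------------------------------------------------
# SOC distribution
# ---------------------------------------------------------------------------

def test_single_soc_fixture_is_total(dictionary):
    reports = [make_report(f"r{i}", events=("Pyrexia",)) for i in range(4)]
    frame = pv.soc_distribution(reports, dictionary)
    assert len(frame) == 1
    assert frame.loc[0, "soc"] == "General disorders and administration site conditions"
    assert frame.loc[0, "proportion"] == pytest.approx(1.0)


def test_soc_distribution_matches_recount(deduped_universe, dictionary):
    reports, _ = deduped_universe
    focal = pv.filter_suspect(reports, "obinutuzumab")
    frame = pv.soc_distribution(focal, dictionary)
    recount = {}
    for r in focal:
        for soc in {dictionary.map(pt) for pt in r.events}:
            recount[soc] = recount.get(soc, 0) + 1
    assert dict(zip(frame["soc"], frame["count"])) == recount
    assert frame["proportion"].sum() == pytest.approx(1.0, abs=1e-9)
    assert list(frame["count"]) == sorted(frame["count"], reverse=True)


def test_unmapped_pts_accumulate(dictionary):
    reports = [make_report("r1", events=("No such term",))]
    frame = pv.soc_distribution(reports, dictionary)
    assert frame.loc[0, "soc"] == "Unmapped"


# ---------------------------------------------------------------------------
# Time to onset
# ---------------------------------------------------------------------------

def test_onset_day_arithmetic():
    report = make_report(start="20200101", onset="20200115")
    summary = pv.time_to_onset([report])
    assert summary.n_evaluable == 1
    assert summary.median_days == 14.0
    assert summary.bin_counts["8-30"] == 1


def test_onset_exclusions():
    reports = [
        make_report("ok", start="20200101", onset="20200115"),
        make_report("neg", start="20200201", onset="20200101"),   # onset before start
        make_report("partial", start="202001", onset="20200115"), # month precision
        make_report("missing", start=None, onset="20200115"),
    ]
    summary = pv.time_to_onset(reports)
    assert summary.n_evaluable == 1
    assert summary.n_excluded == 3
    assert summary.n_reports == 4


def test_onset_bins_and_cumulative():
    from datetime import date, timedelta

    delays = [0, 7, 8, 30, 31, 200]
    reports = [make_report(f"r{i}", start="20200101",
                           onset=(date(2020, 1, 1) + timedelta(days=d)).strftime("%Y%m%d"))
               for i, d in enumerate(delays)]
    summary = pv.time_to_onset(reports)
    assert summary.bin_counts == {"0-7": 2, "8-30": 2, "31-60": 1, "61-90": 0,
                                  "91-180": 0, ">180": 1}
    assert summary.cumulative[">180"] == pytest.approx(1.0)
    assert summary.cumulative["8-30"] == pytest.approx(4 / 6)


def test_onset_median_matches_weibull_oracle():
    """Sample median ≈ scale·(ln 2)^(1/shape) for the generating Weibull."""
    config = pv.GeneratorConfig(
        n_background_reports=0, n_drug_reports=2000,
        pt_catalog=pv.default_pt_catalog(50),
        tto_shape=1.2, tto_scale=20.0, missing_date_fraction=0.0, seed=17)
    reports, _ = pv.generate_reports(config)
    summary = pv.time_to_onset(reports)
    assert summary.n_evaluable == 2000
    median_ref = 20.0 * math.log(2) ** (1 / 1.2)
    density = (1.2 / 20.0) * (median_ref / 20.0) ** 0.2 * 0.5
    se = 1 / (2 * density * math.sqrt(2000))
    assert abs(summary.median_days - median_ref) < 3 * se + 0.5  # +0.5: day rounding


# ---------------------------------------------------------------------------
# Indication stratification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("text, label", [
    ("Follicular lymphoma", "tumor"),
    ("Chronic lymphocytic leukaemia", "tumor"),
    ("Lupus nephritis", "non_tumor"),
    ("Glomerulonephritis membranous", "non_tumor"),
    ("", "unknown"),
    ("Hypertension", "unknown"),
])
def test_classify_indication(text, label):
    assert pv.classify_indication(text) == label


def test_indication_keyword_lists_must_be_disjoint():
    with pytest.raises(ValueError):
        pv.IndicationLexicon(tumor_keywords=("lupus",),
                             non_tumor_keywords=("lupus",))


def _stratified_universe():
    """Focal cohorts with different indications; a PT injected only in the
    tumor-indication cohort."""
    catalog = pv.default_pt_catalog(60)
    tumor_cfg = pv.GeneratorConfig(
        n_background_reports=20000, n_drug_reports=500, pt_catalog=catalog,
        signals=(pv.SignalSpec("Tumour lysis syndrome", 20.0),),
        indication_mix=(("Follicular lymphoma", 1.0),), seed=31)
    non_tumor_cfg = pv.GeneratorConfig(
        n_background_reports=0, n_drug_reports=500, pt_catalog=catalog,
        indication_mix=(("Lupus nephritis", 1.0),),
        case_id_offset=100_000, seed=32)
    tumor_reports, _ = pv.generate_reports(tumor_cfg)
    non_tumor_reports, _ = pv.generate_reports(non_tumor_cfg)
    return tumor_reports + non_tumor_reports


def test_stratified_signal_only_in_injected_stratum():
    reports = _stratified_universe()
    tumor = pv.stratified_signals(reports, "obinutuzumab", "tumor",
                                  exclude_indications=[])
    non_tumor = pv.stratified_signals(reports, "obinutuzumab", "non_tumor",
                                      exclude_indications=[])
    tumor_flagged = {r.event for r in tumor.records if r.flagged}
    non_tumor_flagged = {r.event for r in non_tumor.records if r.flagged}
    assert "Tumour lysis syndrome" in tumor_flagged
    assert "Tumour lysis syndrome" not in non_tumor_flagged
    assert len(tumor.top_by_count) <= 20 and len(tumor.top_by_ror) <= 20


def test_strata_partition_the_focal_a_cells():
    reports = _stratified_universe()
    overall = {t.event: t.a for t in pv.build_tables(reports, "obinutuzumab")}
    per_stratum = []
    for stratum in ("tumor", "non_tumor", "unknown"):
        result = pv.stratified_signals(reports, "obinutuzumab", stratum,
                                       exclude_indications=[])
        per_stratum.append({r.event: r.table.a for r in result.records})
    for event, a in overall.items():
        assert sum(cells.get(event, 0) for cells in per_stratum) == a


def test_empty_stratum_warns_and_returns_empty(caplog):
    reports = [make_report("r1", indications=("Follicular lymphoma",))]
    with caplog.at_level("WARNING"):
        result = pv.stratified_signals(reports, "obinutuzumab", "non_tumor")
    assert result.records == []
    assert "no focal reports" in caplog.text
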