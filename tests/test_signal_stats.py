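"""The four disproportionality statistics against independent direct-formula
oracles, shrinkage properties of the gamma-Poisson shrinker, and the
conjunctive signal rule."""

import math

import numpy as np
import pytest
from scipy import special, stats

import pvsignals as pv
from pvsignals.signal_stats import DEFAULT_MGPS_START


def table(a, b, c, d):
    return pv.ContingencyTable("drug", "event", "PT", a, b, c, d)


# ---------------------------------------------------------------------------
# Independent direct-formula oracles (plain math, no package code)
# ---------------------------------------------------------------------------

def oracle_ror(a, b, c, d):
    log_ror = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (math.exp(log_ror), math.exp(log_ror - 1.96 * se),
            math.exp(log_ror + 1.96 * se))


def oracle_prr_chi2(a, b, c, d):
    n = a + b + c + d
    prr = (a / (a + b)) / (c / (c + d))
    diff = max(0.0, abs(a * d - b * c) - n / 2)
    chi2 = n * diff ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return prr, chi2


def oracle_ic(a, b, c, d, alpha=2.0, beta=2.0, alpha1=1.0, beta1=1.0, gamma11=1.0):
    n = a + b + c + d
    row, col = a + b, a + c
    gamma = gamma11 * (n + alpha) * (n + beta) / ((row + alpha1) * (col + beta1))
    ic = math.log2((a + gamma11) * (n + alpha) * (n + beta)
                   / ((n + gamma) * (row + alpha1) * (col + beta1)))
    var = ((n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
           + (n - row + alpha - alpha1) / ((row + alpha1) * (1 + n + alpha))
           + (n - col + beta - beta1) / ((col + beta1) * (1 + n + beta))) / math.log(2) ** 2
    return ic, math.sqrt(var)


# ---------------------------------------------------------------------------
# ROR / PRR / chi-squared
# ---------------------------------------------------------------------------

def test_symmetric_table_is_null():
    t = table(5, 5, 5, 5)
    assert pv.compute_ror(t).ror == pytest.approx(1.0)
    assert pv.compute_prr_chi2(t).prr == pytest.approx(1.0)
    assert pv.compute_ror(t).ci95_low == pytest.approx(math.exp(-1.96 * math.sqrt(0.8)))


def test_textbook_table_values():
    t = table(10, 90, 100, 9900)
    assert pv.compute_ror(t).ror == pytest.approx(11.0)
    result = pv.compute_prr_chi2(t)
    assert result.prr == pytest.approx(10.0)
    assert result.chi2 == pytest.approx(oracle_prr_chi2(10, 90, 100, 9900)[1], rel=1e-12)
    assert result.chi2 == pytest.approx(66.33, abs=0.005)


def test_zero_cell_not_evaluable_by_default():
    t = table(3, 0, 10, 100)
    assert not pv.compute_ror(t).evaluable
    assert not pv.compute_prr_chi2(t).evaluable
    assert math.isnan(pv.compute_ror(t).ror)


def test_continuity_correction_makes_zero_cells_evaluable():
    t = table(3, 0, 10, 100)
    corrected = pv.compute_ror(t, continuity_correction=True)
    assert corrected.evaluable
    assert corrected.ror == pytest.approx(oracle_ror(3.5, 0.5, 10.5, 100.5)[0])


def test_statistics_match_oracles_on_random_tables():
    """ROR/CI, PRR, Yates chi2 and IC agree with direct formulas to 1e-9."""
    rng = np.random.default_rng(2024)
    cells = rng.integers(1, 10_000, size=(1000, 4))
    for a, b, c, d in cells:
        t = table(int(a), int(b), int(c), int(d))
        ror_ref, lo_ref, hi_ref = oracle_ror(a, b, c, d)
        ror = pv.compute_ror(t)
        assert ror.ror == pytest.approx(ror_ref, rel=1e-9)
        assert ror.ci95_low == pytest.approx(lo_ref, rel=1e-9)
        assert ror.ci95_high == pytest.approx(hi_ref, rel=1e-9)
        prr_ref, chi2_ref = oracle_prr_chi2(a, b, c, d)
        prr = pv.compute_prr_chi2(t)
        assert prr.prr == pytest.approx(prr_ref, rel=1e-9)
        assert prr.chi2 == pytest.approx(chi2_ref, rel=1e-9, abs=1e-12)
        ic_ref, sd_ref = oracle_ic(a, b, c, d)
        ic = pv.compute_ic(t)
        assert ic.ic == pytest.approx(ic_ref, rel=1e-9, abs=1e-12)
        assert ic.ic_sd == pytest.approx(sd_ref, rel=1e-9)


# ---------------------------------------------------------------------------
# Information component
# ---------------------------------------------------------------------------

def test_ic_small_table_reference_value():
    result = pv.compute_ic(table(1, 9, 9, 81))
    assert result.ic == pytest.approx(-0.113, abs=5e-4)
    assert result.ic_minus_2sd == result.ic - 2 * result.ic_sd


def test_ic_near_zero_under_exact_independence():
    result = pv.compute_ic(table(100, 9900, 9900, 980100))
    assert abs(result.ic) < 0.05


@pytest.mark.parametrize("seed", [0, 1])
def test_ic_lower_bound_never_exceeds_ic(seed):
    rng = np.random.default_rng(seed)
    for a, b, c, d in rng.integers(0, 500, size=(50, 4)):
        if a + b + c + d == 0:
            continue
        result = pv.compute_ic(table(int(a), int(b), int(c), int(d)))
        assert result.ic_minus_2sd <= result.ic


# ---------------------------------------------------------------------------
# MGPS / EBGM
# ---------------------------------------------------------------------------

def test_ebgm_degenerate_prior_closed_form():
    h = pv.MgpsHyperparams(1.0, 1.0, 2.0, 4.0, 1.0)   # p_mix pinned to 1
    t = table(5, 5, 5, 85)                             # E = (10)(10)/100 = 1
    assert t.expected_a == pytest.approx(1.0)
    result = pv.compute_ebgm(t, h)
    assert result.ebgm == pytest.approx(math.exp(special.digamma(6)) / 2, abs=1e-6)
    assert result.ebgm05 == pytest.approx(stats.gamma.ppf(0.05, 6) / 2, abs=1e-6)


def test_single_component_likelihood_reduces_to_negative_binomial():
    h = pv.MgpsHyperparams(0.7, 0.3, 2.0, 4.0, 1.0)
    a = np.array([0.0, 1.0, 3.0, 10.0])
    E = np.array([0.5, 1.0, 2.0, 8.0])
    ours = pv.mgps_marginal_loglik(h, a, E, zero_truncated=False)
    ref = stats.nbinom.logpmf(a, 0.7, 0.3 / (0.3 + E)).sum()
    assert ours == pytest.approx(float(ref), rel=1e-12)


def test_ebgm_monotone_in_count():
    h = pv.MgpsHyperparams(*DEFAULT_MGPS_START)
    previous = 0.0
    for a in range(0, 40, 2):
        # margins held fixed: row = 100, column = 60, n = 5000 -> E = 1.2
        t = pv.ContingencyTable("d", "e", "PT", a, 100 - a, 60 - a, 4840 + a)
        assert t.expected_a == pytest.approx(1.2)
        value = pv.compute_ebgm(t, h).ebgm
        assert value >= previous - 1e-12
        previous = value


def test_ebgm_shrinks_between_prior_and_observed():
    """EBGM lies between the prior's central values and the observed ratio.

    The prior's geometric mean bounds from below and its arithmetic mean from
    above (the posterior geometric mean sits under the posterior arithmetic
    mean, which is the quantity the classic prior-vs-observed sandwich
    constrains); a small slack absorbs that gap at finite counts.
    """
    rng = np.random.default_rng(7)
    h = pv.MgpsHyperparams(0.8, 0.5, 3.0, 2.0, 0.4)
    for a, b, c, d in rng.integers(1, 2000, size=(100, 4)):
        t = table(int(a), int(b), int(c), int(d))
        observed = t.a / t.expected_a
        result = pv.compute_ebgm(t, h)
        lo = min(h.prior_geometric_mean, observed)
        hi = max(h.prior_mean, observed)
        assert lo * (1 - 1e-3) <= result.ebgm <= hi * (1 + 1e-3)
        assert result.ebgm05 <= result.ebgm


def test_mgps_fit_beats_true_hyperparams():
    rng = np.random.default_rng(42)
    true = pv.MgpsHyperparams(0.5, 0.25, 4.0, 4.0, 0.25)
    n = 1200
    E = rng.uniform(0.5, 20, n)
    from_first = rng.random(n) < true.p_mix
    lam = np.where(from_first,
                   rng.gamma(true.alpha1, 1 / true.beta1, n),
                   rng.gamma(true.alpha2, 1 / true.beta2, n))
    a = rng.poisson(lam * E)
    fitted = pv.fit_mgps(counts=a, expected=E, exclude_zero_counts=False)
    assert fitted.converged
    ll_true = pv.mgps_marginal_loglik(true, a, E, zero_truncated=False)
    assert fitted.loglik >= ll_true - 1e-3


def test_mgps_warns_on_few_pairs(caplog):
    rng = np.random.default_rng(0)
    E = rng.uniform(1, 5, 20)
    a = rng.poisson(E) + 1
    with caplog.at_level("WARNING"):
        pv.fit_mgps(counts=a, expected=E)
    assert "only 20 pairs" in caplog.text


# ---------------------------------------------------------------------------
# Criteria and ranking
# ---------------------------------------------------------------------------

def record(a=10, ror=5.0, ror_lo=2.0, prr=4.0, ic=1.0, ic_sd=0.2, ebgm05=3.0,
           event="Pyrexia", evaluable=True):
    t = pv.ContingencyTable("drug", event, "PT", a, max(100 - a, 0), 50, 5000)
    rec = pv.SignalRecord(
        drug="drug", event=event, level="PT", table=t,
        ror=pv.RorResult(ror, ror_lo, ror * 2, evaluable=evaluable),
        prr=pv.PrrResult(prr, 30.0, evaluable=evaluable),
        ic=pv.IcResult(ic, ic_sd),
        ebgm=pv.EbgmResult(t.expected_a, ebgm05 + 1, ebgm05, evaluable=evaluable),
    )
    from dataclasses import replace
    return replace(rec, flagged=pv.evaluate_criteria(rec))


@pytest.mark.parametrize("kwargs, expected", [
    (dict(), True),
    (dict(a=2), False),                    # below the 3-report floor
    (dict(ebgm05=1.99), False),            # EBGM05 must strictly exceed 2
    (dict(ror_lo=1.0), False),             # CI lower bound must exceed 1
    (dict(prr=2.0), False),
    (dict(ic=-0.1), False),
    (dict(ic=0.3, ic_sd=0.2), False),      # IC-2SD dips below 0
    (dict(evaluable=False), False),        # not-evaluable vetoes
])
def test_conjunctive_signal_criteria(kwargs, expected):
    assert record(**kwargs).flagged is expected


def test_ranking_exclusions_and_tie_breaks():
    records = [
        record(a=10, ror=5.0),
        record(a=3, ror=5.0, event="Chills"),
        record(a=50, ror=40.0, event="Follicular lymphoma"),   # treated indication
        record(a=40, ror=35.0, event="Disease progression"),   # progression term
        record(a=2, ror=100.0, event="Nausea"),                # below count floor
    ]
    ranked = pv.rank_signals(records, by="ror", top_n=30,
                             exclude_indications=["Follicular lymphoma"])
    assert [r.event for r in ranked] == ["Pyrexia", "Chills"]  # count breaks the tie
    assert pv.rank_signals(records, by="ror", top_n=1,
                           exclude_indications=["Follicular lymphoma"])[0].event == "Pyrexia"


def test_ranking_by_count_uses_ror_tiebreak():
    records = [record(a=10, ror=5.0, event="A"),
               record(a=10, ror=9.0, event="B")]
    ranked = pv.rank_signals(records, by="count")
    assert [r.event for r in ranked] == ["B", "A"]


def test_signal_table_column_order():
    frame = pv.signal_table([record()])
    assert list(frame.columns[:5]) == ["drug", "event", "level", "a", "ror"]
    assert frame.loc[0, "flagged"]
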