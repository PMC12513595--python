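"""The four disproportionality statistics and the conjunctive signal rule.

Given a 2×2 report-count table (a, b, c, d; n = a+b+c+d) for a drug–event
pair, this module computes:

* **ROR** — reporting odds ratio ``ad / bc`` with a log-scale Wald 95% CI,
  ``exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))``.
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with the
  (Yates-corrected, by default) chi-squared statistic
  ``n·(|ad−bc|−n/2)² / [(a+b)(c+d)(a+c)(b+d)]``.
* **IC** — the BCPNN information component ``log2 p(x,y)/(p(x)p(y))`` under
  Beta/Dirichlet pseudo-count priors, using the closed-form posterior
  expectation and variance (Bate-style parameterization); the signal bound is
  the lower two-standard-deviation limit IC − 2SD.
* **EBGM** — DuMouchel's empirical-Bayes gamma–Poisson shrinker: counts
  ``a ~ Poisson(λE)`` with ``E = (a+b)(a+c)/n``, a two-component gamma mixture
  prior on λ fitted by maximum marginal likelihood over all pairs
  (:func:`fit_mgps`), posterior geometric mean EBGM and posterior 5th
  percentile EBGM05.

A pair is flagged as a signal when all of the following hold (each threshold
configurable): a ≥ 3, ROR CI lower bound > 1, PRR > 2, IC > 0, IC − 2SD > 0,
EBGM05 > 2.  A statistic rendered not-evaluable by zero cells vetoes the flag
rather than being imputed; an optional Haldane–Anscombe +0.5 continuity
correction makes zero-cell ROR/PRR evaluable instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

from .contingency import ContingencyTable
from .vocab import fold

logger = logging.getLogger(__name__)

Z95 = 1.96  # conventional two-sided 95% normal quantile as printed in the field

DEFAULT_PROGRESSION_TERMS = (
    "disease progression",
    "malignant neoplasm progression",
    "neoplasm progression",
    "disease recurrence",
)


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RorResult:
    ror: float
    ci95_low: float
    ci95_high: float
    evaluable: bool = True


@dataclass(frozen=True)
class PrrResult:
    prr: float
    chi2: float
    evaluable: bool = True


@dataclass(frozen=True)
class BcpnnPriors:
    """Pseudo-count priors of the closed-form BCPNN posterior."""

    alpha: float = 2.0
    beta: float = 2.0
    alpha1: float = 1.0
    beta1: float = 1.0
    gamma11: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.alpha1, self.beta1, self.gamma11) <= 0:
            raise ValueError("all BCPNN pseudo-counts must be positive")


@dataclass(frozen=True)
class IcResult:
    ic: float
    ic_sd: float

    @property
    def ic_minus_2sd(self) -> float:
        return self.ic - 2.0 * self.ic_sd


@dataclass(frozen=True)
class MgpsHyperparams:
    """Two-component gamma mixture prior of the gamma–Poisson shrinker."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p_mix: float
    converged: bool = True
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shapes and rates must be positive")
        if not 0 < self.p_mix <= 1:
            raise ValueError("p_mix must be in (0, 1]")

    @property
    def prior_mean(self) -> float:
        return (self.p_mix * self.alpha1 / self.beta1
                + (1 - self.p_mix) * self.alpha2 / self.beta2)

    @property
    def prior_geometric_mean(self) -> float:
        log_gm = (self.p_mix * (special.digamma(self.alpha1) - math.log(self.beta1))
                  + (1 - self.p_mix) * (special.digamma(self.alpha2) - math.log(self.beta2)))
        return math.exp(log_gm)


DEFAULT_MGPS_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass(frozen=True)
class EbgmResult:
    expected_count_E: float
    ebgm: float
    ebgm05: float
    evaluable: bool = True


@dataclass(frozen=True)
class SignalCriteria:
    """Conjunctive positive-signal rule; every threshold is configurable."""

    min_a: int = 3
    ror_ci_low: float = 1.0
    prr: float = 2.0
    ic: float = 0.0
    ic_minus_2sd: float = 0.0
    ebgm05: float = 2.0


@dataclass(frozen=True)
class SignalRecord:
    drug: str
    event: str
    level: str
    table: ContingencyTable
    ror: RorResult
    prr: PrrResult
    ic: IcResult
    ebgm: EbgmResult
    flagged: bool = False


# ---------------------------------------------------------------------------
# Frequentist statistics
# ---------------------------------------------------------------------------

def compute_ror(t: ContingencyTable, continuity_correction: bool = False) -> RorResult:
    """Reporting odds ratio with log-scale Wald 95% CI.

    Zero cells make the ratio undefined; by default the result is marked
    not-evaluable, with the Haldane–Anscombe +0.5 correction as an opt-in.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0:
        if not continuity_correction:
            return RorResult(math.nan, math.nan, math.nan, evaluable=False)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_ror = math.log(a) + math.log(d) - math.log(b) - math.log(c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RorResult(math.exp(log_ror),
                     math.exp(log_ror - Z95 * se),
                     math.exp(log_ror + Z95 * se))


def compute_prr_chi2(t: ContingencyTable, yates: bool = True,
                     continuity_correction: bool = False) -> PrrResult:
    """Proportional reporting ratio and its chi-squared statistic.

    ``yates`` applies the continuity-corrected chi-squared formula (the
    correction subtracts n/2 from |ad − bc|, floored at zero).
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0:
        if not continuity_correction:
            return PrrResult(math.nan, math.nan, evaluable=False)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    n = a + b + c + d
    prr = (a / (a + b)) / (c / (c + d))
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    chi2 = n * diff ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return PrrResult(prr, chi2)


# ---------------------------------------------------------------------------
# BCPNN information component
# ---------------------------------------------------------------------------

def compute_ic(t: ContingencyTable, priors: BcpnnPriors = BcpnnPriors()) -> IcResult:
    """Closed-form posterior mean and SD of the information component.

    Defined for zero cells by the pseudo-counts; base-2 logarithm throughout.
    """
    a = float(t.a)
    row = float(t.a + t.b)   # focal-drug margin
    col = float(t.a + t.c)   # event margin
    n = float(t.n)
    pr = priors
    gamma = pr.gamma11 * (n + pr.alpha) * (n + pr.beta) / ((row + pr.alpha1) * (col + pr.beta1))
    ic = math.log2((a + pr.gamma11) * (n + pr.alpha) * (n + pr.beta)
                   / ((n + gamma) * (row + pr.alpha1) * (col + pr.beta1)))
    var = ((n - a + gamma - pr.gamma11) / ((a + pr.gamma11) * (1 + n + gamma))
           + (n - row + pr.alpha - pr.alpha1) / ((row + pr.alpha1) * (1 + n + pr.alpha))
           + (n - col + pr.beta - pr.beta1) / ((col + pr.beta1) * (1 + n + pr.beta))
           ) / math.log(2) ** 2
    return IcResult(ic, math.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# Gamma-Poisson shrinker (MGPS / EBGM)
# ---------------------------------------------------------------------------

def _nb_logpmf(a: np.ndarray, shape: float, rate: float, E: np.ndarray) -> np.ndarray:
    # marginal of Poisson(lambda*E) with lambda ~ Gamma(shape, rate);
    # negative binomial with size `shape` and success probability rate/(rate+E)
    log_p = math.log(rate) - np.log(rate + E)
    log_q = np.log(E) - np.log(rate + E)
    return (special.gammaln(shape + a) - special.gammaln(shape)
            - special.gammaln(a + 1.0) + shape * log_p + a * log_q)


def mgps_marginal_loglik(h: MgpsHyperparams, a: np.ndarray, E: np.ndarray,
                         zero_truncated: bool = True) -> float:
    """Log marginal likelihood of counts under the mixture prior.

    With ``zero_truncated`` the likelihood conditions on a ≥ 1, matching the
    default fitting convention that drops zero-count pairs.
    """
    a = np.asarray(a, dtype=float)
    E = np.asarray(E, dtype=float)
    lw1 = math.log(h.p_mix) + _nb_logpmf(a, h.alpha1, h.beta1, E) if h.p_mix > 0 else -np.inf
    if h.p_mix < 1:
        lw2 = math.log1p(-h.p_mix) + _nb_logpmf(a, h.alpha2, h.beta2, E)
        ll = np.logaddexp(lw1, lw2)
    else:
        ll = lw1
    if zero_truncated:
        z1 = math.log(h.p_mix) + _nb_logpmf(np.zeros_like(E), h.alpha1, h.beta1, E) \
            if h.p_mix > 0 else -np.inf
        if h.p_mix < 1:
            z2 = math.log1p(-h.p_mix) + _nb_logpmf(np.zeros_like(E), h.alpha2, h.beta2, E)
            log_p0 = np.logaddexp(z1, z2)
        else:
            log_p0 = z1
        ll = ll - np.log1p(-np.exp(log_p0))
    return float(ll.sum())


_THETA_BOUND = 12.0  # |log shape/rate|, |logit p_mix| cap: keeps params in (6e-6, 1.6e5)


def _unpack_theta(theta: np.ndarray) -> tuple[float, float, float, float, float]:
    clipped = np.clip(theta, -_THETA_BOUND, _THETA_BOUND)
    a1, b1, a2, b2 = np.exp(clipped[:4])
    p = 1.0 / (1.0 + math.exp(-clipped[4]))
    return float(a1), float(b1), float(a2), float(b2), float(p)


def fit_mgps(tables: Iterable[ContingencyTable] | None = None,
             counts: np.ndarray | None = None,
             expected: np.ndarray | None = None,
             start: Sequence[float] = DEFAULT_MGPS_START,
             exclude_zero_counts: bool = True,
             extra_starts: bool = True) -> MgpsHyperparams:
    """Fit the five mixture hyperparameters by maximum marginal likelihood.

    Either pass PT-level ``tables`` (counts a and baseline expectations
    E = (a+b)(a+c)/n are extracted) or raw ``counts``/``expected`` arrays.
    Zero-count pairs are dropped by default and the likelihood is
    zero-truncated accordingly, so their exclusion does not bias the prior
    upward.  Positivity is enforced by log-reparameterization and the mixture
    weight by a logit; a few fixed alternative starts guard against local
    optima.  Non-convergence is flagged on the result rather than raised.
    """
    if counts is None or expected is None:
        if tables is None:
            raise ValueError("pass tables or counts+expected")
        tables = list(tables)
        counts = np.array([t.a for t in tables], dtype=float)
        expected = np.array([t.expected_a for t in tables], dtype=float)
    counts = np.asarray(counts, dtype=float)
    expected = np.asarray(expected, dtype=float)
    keep = expected > 0
    if exclude_zero_counts:
        keep &= counts > 0
    counts, expected = counts[keep], expected[keep]
    if len(counts) < 50:
        logger.warning("MGPS fit on only %d pairs; hyperparameters may be unstable",
                       len(counts))
    if len(counts) == 0:
        raise ValueError("no usable (count, expected) pairs for MGPS fit")

    penalty = 1e12  # finite penalty keeps numeric gradients usable

    def negloglik(theta: np.ndarray) -> float:
        a1, b1, a2, b2, p = _unpack_theta(theta)
        try:
            h = MgpsHyperparams(a1, b1, a2, b2, min(max(p, 1e-12), 1 - 1e-12))
        except ValueError:
            return penalty
        with np.errstate(all="ignore"):
            ll = mgps_marginal_loglik(h, counts, expected,
                                      zero_truncated=exclude_zero_counts)
        return penalty if not np.isfinite(ll) else -ll

    def theta_of(params: Sequence[float]) -> np.ndarray:
        a1, b1, a2, b2, p = params
        return np.array([math.log(a1), math.log(b1), math.log(a2), math.log(b2),
                         math.log(p / (1 - p))])

    starts = [theta_of(start)]
    if extra_starts:
        starts += [theta_of((1.0, 1.0, 1.0, 1.0, 0.5)),
                   theta_of((2.0, 0.5, 0.5, 2.0, 0.2))]

    bounds = [(-_THETA_BOUND, _THETA_BOUND)] * 5
    best_fun, best_theta, any_success = math.inf, starts[0], False
    for theta0 in starts:
        res1 = optimize.minimize(negloglik, theta0, method="L-BFGS-B", bounds=bounds)
        res2 = optimize.minimize(negloglik, res1.x, method="Nelder-Mead",
                                 options={"xatol": 1e-7, "fatol": 1e-9,
                                          "maxiter": 3000})
        res = res2 if res2.fun <= res1.fun else res1
        if res.fun < best_fun:
            best_fun, best_theta = float(res.fun), res.x
            any_success = bool(res1.success or res2.success)
    a1, b1, a2, b2, p = _unpack_theta(best_theta)
    converged = any_success and np.isfinite(best_fun) and best_fun < penalty
    if not converged:
        logger.warning("MGPS optimizer did not converge")
    return MgpsHyperparams(a1, b1, a2, b2, min(max(p, 1e-12), 1 - 1e-12),
                           converged=converged, loglik=float(-best_fun))


def compute_ebgm(t: ContingencyTable, h: MgpsHyperparams,
                 quantile: float = 0.05, tol: float = 1e-8) -> EbgmResult:
    """Posterior geometric mean (EBGM) and lower posterior quantile (EBGM05).

    The posterior on the relative reporting rate λ is the gamma mixture
    ``Q·Gamma(α1+a, β1+E) + (1−Q)·Gamma(α2+a, β2+E)`` with component weight Q
    from the two negative-binomial marginal likelihoods.  EBGM05 solves the
    mixture CDF = 0.05 by bracketed root finding.
    """
    E = t.expected_a
    if E <= 0:
        return EbgmResult(E, math.nan, math.nan, evaluable=False)
    a = float(t.a)
    if h.p_mix >= 1.0:
        Q = 1.0
    else:
        lw1 = math.log(h.p_mix) + float(_nb_logpmf(np.array([a]), h.alpha1, h.beta1,
                                                   np.array([E]))[0])
        lw2 = math.log1p(-h.p_mix) + float(_nb_logpmf(np.array([a]), h.alpha2, h.beta2,
                                                      np.array([E]))[0])
        m = max(lw1, lw2)
        Q = math.exp(lw1 - m) / (math.exp(lw1 - m) + math.exp(lw2 - m))

    s1, r1 = h.alpha1 + a, h.beta1 + E
    s2, r2 = h.alpha2 + a, h.beta2 + E
    log_ebgm = Q * (special.digamma(s1) - math.log(r1))
    if Q < 1.0:
        log_ebgm += (1 - Q) * (special.digamma(s2) - math.log(r2))
    ebgm = math.exp(log_ebgm)

    q1 = stats.gamma.ppf(quantile, s1, scale=1 / r1)
    q2 = stats.gamma.ppf(quantile, s2, scale=1 / r2) if Q < 1.0 else q1
    # the mixture quantile always lies between the component quantiles
    lo, hi = min(q1, q2), max(q1, q2)
    if hi - lo < tol:
        ebgm05 = 0.5 * (lo + hi)
    else:
        def cdf_gap(x: float) -> float:
            cdf = Q * stats.gamma.cdf(x, s1, scale=1 / r1)
            if Q < 1.0:
                cdf += (1 - Q) * stats.gamma.cdf(x, s2, scale=1 / r2)
            return cdf - quantile

        g_lo, g_hi = cdf_gap(lo), cdf_gap(hi)
        if g_lo >= 0.0:        # degenerate mixture weight: root sits on an endpoint
            ebgm05 = lo
        elif g_hi <= 0.0:
            ebgm05 = hi
        else:
            try:
                ebgm05 = optimize.brentq(cdf_gap, lo, hi, xtol=tol)
            except ValueError as exc:  # pragma: no cover
                raise RuntimeError(
                    f"EBGM05 bracket failure for pair ({t.drug}, {t.event})") from exc
    return EbgmResult(E, ebgm, ebgm05)


# ---------------------------------------------------------------------------
# Signal evaluation and ranking
# ---------------------------------------------------------------------------

def evaluate_criteria(rec: SignalRecord,
                      crit: SignalCriteria = SignalCriteria()) -> bool:
    """Conjunction of the six positive-signal conditions.

    Any not-evaluable statistic vetoes the flag.
    """
    if rec.table.a < crit.min_a:
        return False
    if not (rec.ror.evaluable and rec.prr.evaluable and rec.ebgm.evaluable):
        return False
    return bool(rec.ror.ci95_low > crit.ror_ci_low
                and rec.prr.prr > crit.prr
                and rec.ic.ic > crit.ic
                and rec.ic.ic_minus_2sd > crit.ic_minus_2sd
                and rec.ebgm.ebgm05 > crit.ebgm05)


def score_tables(tables: Sequence[ContingencyTable],
                 hyperparams: MgpsHyperparams | None = None,
                 priors: BcpnnPriors = BcpnnPriors(),
                 criteria: SignalCriteria = SignalCriteria(),
                 continuity_correction: bool = False,
                 yates: bool = True,
                 force_ebgm: bool = False) -> list[SignalRecord]:
    """Compute all four statistics and the signal flag for each table.

    The mixture prior is fitted across the supplied tables unless given.  If
    the fit did not converge, EBGM results are suppressed (not-evaluable,
    which vetoes every flag) unless ``force_ebgm`` is set.
    """
    tables = list(tables)
    if not tables:
        return []
    if hyperparams is None:
        hyperparams = fit_mgps(tables)
    suppress_ebgm = not hyperparams.converged and not force_ebgm
    if suppress_ebgm:
        logger.warning("MGPS fit unconverged: EBGM suppressed, no pair can be flagged")

    records = []
    for t in tables:
        if suppress_ebgm:
            ebgm = EbgmResult(t.expected_a, math.nan, math.nan, evaluable=False)
        else:
            ebgm = compute_ebgm(t, hyperparams)
        rec = SignalRecord(
            drug=t.drug, event=t.event, level=t.level, table=t,
            ror=compute_ror(t, continuity_correction),
            prr=compute_prr_chi2(t, yates=yates,
                                 continuity_correction=continuity_correction),
            ic=compute_ic(t, priors),
            ebgm=ebgm,
        )
        records.append(replace(rec, flagged=evaluate_criteria(rec, criteria)))
    return records


def rank_signals(records: Iterable[SignalRecord],
                 by: str = "ror",
                 top_n: int = 30,
                 exclude_indications: Sequence[str] = (),
                 exclude_progression: Sequence[str] = DEFAULT_PROGRESSION_TERMS,
                 flagged_only: bool = True,
                 min_a: int = 3) -> list[SignalRecord]:
    """Top-N signals sorted descending by ROR or report count.

    Drops pairs below ``min_a`` reports, events equal to a treated indication,
    and events containing a disease-progression term; the non-chosen key
    breaks ties.
    """
    if by not in ("ror", "count"):
        raise ValueError("rank key must be 'ror' or 'count'")
    indication_keys = {fold(text) for text in exclude_indications if text}
    progression_keys = [fold(term) for term in exclude_progression]

    kept = []
    for rec in records:
        if flagged_only and not rec.flagged:
            continue
        if rec.table.a < min_a:
            continue
        event_key = fold(rec.event)
        if event_key in indication_keys:
            continue
        if any(term in event_key for term in progression_keys):
            continue
        kept.append(rec)

    def sort_key(rec: SignalRecord):
        ror = rec.ror.ror if rec.ror.evaluable else -math.inf
        return (ror, rec.table.a) if by == "ror" else (rec.table.a, ror)

    kept.sort(key=sort_key, reverse=True)
    return kept[:top_n]


def signal_table(records: Sequence[SignalRecord]):
    """Export frame mirroring the published column order:
    drug, event, level, a, ROR (CI), PRR (χ²), IC (IC−2SD), EBGM (EBGM05), flag."""
    import pandas as pd

    rows = []
    for r in records:
        rows.append({
            "drug": r.drug, "event": r.event, "level": r.level, "a": r.table.a,
            "ror": r.ror.ror, "ror_ci95_low": r.ror.ci95_low,
            "ror_ci95_high": r.ror.ci95_high,
            "prr": r.prr.prr, "chi2": r.prr.chi2,
            "ic": r.ic.ic, "ic_minus_2sd": r.ic.ic_minus_2sd,
            "ebgm": r.ebgm.ebgm, "ebgm05": r.ebgm.ebgm05,
            "flagged": r.flagged,
        })
    return pd.DataFrame(rows, columns=["drug", "event", "level", "a", "ror",
                                       "ror_ci95_low", "ror_ci95_high", "prr",
                                       "chi2", "ic", "ic_minus_2sd", "ebgm",
                                       "ebgm05", "flagged"])
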