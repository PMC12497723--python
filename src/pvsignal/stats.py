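"""Disproportionality statistics for spontaneous-report 2x2 tables.

Four estimators of the same question — is the event reported more often
with the drug than the database background predicts? — with different
variance behaviour at small counts:

* ROR  — reporting odds ratio ad/bc, Wald 95% CI on the log scale.
* PRR  — proportional reporting ratio [a/(a+b)]/[c/(c+d)], paired with a
  Yates-corrected chi-square statistic.
* BCPNN IC — the information component, a shrunk log2 observed-to-expected
  ratio with closed-form posterior moments (Bate et al. 1998 style priors);
  IC025 is E(IC) minus a multiple (default 2) of the posterior SD.
* MGPS EBGM — DuMouchel's empirical-Bayes geometric mean of the
  observed/expected ratio under a two-component gamma mixture prior fitted
  by marginal (negative-binomial mixture) maximum likelihood across all
  tables; EBGM05 is the posterior 5th percentile.

Zero cells: when any cell is 0 the Haldane–Anscombe +0.5 correction is
applied to all four cells for ROR and PRR only; nonzero tables are left
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .contingency import ContingencyTable

__all__ = [
    "ror_with_ci",
    "prr_with_chi2",
    "ic_point",
    "BcpnnPrior",
    "bcpnn_ic",
    "MgpsPrior",
    "fit_mgps_prior",
    "mgps_loglik",
    "posterior_mixture",
    "ebgm_with_lb",
    "ebgm_simplified",
    "ThresholdCriteria",
    "SignalResult",
    "apply_thresholds",
    "compute_signal",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


def _cells(t: ContingencyTable, haldane: bool = True) -> tuple[float, float, float, float]:
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if haldane and min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return a, b, c, d


def ror_with_ci(t: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio ad/bc with Wald 95% CI on the natural-log scale."""
    a, b, c, d = _cells(t)
    ror = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * np.exp(-_Z95 * se), ror * np.exp(_Z95 * se)


def prr_with_chi2(t: ContingencyTable) -> tuple[float, float]:
    """Proportional reporting ratio with a Yates-corrected chi-square."""
    a, b, c, d = _cells(t)
    prr = (a / (a + b)) / (c / (c + d))
    obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    if obs.sum(axis=0).min() == 0 or obs.sum(axis=1).min() == 0:
        chi2 = 0.0  # a degenerate margin carries no association evidence
    else:
        chi2 = float(stats.chi2_contingency(obs, correction=True).statistic)
    return prr, chi2


def ic_point(t: ContingencyTable) -> float:
    """Prior-free information component log2(a*N / ((a+b)(a+c)))."""
    a, b, c, d = _cells(t)
    n = a + b + c + d
    return float(np.log2(a * n / ((a + b) * (a + c))))


@dataclass(frozen=True)
class BcpnnPrior:
    """Standard BCPNN hyperparameters (uniform-style beta/dirichlet priors)."""

    alpha1: float = 1.0  # drug margin
    beta1: float = 1.0  # event margin
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0


def bcpnn_ic(
    t: ContingencyTable,
    prior: BcpnnPrior = BcpnnPrior(),
    multiplier: float = 2.0,
) -> tuple[float, float]:
    """Closed-form posterior mean of the IC and its lower bound.

    Returns (E(IC), E(IC) - multiplier * sqrt(V(IC))).
    """
    a = float(t.a)
    row = float(t.a + t.b)
    col = float(t.a + t.c)
    n = float(t.n_total)
    p = prior
    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / (
        (row + p.alpha1) * (col + p.beta1)
    )
    e_ic = np.log2(
        (a + p.gamma11) * (n + p.alpha) * (n + p.beta)
        / ((n + gamma) * (row + p.alpha1) * (col + p.beta1))
    )
    v_ic = (
        (n - a + gamma - p.gamma11) / ((a + p.gamma11) * (1 + n + gamma))
        + (n - row + p.alpha - p.alpha1) / ((row + p.alpha1) * (1 + n + p.alpha))
        + (n - col + p.beta - p.beta1) / ((col + p.beta1) * (1 + n + p.beta))
    ) / (np.log(2.0) ** 2)
    return float(e_ic), float(e_ic - multiplier * np.sqrt(v_ic))


# ---------------------------------------------------------------------------
# MGPS / EBGM


@dataclass(frozen=True)
class MgpsPrior:
    """Two-component gamma mixture prior on the reporting ratio lambda.

    Component j is Gamma(shape alpha_j, rate beta_j); p_mix weights the
    first component.  DuMouchel's canonical starting values are
    (0.2, 0.1, 2, 4, 1/3).
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p_mix: float

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma parameters must be positive")
        if not 0.0 <= self.p_mix <= 1.0:
            raise ValueError("p_mix must lie in [0, 1]")


def _nb_logpmf(a: np.ndarray, alpha: float, beta: float, e: np.ndarray) -> np.ndarray:
    """Marginal of a | lambda~Gamma(alpha, beta), a|lambda ~ Poisson(lambda*E)."""
    return (
        special.gammaln(alpha + a)
        - special.gammaln(alpha)
        - special.gammaln(a + 1.0)
        + alpha * np.log(beta / (beta + e))
        + a * np.log(e / (beta + e))
    )


def mgps_loglik(
    prior: MgpsPrior, a: np.ndarray, expected: np.ndarray
) -> float:
    """Mixture negative-binomial marginal log-likelihood of observed counts."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(expected, dtype=float)
    l1 = _nb_logpmf(a, prior.alpha1, prior.beta1, e)
    l2 = _nb_logpmf(a, prior.alpha2, prior.beta2, e)
    with np.errstate(divide="ignore"):
        terms = np.logaddexp(
            np.log(prior.p_mix) + l1, np.log1p(-prior.p_mix) + l2
        )
    return float(terms.sum())


_CANONICAL_START = np.array([0.2, 0.1, 2.0, 4.0, 1.0 / 3.0])


def fit_mgps_prior(
    tables: Sequence[ContingencyTable] | tuple[np.ndarray, np.ndarray],
    n_restarts: int = 3,
    seed: int = 0,
) -> MgpsPrior:
    """Fit the mixture prior by direct marginal-likelihood maximization.

    Accepts either a list of contingency tables or a pre-extracted
    ``(a, expected)`` array pair.  Optimization runs L-BFGS-B on
    unconstrained transforms (log gamma parameters, logit mixture weight)
    from the canonical start plus ``n_restarts`` seeded perturbations; the
    best optimum wins, so the fit is deterministic for a fixed seed.
    """
    if isinstance(tables, tuple):
        a, e = (np.asarray(x, dtype=float) for x in tables)
    else:
        if len(tables) < 2:
            raise ValueError("MGPS prior fitting needs at least 2 tables")
        a = np.asarray([t.a for t in tables], dtype=float)
        e = np.asarray([t.expected for t in tables], dtype=float)
    if np.all(a == 0):
        raise ValueError("degenerate input: every table has a = 0")
    e = np.maximum(e, 1e-12)

    def nll(theta: np.ndarray) -> float:
        a1, b1, a2, b2 = np.exp(np.clip(theta[:4], -20.0, 20.0))
        p = special.expit(theta[4])
        p = min(max(p, 1e-12), 1 - 1e-12)
        return -mgps_loglik(MgpsPrior(a1, b1, a2, b2, p), a, e)

    bounds = [(-20.0, 20.0)] * 4 + [(-30.0, 30.0)]

    rng = np.random.default_rng(seed)
    starts = [_CANONICAL_START]
    # one start from a single-gamma fit: protects the nested case where the
    # data carry no mixture structure
    single = optimize.minimize(
        lambda th: nll(np.array([th[0], th[1], th[0], th[1], 0.0])),
        [0.0, 0.0],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10},
    )
    sa, sb = np.exp(np.clip(single.x, -20.0, 20.0))
    starts.append(np.array([sa, sb, sa * 1.5, sb, 0.5]))
    for _ in range(n_restarts):
        starts.append(_CANONICAL_START * np.exp(rng.normal(0, 0.5, size=5)))
    best = None
    for s in starts:
        theta0 = np.concatenate([np.log(s[:4]), [special.logit(min(s[4], 0.95))]])
        res = optimize.minimize(
            nll, theta0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-9, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun:
            best = res
    # simplex polish: L-BFGS-B's finite-difference gradient can stall a
    # few 1e-4 short of the optimum on flat mixture likelihoods
    polish = optimize.minimize(
        nll, best.x, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 4000},
    )
    if polish.fun < best.fun:
        best = polish
    th = best.x
    a1, b1, a2, b2 = np.exp(np.clip(th[:4], -20.0, 20.0))
    p = float(special.expit(th[4]))
    # canonical order: first component has the smaller prior mean
    if a1 / b1 > a2 / b2:
        a1, b1, a2, b2, p = a2, b2, a1, b1, 1.0 - p
    return MgpsPrior(
        alpha1=float(a1), beta1=float(b1),
        alpha2=float(a2), beta2=float(b2), p_mix=p,
    )


def posterior_mixture(
    t: ContingencyTable, prior: MgpsPrior
) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Posterior of lambda given a: mixture of two gammas.

    Returns (Q1, (shape1, rate1), (shape2, rate2)) where Q1 is the
    posterior weight on the first component.
    """
    a = float(t.a)
    e = max(t.expected, 1e-12)
    l1 = _nb_logpmf(np.array(a), prior.alpha1, prior.beta1, np.array(e))
    l2 = _nb_logpmf(np.array(a), prior.alpha2, prior.beta2, np.array(e))
    p = min(max(prior.p_mix, 1e-300), 1.0 - 1e-16)
    log_w1 = np.log(p) + l1
    log_w2 = np.log1p(-p) + l2
    q1 = float(np.exp(log_w1 - np.logaddexp(log_w1, log_w2)))
    return q1, (prior.alpha1 + a, prior.beta1 + e), (prior.alpha2 + a, prior.beta2 + e)


def ebgm_with_lb(
    t: ContingencyTable, prior: MgpsPrior, percentile: float = 0.05
) -> tuple[float, float]:
    """EBGM (posterior geometric mean of lambda) and its lower percentile.

    EBGM = exp(E[ln lambda]); the default bound is the posterior 5th
    percentile (EBGM05), found by root-finding on the mixture-gamma CDF.
    """
    q1, (s1, r1), (s2, r2) = posterior_mixture(t, prior)
    e_log = q1 * (special.digamma(s1) - np.log(r1)) + (1 - q1) * (
        special.digamma(s2) - np.log(r2)
    )
    ebgm = float(np.exp(e_log))

    def cdf(lam: float) -> float:
        return q1 * stats.gamma.cdf(lam, s1, scale=1 / r1) + (1 - q1) * stats.gamma.cdf(
            lam, s2, scale=1 / r2
        ) - percentile

    hi = max(ebgm * 10, 10.0)
    while cdf(hi) < 0:  # pragma: no cover - pathological priors only
        hi *= 10
    lb = float(optimize.brentq(cdf, 1e-12, hi, xtol=1e-12, rtol=1e-12))
    return ebgm, lb


def ebgm_simplified(t: ContingencyTable) -> tuple[float, float]:
    """No-shrinkage comparator: a/E with a chi-square-based 5% lower bound.

    The bound is the exact Poisson-rate lower limit chi2(0.05, 2a)/2 / E.
    """
    e = max(t.expected, 1e-12)
    point = t.a / e
    lb = 0.0 if t.a == 0 else float(stats.chi2.ppf(0.05, 2 * t.a) / 2.0 / e)
    return point, lb


# ---------------------------------------------------------------------------
# thresholds and assembled results


@dataclass(frozen=True)
class ThresholdCriteria:
    """Positivity thresholds per method (the common screening convention)."""

    ror_min_a: int = 3
    ror_lo_gt: float = 1.0
    prr_min_a: int = 3
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0


@dataclass(frozen=True)
class SignalResult:
    term: str
    level: str
    a: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    ror_flag: bool
    prr_flag: bool
    bcpnn_flag: bool
    mgps_flag: bool

    @property
    def methods_flagged(self) -> frozenset[str]:
        return frozenset(
            name
            for name, flag in (
                ("ROR", self.ror_flag),
                ("PRR", self.prr_flag),
                ("BCPNN", self.bcpnn_flag),
                ("MGPS", self.mgps_flag),
            )
            if flag
        )

    @property
    def consensus_any(self) -> bool:
        return bool(self.methods_flagged)

    @property
    def consensus_all(self) -> bool:
        return len(self.methods_flagged) == 4


def apply_thresholds(
    a: int,
    ror_lo: float,
    prr: float,
    chi2: float,
    ic025: float,
    ebgm05: float,
    criteria: ThresholdCriteria = ThresholdCriteria(),
) -> dict[str, bool]:
    """Per-method positivity flags; boundary values do not flag."""
    return {
        "ror_flag": a >= criteria.ror_min_a and ror_lo > criteria.ror_lo_gt,
        "prr_flag": (
            a >= criteria.prr_min_a
            and prr >= criteria.prr_min
            and chi2 >= criteria.chi2_min
        ),
        "bcpnn_flag": ic025 > criteria.ic025_gt,
        "mgps_flag": ebgm05 > criteria.ebgm05_gt,
    }


def compute_signal(
    t: ContingencyTable,
    prior: MgpsPrior,
    criteria: ThresholdCriteria = ThresholdCriteria(),
    bcpnn_prior: BcpnnPrior = BcpnnPrior(),
    ic_multiplier: float = 2.0,
) -> SignalResult:
    """All four statistics, interval bounds and flags for one table."""
    ror, lo, hi = ror_with_ci(t)
    prr, chi2 = prr_with_chi2(t)
    ic, ic025 = bcpnn_ic(t, bcpnn_prior, ic_multiplier)
    ebgm, ebgm05 = ebgm_with_lb(t, prior)
    flags = apply_thresholds(t.a, lo, prr, chi2, ic025, ebgm05, criteria)
    return SignalResult(
        term=t.term, level=t.level, a=t.a,
        ror=ror, ror_lo=lo, ror_hi=hi,
        prr=prr, chi2=chi2, ic=ic, ic025=ic025,
        ebgm=ebgm, ebgm05=ebgm05, **flags,
    )
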