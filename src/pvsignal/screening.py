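"""Run the four disproportionality methods over all terms and rank."""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .contingency import all_tables
from .io import CaseReport
from .stats import (
    BcpnnPrior,
    MgpsPrior,
    SignalResult,
    ThresholdCriteria,
    compute_signal,
    fit_mgps_prior,
)

__all__ = [
    "screen",
    "method_combination_counts",
    "top_n",
    "results_to_frame",
    "format_published_style",
]

logger = logging.getLogger(__name__)

METHODS = ("ROR", "PRR", "BCPNN", "MGPS")


def screen(
    exposed: Sequence[CaseReport],
    background: Sequence[CaseReport],
    level: str = "PT",
    soc_map: Mapping[str, str] | None = None,
    criteria: ThresholdCriteria = ThresholdCriteria(),
    bcpnn_prior: BcpnnPrior = BcpnnPrior(),
    ic_multiplier: float = 2.0,
    mgps_prior: MgpsPrior | None = None,
    mgps_seed: int = 0,
) -> list[SignalResult]:
    """Statistics for every term reported in the exposed cohort, ranked.

    The MGPS prior is fitted once across all tables (unless supplied);
    results are sorted by case count descending, ties broken by ROR
    descending then term, so output order is deterministic.
    """
    tables = all_tables(exposed, background, level=level, soc_map=soc_map)
    if not tables:
        return []
    if mgps_prior is None:
        if len(tables) >= 2:
            mgps_prior = fit_mgps_prior(tables, seed=mgps_seed)
        else:
            logger.warning("single term: using canonical MGPS prior, not fitted")
            mgps_prior = MgpsPrior(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)
    results = [
        compute_signal(t, mgps_prior, criteria, bcpnn_prior, ic_multiplier)
        for t in tables
    ]
    results.sort(key=lambda r: (-r.a, -r.ror, r.term))
    return results


def method_combination_counts(
    results: Iterable[SignalResult],
) -> dict[frozenset[str], int]:
    """Terms flagged by exactly each subset of the four methods.

    The Venn-diagram counts: keys are frozensets of method names (the
    empty set collects unflagged terms); values sum to the number of
    terms.
    """
    counts: dict[frozenset[str], int] = {}
    for r in results:
        key = r.methods_flagged
        counts[key] = counts.get(key, 0) + 1
    return counts


def top_n(results: Sequence[SignalResult], n: int) -> pd.DataFrame:
    """First ``n`` ranked rows formatted in the published-table layout."""
    if n > len(results):
        logger.info("requested top %d of %d results; returning all", n, len(results))
    return format_published_style(results[: max(n, 0)])


def results_to_frame(results: Iterable[SignalResult]) -> pd.DataFrame:
    """Raw numeric export, one row per term."""
    return pd.DataFrame(
        [
            {
                "term": r.term, "level": r.level, "case_reports": r.a,
                "ror": r.ror, "ror_lo": r.ror_lo, "ror_hi": r.ror_hi,
                "prr": r.prr, "chi2": r.chi2, "ic": r.ic, "ic025": r.ic025,
                "ebgm": r.ebgm, "ebgm05": r.ebgm05,
                "ror_flag": r.ror_flag, "prr_flag": r.prr_flag,
                "bcpnn_flag": r.bcpnn_flag, "mgps_flag": r.mgps_flag,
                "consensus_any": r.consensus_any, "consensus_all": r.consensus_all,
            }
            for r in results
        ]
    )


def format_published_style(results: Iterable[SignalResult]) -> pd.DataFrame:
    """Columns in the conventional report layout: estimate (bound) strings."""
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "case_reports": r.a,
                "ROR (95% CI)": f"{r.ror:.2f} ({r.ror_lo:.2f}-{r.ror_hi:.2f})",
                "PRR (chi2)": f"{r.prr:.2f} ({r.chi2:.2f})",
                "EBGM (EBGM05)": f"{r.ebgm:.2f} ({r.ebgm05:.2f})",
                "IC (IC025)": f"{r.ic:.2f} ({r.ic025:.2f})",
            }
            for r in results
        ]
    )
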