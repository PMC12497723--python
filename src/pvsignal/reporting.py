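"""Descriptive tables and the end-of-run report bundle.

Percentages are rounded half-up to one decimal, matching the usual
presentation of report-characteristics tables; every characteristic
carries a "Not specified" row so its column sums to the cohort total.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .io import NOT_SPECIFIED, CaseReport
from .screening import method_combination_counts, results_to_frame
from .stats import SignalResult
from .tto import OnsetSample, WeibullFit, bin_onsets, summarize_onsets

__all__ = [
    "round_percent",
    "describe_cohort",
    "annual_counts",
    "quarterly_partition",
    "cumulative_incidence",
    "write_report_bundle",
]

logger = logging.getLogger(__name__)

_OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-Threatening",
    "HO": "Hospitalization",
    "DS": "Disability",
    "CA": "Cancer / congenital anomaly",
    "RI": "Required intervention to prevent permanent impairment",
    "OT": "Other serious outcome",
}


def round_percent(count: int, total: int) -> float:
    """count/total as a percentage, one decimal, half-up."""
    if total == 0:
        return 0.0
    pct = Decimal(count) / Decimal(total) * 100
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _age_band(age: float | None) -> str:
    if age is None:
        return NOT_SPECIFIED
    if age < 18:
        return "<18"
    if age <= 65:
        return "18-65"
    if age <= 85:
        return "65-85"
    return ">85"


def _weight_band(wt: float | None) -> str:
    if wt is None:
        return NOT_SPECIFIED
    if wt < 50:
        return "<50"
    if wt <= 100:
        return "50-100"
    return ">100"


def _characteristics(case: CaseReport) -> dict[str, str]:
    ps_indication = next(
        (d.indication for d in case.drugs if d.role_cod == "PS" and d.indication),
        None,
    )
    outcome = case.outcomes[0] if case.outcomes else None
    return {
        "sex": case.sex,
        "weight_kg": _weight_band(case.weight_kg),
        "age_years": _age_band(case.age_years),
        "country": case.country,
        "reporter": case.reporter,
        "report_year": str(case.fda_dt.year) if case.fda_dt else NOT_SPECIFIED,
        "outcome": _OUTCOME_LABELS.get(outcome, outcome) if outcome else NOT_SPECIFIED,
        "indication": ps_indication or NOT_SPECIFIED,
    }


def describe_cohort(exposed_cases: Sequence[CaseReport]) -> pd.DataFrame:
    """Frequency table per characteristic with counts and percentages.

    Columns: characteristic, category, count, percent.  Within each
    characteristic the categories (including "Not specified") partition
    the cohort, so counts sum to the total and percentages to ~100.
    """
    total = len(exposed_cases)
    counters: dict[str, Counter[str]] = {}
    for case in exposed_cases:
        for char, cat in _characteristics(case).items():
            counters.setdefault(char, Counter())[cat] += 1
    rows = []
    for char, counter in counters.items():
        ordered = sorted(
            counter.items(), key=lambda kv: (kv[0] == NOT_SPECIFIED, -kv[1], kv[0])
        )
        for cat, count in ordered:
            rows.append(
                {
                    "characteristic": char,
                    "category": cat,
                    "count": count,
                    "percent": round_percent(count, total),
                }
            )
    return pd.DataFrame(rows)


def annual_counts(exposed_cases: Sequence[CaseReport]) -> dict[int, int]:
    """Reports per receipt year (FDA_DT); no year is silently truncated."""
    counts: Counter[int] = Counter(
        case.fda_dt.year for case in exposed_cases if case.fda_dt
    )
    return dict(sorted(counts.items()))


def quarterly_partition(
    cases: Sequence[CaseReport],
) -> dict[str, list[CaseReport]]:
    """Cases keyed by receipt quarter label (e.g. "2019Q3"), ordered."""
    out: dict[str, list[CaseReport]] = {}
    for case in cases:
        if case.fda_dt is None:
            continue
        month = int(case.fda_dt.raw[4:6]) if case.fda_dt.precision != "year" else 1
        label = f"{case.fda_dt.year}Q{(month - 1) // 3 + 1}"
        out.setdefault(label, []).append(case)
    return dict(sorted(out.items()))


def cumulative_incidence(
    quarterly_results: Sequence[tuple[str, Sequence[SignalResult]]],
    term: str,
    strict: bool = False,
) -> list[tuple[str, int]]:
    """Cumulative case count for one term across ordered quarters.

    With ``strict`` the term must appear in at least one quarter's
    results; otherwise an absent term yields an all-zero series.
    """
    seen = {r.term for _, results in quarterly_results for r in results}
    if strict and term not in seen:
        raise KeyError(f"term {term!r} not present in any quarter's results")
    series: list[tuple[str, int]] = []
    running = 0
    for quarter, results in quarterly_results:
        running += next((r.a for r in results if r.term == term), 0)
        series.append((quarter, running))
    return series


def write_report_bundle(
    out_dir: str | Path,
    exposed_cases: Sequence[CaseReport],
    pt_results: Sequence[SignalResult],
    soc_results: Sequence[SignalResult] | None = None,
    tto_sample: OnsetSample | None = None,
    tto_fit: WeibullFit | None = None,
    subgroup_results: Mapping[str, Sequence[SignalResult]] | None = None,
    sensitivity_results: Sequence[SignalResult] | None = None,
    config_echo: Mapping[str, object] | None = None,
    seed: int | None = None,
) -> Path:
    """Write the full report bundle directory and return its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    describe_cohort(exposed_cases).to_csv(out / "cohort.csv", index=False)
    pd.DataFrame(
        annual_counts(exposed_cases).items(), columns=["year", "count"]
    ).to_csv(out / "annual.csv", index=False)
    results_to_frame(pt_results).to_csv(out / "signals_pt.csv", index=False)
    if soc_results is not None:
        results_to_frame(soc_results).to_csv(out / "signals_soc.csv", index=False)
    venn = method_combination_counts(pt_results)
    pd.DataFrame(
        [
            {"methods": "+".join(sorted(k)) or "none", "terms": v}
            for k, v in sorted(venn.items(), key=lambda kv: sorted(kv[0]))
        ]
    ).to_csv(out / "venn.csv", index=False)
    if tto_sample is not None and tto_sample.days:
        median, q1, q3 = summarize_onsets(tto_sample)
        row = {
            "case_reports": len(tto_sample.days),
            "median_days": median,
            "q1_days": q1,
            "q3_days": q3,
            "n_excluded_missing": tto_sample.n_excluded_missing,
            "n_excluded_negative": tto_sample.n_excluded_negative,
        }
        for label, count in zip(
            ["0_30", "31_60", "61_90", "91_180", "181_360", "gt360"],
            bin_onsets(tto_sample),
        ):
            row[f"bin_{label}"] = count
        if tto_fit is not None:
            row.update(
                alpha=tto_fit.alpha, alpha_lo=tto_fit.alpha_lo,
                alpha_hi=tto_fit.alpha_hi, beta=tto_fit.beta,
                beta_lo=tto_fit.beta_lo, beta_hi=tto_fit.beta_hi,
                classification=tto_fit.classification,
            )
        pd.DataFrame([row]).to_csv(out / "tto.csv", index=False)
    elif tto_sample is not None:
        pd.DataFrame(
            [
                {
                    "case_reports": 0,
                    "n_excluded_missing": tto_sample.n_excluded_missing,
                    "n_excluded_negative": tto_sample.n_excluded_negative,
                }
            ]
        ).to_csv(out / "tto.csv", index=False)
    for stratum, results in (subgroup_results or {}).items():
        safe = "".join(ch if ch.isalnum() else "_" for ch in stratum)
        results_to_frame(results).to_csv(
            out / f"subgroup_{safe}.csv", index=False
        )
    if sensitivity_results is not None:
        results_to_frame(sensitivity_results).to_csv(
            out / "sensitivity.csv", index=False
        )
    echo = dict(config_echo or {})
    blob = json.dumps(echo, sort_keys=True, default=str)
    log = {
        "seed": seed,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "config": echo,
        "n_exposed": len(exposed_cases),
        "n_pt_results": len(pt_results),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return out
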