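"""Subgroup (stratified) and monotherapy sensitivity screening.

Subgroup screens compare each stratum's exposed cases against the
same-stratum background, removing the stratifier as a confounder.  The
monotherapy filter keeps only exposed cases whose single drug record is
the target as primary suspect, the standard co-medication sensitivity
analysis.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .io import CaseReport, filter_primary_suspect
from .screening import screen
from .stats import SignalResult, ThresholdCriteria

__all__ = ["subgroup_screen", "monotherapy_filter"]

logger = logging.getLogger(__name__)

_STRATIFIERS = {"sex": lambda case: case.sex}


def subgroup_screen(
    cases: Sequence[CaseReport],
    drug_name: str,
    stratifier: str = "sex",
    level: str = "PT",
    soc_map: Mapping[str, str] | None = None,
    criteria: ThresholdCriteria = ThresholdCriteria(),
    min_exposed: int = 10,
) -> dict[str, list[SignalResult]]:
    """Per-stratum ranked results, one screen per stratum value.

    Strata with fewer than ``min_exposed`` exposed cases are skipped with
    a log entry.  The "not specified" stratum is screened like any other
    but callers conventionally do not report it as a signal stratum.
    """
    try:
        key = _STRATIFIERS[stratifier]
    except KeyError:
        raise ValueError(
            f"unknown stratifier {stratifier!r}; supported: {sorted(_STRATIFIERS)}"
        ) from None
    strata: dict[str, list[CaseReport]] = {}
    for case in cases:
        strata.setdefault(key(case), []).append(case)
    out: dict[str, list[SignalResult]] = {}
    for value in sorted(strata):
        exposed, background = filter_primary_suspect(strata[value], drug_name)
        if len(exposed) < min_exposed:
            logger.info(
                "stratum %s=%r skipped: %d exposed cases (< %d)",
                stratifier, value, len(exposed), min_exposed,
            )
            continue
        out[value] = screen(
            exposed, background, level=level, soc_map=soc_map, criteria=criteria
        )
    return out


def monotherapy_filter(
    cases: Sequence[CaseReport], drug_name: str
) -> list[CaseReport]:
    """Exposed cases whose only drug record is the target with role PS."""
    return [
        case
        for case in cases
        if len(case.drugs) == 1
        and case.drugs[0].name == drug_name
        and case.drugs[0].role_cod == "PS"
    ]
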