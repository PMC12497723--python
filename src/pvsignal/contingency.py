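"""Four-cell (2x2) contingency tables for drug–event pairs.

The counting unit is the case: a case contributes at most one count to a
term even if the PT appears on several reaction rows, and at most one
count to a SOC even when several of its PTs map there.  The background is
the whole deduplicated non-exposed database.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import CaseReport

__all__ = ["ContingencyTable", "count_term", "all_tables", "tables_to_frame",
           "UNMAPPED_SOC"]

logger = logging.getLogger(__name__)

UNMAPPED_SOC = "UNMAPPED"


@dataclass(frozen=True)
class ContingencyTable:
    """Cells a (exposed with term), b, c (background with term), d."""

    term: str
    level: str  # "PT" | "SOC"
    a: int
    b: int
    c: int
    d: int

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected a under independence: (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n_total

    def swapped(self) -> "ContingencyTable":
        return ContingencyTable(self.term, self.level, self.c, self.d, self.a, self.b)


def _case_terms(
    case: CaseReport, level: str, soc_map: Mapping[str, str] | None
) -> frozenset[str]:
    if level == "PT":
        return case.reactions
    if level == "SOC":
        if soc_map is None:
            raise ValueError("SOC-level counting requires a PT->SOC mapping")
        return frozenset(soc_map.get(pt, UNMAPPED_SOC) for pt in case.reactions)
    raise ValueError(f"unknown level {level!r} (expected 'PT' or 'SOC')")


def count_term(
    exposed: Sequence[CaseReport],
    background: Sequence[CaseReport],
    term: str,
    level: str = "PT",
    soc_map: Mapping[str, str] | None = None,
) -> ContingencyTable:
    """The four-cell table for one term at PT or SOC level."""
    a = sum(term in _case_terms(case, level, soc_map) for case in exposed)
    c = sum(term in _case_terms(case, level, soc_map) for case in background)
    return ContingencyTable(
        term=term, level=level, a=a, b=len(exposed) - a, c=c,
        d=len(background) - c,
    )


def all_tables(
    exposed: Sequence[CaseReport],
    background: Sequence[CaseReport],
    level: str = "PT",
    soc_map: Mapping[str, str] | None = None,
) -> list[ContingencyTable]:
    """One table per term observed in the exposed cohort (a >= 1)."""
    a_counts: Counter[str] = Counter()
    for case in exposed:
        a_counts.update(_case_terms(case, level, soc_map))
    c_counts: Counter[str] = Counter()
    for case in background:
        c_counts.update(_case_terms(case, level, soc_map) & a_counts.keys())
    if level == "SOC" and UNMAPPED_SOC in a_counts:
        logger.warning(
            "%d exposed cases carry PTs missing from the SOC map",
            a_counts[UNMAPPED_SOC],
        )
    n_exp, n_bg = len(exposed), len(background)
    return [
        ContingencyTable(
            term=term, level=level, a=a, b=n_exp - a,
            c=c_counts.get(term, 0), d=n_bg - c_counts.get(term, 0),
        )
        for term, a in sorted(a_counts.items())
    ]


def tables_to_frame(tables: Iterable[ContingencyTable]) -> pd.DataFrame:
    """CSV-ready export with columns term, level, a, b, c, d, N."""
    return pd.DataFrame(
        [
            {"term": t.term, "level": t.level, "a": t.a, "b": t.b,
             "c": t.c, "d": t.d, "N": t.n_total}
            for t in tables
        ]
    )
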