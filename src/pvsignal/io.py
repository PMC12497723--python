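"""Reading FAERS-style quarterly ASCII tables and assembling case reports.

The FDA distributes FAERS as dollar-sign-delimited text tables (DEMO,
DRUG, REAC, THER, OUTC, INDI), one header line each.  This module parses
those tables, removes duplicate reports (one retained record per CASEID:
most recent FDA_DT, ties broken by the higher PRIMARYID), and joins the
tables into per-case records suitable for disproportionality analysis.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dates import PartialDate, parse_partial_date

__all__ = [
    "RawTables",
    "DrugRecord",
    "CaseReport",
    "read_faers_tables",
    "write_faers_tables",
    "deduplicate",
    "assemble_cases",
    "filter_primary_suspect",
    "normalize_drug_name",
    "cases_to_jsonl",
    "cases_from_jsonl",
]

logger = logging.getLogger(__name__)

NOT_SPECIFIED = "Not specified"

#: mandatory columns per table; a missing one is a hard error
REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("primaryid", "caseid", "fda_dt"),
    "drug": ("primaryid", "drug_seq", "drugname", "role_cod"),
    "reac": ("primaryid", "pt"),
    "ther": ("primaryid", "dsg_drug_seq", "start_dt"),
    "outc": ("primaryid", "outc_cod"),
    "indi": ("primaryid", "indi_drug_seq", "indi_pt"),
}

#: optional DEMO columns, filled with "" when absent from the file
OPTIONAL_DEMO_COLUMNS = (
    "event_dt",
    "sex",
    "age",
    "age_cod",
    "wt",
    "wt_cod",
    "occr_country",
    "occp_cod",
)


@dataclass
class RawTables:
    """The six parsed quarterly tables, columns lower-cased, all-string."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame
    n_bad_lines: dict[str, int] = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "demo": self.demo,
            "drug": self.drug,
            "reac": self.reac,
            "ther": self.ther,
            "outc": self.outc,
            "indi": self.indi,
        }


@dataclass(frozen=True)
class DrugRecord:
    drug_seq: int
    name: str  # normalized
    role_cod: str  # PS / SS / C / I
    therapy_start: PartialDate | None = None
    indication: str | None = None


@dataclass(frozen=True)
class CaseReport:
    """One deduplicated safety report."""

    primaryid: str
    caseid: str
    fda_dt: PartialDate | None
    event_dt: PartialDate | None
    sex: str
    age_years: float | None
    weight_kg: float | None
    country: str
    reporter: str
    outcomes: tuple[str, ...]
    drugs: tuple[DrugRecord, ...]
    reactions: frozenset[str]

    def has_drug(self, name: str, roles: Sequence[str] | None = None) -> bool:
        return any(
            d.name == name and (roles is None or d.role_cod in roles)
            for d in self.drugs
        )


def _read_one(path: str | Path, name: str, delimiter: str) -> tuple[pd.DataFrame, int]:
    bad = 0

    def _on_bad(line: list[str]):  # pragma: no cover - exercised via malformed file
        nonlocal bad
        bad += 1
        return None

    df = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        engine="python",
        on_bad_lines=_on_bad,
    )
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS[name] if c not in df.columns]
    if missing:
        raise ValueError(
            f"{name.upper()}/{missing[0]}: mandatory column missing from {path}"
        )
    return df, bad


def read_faers_tables(
    paths: Mapping[str, str | Path], delimiter: str = "$"
) -> RawTables:
    """Parse the six quarterly tables.

    ``paths`` maps the table names demo/drug/reac/ther/outc/indi to files.
    Unparseable rows are counted (``RawTables.n_bad_lines``) and logged,
    never fatal; a missing mandatory column is a hard error naming the
    table and column.
    """
    frames: dict[str, pd.DataFrame] = {}
    n_bad: dict[str, int] = {}
    for name in REQUIRED_COLUMNS:
        if name not in paths:
            raise ValueError(f"no path supplied for table {name.upper()}")
        df, bad = _read_one(paths[name], name, delimiter)
        if bad:
            logger.warning("%s: skipped %d unparseable rows", name.upper(), bad)
        frames[name] = df
        n_bad[name] = bad
    demo = frames["demo"]
    for col in OPTIONAL_DEMO_COLUMNS:
        if col not in demo.columns:
            demo[col] = ""
    return RawTables(**frames, n_bad_lines=n_bad)


def write_faers_tables(
    tables: RawTables, out_dir: str | Path, delimiter: str = "$"
) -> dict[str, Path]:
    """Write the six tables in the same dialect ``read_faers_tables`` reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.tables().items():
        p = out / f"{name.upper()}.txt"
        df.to_csv(p, sep=delimiter, index=False)
        paths[name] = p
    return paths


# ---------------------------------------------------------------------------
# deduplication


def _primaryid_key(pid: str):
    # numeric comparison when castable (FAERS primaryids are numeric strings)
    s = str(pid).strip()
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


def deduplicate(demo: pd.DataFrame) -> set[str]:
    """One retained PRIMARYID per CASEID.

    Keeps the row with the most recent FDA_DT within each CASEID group
    (zero-padded numeric order on the partial date); ties on FDA_DT are
    broken by the higher PRIMARYID.
    """
    retained: set[str] = set()
    best: dict[str, tuple[int, tuple, str]] = {}
    for pid, caseid, fda in zip(demo["primaryid"], demo["caseid"], demo["fda_dt"]):
        d = parse_partial_date(fda)
        key = (d.sort_key() if d is not None else -1, _primaryid_key(pid), str(pid))
        cur = best.get(caseid)
        if cur is None or key[:2] > cur[:2]:
            best[caseid] = key
    retained = {key[2] for key in best.values()}
    return retained


# ---------------------------------------------------------------------------
# drug-name normalization

_DOSE_SUFFIX = re.compile(
    r"[\s(]*\b\d+(\.\d+)?\s*(MG|MCG|G|ML|MG/ML|%)\b.*$", re.IGNORECASE
)


def normalize_drug_name(
    name: str, synonyms: Mapping[str, str] | None = None
) -> str:
    """Trim, uppercase, collapse whitespace, strip trailing dosage suffixes.

    ``synonyms`` maps normalized variants (brand names, salts) onto one
    canonical ingredient name; matching is exact after normalization.
    """
    s = re.sub(r"\s+", " ", str(name).strip().upper())
    s = _DOSE_SUFFIX.sub("", s).strip()
    if synonyms:
        s = synonyms.get(s, s)
    return s


# ---------------------------------------------------------------------------
# case assembly


def _to_float(value: str) -> float | None:
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


_AGE_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / (365.25 * 24.0),
    "": 1.0,
}


def _age_years(age: str, age_cod: str) -> float | None:
    v = _to_float(age)
    if v is None:
        return None
    factor = _AGE_TO_YEARS.get(str(age_cod).strip().upper())
    if factor is None:
        return None
    return v * factor


def assemble_cases(
    tables: RawTables,
    retained: set[str] | None = None,
    synonyms: Mapping[str, str] | None = None,
) -> list[CaseReport]:
    """Join the six tables into one :class:`CaseReport` per retained id.

    Drug rows join to THER via (primaryid, drug_seq == dsg_drug_seq) and to
    INDI via (primaryid, drug_seq == indi_drug_seq); reaction PTs collapse
    to a set; drug names are normalized.  Rows whose primaryid is not in
    DEMO are orphans: logged and dropped.
    """
    if retained is None:
        retained = deduplicate(tables.demo)
    demo = tables.demo[tables.demo["primaryid"].isin(retained)]
    demo_ids = set(demo["primaryid"])

    def _grouped(df: pd.DataFrame, label: str) -> dict[str, list]:
        orphans = (~df["primaryid"].isin(set(tables.demo["primaryid"]))).sum()
        if orphans:
            logger.warning("%s: dropped %d orphan rows", label, int(orphans))
        sub = df[df["primaryid"].isin(demo_ids)]
        groups: dict[str, list] = {}
        for row in sub.itertuples(index=False):
            groups.setdefault(row.primaryid, []).append(row)
        return groups

    drug_g = _grouped(tables.drug, "DRUG")
    reac_g = _grouped(tables.reac, "REAC")
    ther_g = _grouped(tables.ther, "THER")
    outc_g = _grouped(tables.outc, "OUTC")
    indi_g = _grouped(tables.indi, "INDI")

    cases: list[CaseReport] = []
    for row in demo.itertuples(index=False):
        pid = row.primaryid
        ther_by_seq = {
            str(t.dsg_drug_seq): parse_partial_date(t.start_dt)
            for t in ther_g.get(pid, [])
        }
        indi_by_seq = {
            str(i.indi_drug_seq): str(i.indi_pt).strip()
            for i in indi_g.get(pid, [])
            if str(i.indi_pt).strip()
        }
        drugs = tuple(
            DrugRecord(
                drug_seq=int(d.drug_seq),
                name=normalize_drug_name(d.drugname, synonyms),
                role_cod=str(d.role_cod).strip().upper(),
                therapy_start=ther_by_seq.get(str(d.drug_seq)),
                indication=indi_by_seq.get(str(d.drug_seq)),
            )
            for d in sorted(drug_g.get(pid, []), key=lambda d: int(d.drug_seq))
        )
        reactions = frozenset(
            str(r.pt).strip().upper() for r in reac_g.get(pid, []) if str(r.pt).strip()
        )
        outcomes = tuple(
            sorted({str(o.outc_cod).strip().upper() for o in outc_g.get(pid, [])})
        )
        sex = str(row.sex).strip().upper() or NOT_SPECIFIED
        country = str(row.occr_country).strip().upper() or NOT_SPECIFIED
        reporter = str(row.occp_cod).strip().upper() or NOT_SPECIFIED
        cases.append(
            CaseReport(
                primaryid=str(pid),
                caseid=str(row.caseid),
                fda_dt=parse_partial_date(row.fda_dt),
                event_dt=parse_partial_date(row.event_dt),
                sex=sex,
                age_years=_age_years(row.age, row.age_cod),
                weight_kg=_to_float(row.wt),
                country=country,
                reporter=reporter,
                outcomes=outcomes,
                drugs=drugs,
                reactions=reactions,
            )
        )
    cases.sort(key=lambda c: _primaryid_key(c.primaryid))
    return cases


def filter_primary_suspect(
    cases: Iterable[CaseReport], drug_name: str
) -> tuple[list[CaseReport], list[CaseReport]]:
    """Partition cases into (exposed, background) on PS role for the drug.

    A case carrying the drug only as concomitant/interacting stays in the
    background; the partition is exhaustive and disjoint.
    """
    exposed: list[CaseReport] = []
    background: list[CaseReport] = []
    for case in cases:
        (exposed if case.has_drug(drug_name, roles=("PS",)) else background).append(
            case
        )
    return exposed, background


# ---------------------------------------------------------------------------
# JSON-lines checkpointing


def _case_to_dict(case: CaseReport) -> dict:
    d = asdict(case)
    d["fda_dt"] = case.fda_dt.raw if case.fda_dt else None
    d["event_dt"] = case.event_dt.raw if case.event_dt else None
    d["reactions"] = sorted(case.reactions)
    d["drugs"] = [
        {
            **asdict(dr),
            "therapy_start": dr.therapy_start.raw if dr.therapy_start else None,
        }
        for dr in case.drugs
    ]
    return d


def cases_to_jsonl(cases: Iterable[CaseReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        for case in cases:
            fh.write(json.dumps(_case_to_dict(case), sort_keys=True) + "\n")


def cases_from_jsonl(path: str | Path) -> list[CaseReport]:
    cases = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            cases.append(
                CaseReport(
                    primaryid=d["primaryid"],
                    caseid=d["caseid"],
                    fda_dt=parse_partial_date(d["fda_dt"]),
                    event_dt=parse_partial_date(d["event_dt"]),
                    sex=d["sex"],
                    age_years=d["age_years"],
                    weight_kg=d["weight_kg"],
                    country=d["country"],
                    reporter=d["reporter"],
                    outcomes=tuple(d["outcomes"]),
                    drugs=tuple(
                        DrugRecord(
                            drug_seq=dr["drug_seq"],
                            name=dr["name"],
                            role_cod=dr["role_cod"],
                            therapy_start=parse_partial_date(dr["therapy_start"]),
                            indication=dr["indication"],
                        )
                        for dr in d["drugs"]
                    ),
                    reactions=frozenset(d["reactions"]),
                )
            )
    return cases
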