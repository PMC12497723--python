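"""Synthetic spontaneous-reporting-system generator with known ground truth.

Emits FAERS-shaped quarterly tables (DEMO/DRUG/REAC/THER/OUTC/INDI) in
which everything downstream analyses estimate is planted by construction:
drug–event associations of chosen strength, a Weibull onset-time
distribution, duplicate report shadows, and co-medication.  Defaults
mirror a cyclobenzaprine-like exposed cohort: ~5% of 50,000 reports carry
the target drug as primary suspect (an exposed-cohort size of ~2,500),
demographic margins follow the published report profile, and onset times
follow Weibull(shape 0.38, scale 46.9 days) with ~12% of reports carrying
usable timing.

Duplicates are always "older shadow copies" (strictly older FDA_DT, lower
PRIMARYID) so the deduplication rule's correct answer is knowable exactly.
Each case has exactly one primary-suspect drug; co-medications get role C.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import NOT_SPECIFIED, RawTables

__all__ = [
    "PlantedSignal",
    "SyntheticConfig",
    "default_pt_vocabulary",
    "generate",
    "ground_truth",
    "soc_mapping",
]

logger = logging.getLogger(__name__)

#: background primary-suspect / concomitant drugs (never the target)
DECOY_DRUGS = (
    "IBUPROFEN",
    "ACETAMINOPHEN",
    "NAPROXEN",
    "OMEPRAZOLE",
    "LISINOPRIL",
    "METFORMIN",
    "ATORVASTATIN",
    "SERTRALINE",
    "GABAPENTIN",
    "TRAMADOL",
    "AMLODIPINE",
    "LEVOTHYROXINE",
    "PREDNISONE",
    "DULOXETINE",
    "ALPRAZOLAM",
)

INDICATION_PTS = (
    "MUSCLE SPASMS",
    "BACK PAIN",
    "PAIN",
    "SUICIDE ATTEMPT",
    "MUSCLE RELAXANT THERAPY",
)

_AGE_BANDS = {"<18": (1, 17), "18-65": (18, 65), "65-85": (66, 85), ">85": (86, 100)}
_WT_BANDS = {"<50": (30, 49), "50-100": (50, 100), ">100": (101, 150)}


def default_pt_vocabulary(n_pts: int = 200) -> tuple[tuple[str, float], ...]:
    """A skewed PT frequency spectrum: baselines geometric 0.03 → 0.0005."""
    baselines = np.geomspace(0.03, 0.0005, n_pts)
    return tuple((f"PT_{i + 1:04d}", float(b)) for i, b in enumerate(baselines))


@dataclass(frozen=True)
class PlantedSignal:
    """A drug–event association of known strength.

    ``target_rr`` multiplies the PT's baseline probability in exposed
    cases (clipped at 1).  ``sex`` restricts the excess risk to one sex
    code ("M"/"F"), for subgroup-recovery experiments.
    """

    pt: str
    target_rr: float
    sex: str | None = None


@dataclass(frozen=True)
class SyntheticConfig:
    n_cases: int = 50_000
    target_drug: str = "CYCLOBENZAPRINE"
    p_exposed: float = 0.05
    pt_vocabulary: tuple[tuple[str, float], ...] = field(
        default_factory=default_pt_vocabulary
    )
    planted_signals: tuple[PlantedSignal, ...] = ()
    sex_probs: tuple[tuple[str, float], ...] = (
        ("F", 0.538),
        ("M", 0.313),
        (NOT_SPECIFIED, 0.149),
    )
    age_probs: tuple[tuple[str, float], ...] = (
        ("<18", 0.031),
        ("18-65", 0.525),
        ("65-85", 0.099),
        (">85", 0.009),
        (NOT_SPECIFIED, 0.336),
    )
    weight_probs: tuple[tuple[str, float], ...] = (
        ("<50", 0.009),
        ("50-100", 0.212),
        (">100", 0.040),
        (NOT_SPECIFIED, 0.739),
    )
    country_probs: tuple[tuple[str, float], ...] = (
        ("US", 0.854),
        ("CA", 0.093),
        ("OTHER", 0.053),
    )
    reporter_probs: tuple[tuple[str, float], ...] = (
        ("CN", 0.277),
        ("MD", 0.276),
        ("OT", 0.158),
        ("PH", 0.116),
        ("HP", 0.095),
        ("LW", 0.002),
        (NOT_SPECIFIED, 0.076),
    )
    outcome_probs: tuple[tuple[str, float], ...] = (
        ("DE", 0.340),
        ("OT", 0.174),
        ("HO", 0.149),
        ("LT", 0.045),
        ("DS", 0.017),
        ("RI", 0.007),
        ("CA", 0.005),
        (NOT_SPECIFIED, 0.263),
    )
    onset_shape: float = 0.38  # Weibull beta (ground truth)
    onset_scale: float = 46.9  # Weibull alpha, days
    p_comedication: float = 0.6
    p_duplicate: float = 0.05
    p_onset_recorded: float = 0.12
    p_indication_recorded: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_exposed", "p_comedication", "p_duplicate",
                     "p_onset_recorded", "p_indication_recorded"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.onset_shape <= 0 or self.onset_scale <= 0:
            raise ValueError("Weibull onset parameters must be positive")
        for name in ("sex_probs", "age_probs", "weight_probs", "country_probs",
                     "reporter_probs", "outcome_probs"):
            probs = [p for _, p in getattr(self, name)]
            if any(p < 0 or p > 1 for p in probs):
                raise ValueError(f"{name}: probability outside [0, 1]")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name}: probabilities sum to {sum(probs)}, not 1")
        for pt, b in self.pt_vocabulary:
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"baseline probability for {pt} outside [0, 1]")
        vocab = {pt for pt, _ in self.pt_vocabulary}
        for sig in self.planted_signals:
            if sig.target_rr < 1.0:
                raise ValueError(f"target_rr for {sig.pt} must be >= 1")
            if sig.pt not in vocab:
                raise ValueError(f"planted PT {sig.pt} not in vocabulary")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def ground_truth(config: SyntheticConfig) -> dict[str, float]:
    """True relative risk per PT: effective (post-clipping) RR, 1 if unplanted."""
    baselines = dict(config.pt_vocabulary)
    truth = {pt: 1.0 for pt in baselines}
    for sig in config.planted_signals:
        b = baselines[sig.pt]
        truth[sig.pt] = min(1.0, b * sig.target_rr) / b if b > 0 else 1.0
    return truth


def soc_mapping(config: SyntheticConfig, n_socs: int = 26) -> dict[str, str]:
    """A deterministic PT→SOC assignment for SOC-level analyses (round-robin)."""
    return {
        pt: f"SOC_{(i % n_socs) + 1:02d}"
        for i, (pt, _) in enumerate(config.pt_vocabulary)
    }


def _draw_categorical(rng, probs: tuple[tuple[str, float], ...], n: int) -> np.ndarray:
    cats = [c for c, _ in probs]
    p = np.asarray([q for _, q in probs], dtype=float)
    idx = rng.choice(len(cats), size=n, p=p / p.sum())
    return np.asarray(cats, dtype=object)[idx]


def _ord_to_str(ordinals: np.ndarray) -> list[str]:
    return [
        datetime.date.fromordinal(int(o)).strftime("%Y%m%d") for o in ordinals
    ]


def generate(config: SyntheticConfig) -> RawTables:
    """Draw one synthetic report database; byte-identical per seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    pts = [pt for pt, _ in config.pt_vocabulary]
    baselines = np.asarray([b for _, b in config.pt_vocabulary], dtype=float)
    n_pts = len(pts)

    exposed = rng.random(n) < config.p_exposed
    sex = _draw_categorical(rng, config.sex_probs, n)

    # reaction incidence, one Bernoulli column per PT
    planted = {pt: sig for sig in config.planted_signals for pt in [sig.pt]}
    incidence = np.zeros((n, n_pts), dtype=bool)
    for j, pt in enumerate(pts):
        p = np.full(n, baselines[j])
        sig = planted.get(pt)
        if sig is not None:
            eff = baselines[j] * sig.target_rr
            if eff > 1.0:
                logger.warning(
                    "planted probability for %s clips at 1 (baseline %.4g x RR %.3g)",
                    pt, baselines[j], sig.target_rr,
                )
                eff = 1.0
            mask = exposed if sig.sex is None else exposed & (sex == sig.sex)
            p[mask] = eff
        incidence[:, j] = rng.random(n) < p

    # every case reports at least one PT
    empty = ~incidence.any(axis=1)
    if empty.any():
        fill = rng.choice(n_pts, size=int(empty.sum()), p=baselines / baselines.sum())
        incidence[np.flatnonzero(empty), fill] = True

    age_band = _draw_categorical(rng, config.age_probs, n)
    age = np.full(n, "", dtype=object)
    for band, (lo, hi) in _AGE_BANDS.items():
        m = age_band == band
        age[m] = [str(v) for v in rng.integers(lo, hi + 1, size=int(m.sum()))]
    wt_band = _draw_categorical(rng, config.weight_probs, n)
    wt = np.full(n, "", dtype=object)
    for band, (lo, hi) in _WT_BANDS.items():
        m = wt_band == band
        wt[m] = [str(v) for v in rng.integers(lo, hi + 1, size=int(m.sum()))]

    country = _draw_categorical(rng, config.country_probs, n)
    reporter = _draw_categorical(rng, config.reporter_probs, n)
    outcome = _draw_categorical(rng, config.outcome_probs, n)

    # therapy start, Weibull onset (ceil to whole days, min 1), report receipt
    start_lo = datetime.date(2004, 1, 1).toordinal()
    start_hi = datetime.date(2023, 12, 31).toordinal()
    start_ord = rng.integers(start_lo, start_hi + 1, size=n)
    onset = np.maximum(
        np.ceil(config.onset_scale * rng.weibull(config.onset_shape, size=n)), 1.0
    ).astype(int)
    event_ord = start_ord + onset
    fda_ord = event_ord + rng.integers(0, 61, size=n)
    onset_recorded = rng.random(n) < config.p_onset_recorded

    ps_drug = np.where(
        exposed,
        config.target_drug,
        rng.choice(np.asarray(DECOY_DRUGS, dtype=object), size=n),
    )
    has_comed = rng.random(n) < config.p_comedication
    n_comed = np.where(has_comed, rng.integers(1, 4, size=n), 0)
    has_indi = rng.random(n) < config.p_indication_recorded
    indi_pt = _draw_categorical(
        rng, tuple((p, 1 / len(INDICATION_PTS)) for p in INDICATION_PTS), n
    )
    dup = rng.random(n) < config.p_duplicate
    dup_age = rng.integers(1, 301, size=n)  # shadow FDA_DT this many days older

    sex_str = np.where(sex == NOT_SPECIFIED, "", sex)
    country_str = np.where(country == NOT_SPECIFIED, "", country)
    reporter_str = np.where(reporter == NOT_SPECIFIED, "", reporter)
    fda_str = _ord_to_str(fda_ord)
    event_str = _ord_to_str(event_ord)
    start_str = _ord_to_str(start_ord)

    demo_rows, drug_rows, reac_rows = [], [], []
    ther_rows, outc_rows, indi_rows = [], [], []
    for i in range(n):
        pid = str((i + 1) * 10 + 5)
        caseid = str(i + 1)
        ev = event_str[i] if onset_recorded[i] else ""
        demo_rows.append(
            (pid, caseid, fda_str[i], ev, sex_str[i], age[i],
             "YR" if age[i] else "", wt[i], "KG" if wt[i] else "",
             country_str[i], reporter_str[i])
        )
        case_drugs = [(1, ps_drug[i], "PS")]
        if n_comed[i]:
            comeds = rng.choice(
                np.asarray(DECOY_DRUGS, dtype=object), size=int(n_comed[i]),
                replace=False,
            )
            case_drugs += [(seq + 2, name, "C") for seq, name in enumerate(comeds)]
        for seq, name, role in case_drugs:
            drug_rows.append((pid, str(seq), name, role))
        case_pts = [pts[j] for j in np.flatnonzero(incidence[i])]
        for pt in case_pts:
            reac_rows.append((pid, pt))
        if onset_recorded[i]:
            ther_rows.append((pid, "1", start_str[i]))
        if outcome[i] != NOT_SPECIFIED:
            outc_rows.append((pid, outcome[i]))
        if has_indi[i]:
            indi_rows.append((pid, "1", indi_pt[i]))
        if dup[i]:
            shadow_pid = str((i + 1) * 10 + 1)
            shadow_fda = datetime.date.fromordinal(
                int(fda_ord[i] - dup_age[i])
            ).strftime("%Y%m%d")
            demo_rows.append(
                (shadow_pid, caseid, shadow_fda, ev, sex_str[i], age[i],
                 "YR" if age[i] else "", wt[i], "KG" if wt[i] else "",
                 country_str[i], reporter_str[i])
            )
            for seq, name, role in case_drugs:
                drug_rows.append((shadow_pid, str(seq), name, role))
            for pt in case_pts:
                reac_rows.append((shadow_pid, pt))

    demo = pd.DataFrame(
        demo_rows,
        columns=["primaryid", "caseid", "fda_dt", "event_dt", "sex", "age",
                 "age_cod", "wt", "wt_cod", "occr_country", "occp_cod"],
    )
    drug = pd.DataFrame(
        drug_rows, columns=["primaryid", "drug_seq", "drugname", "role_cod"]
    )
    reac = pd.DataFrame(reac_rows, columns=["primaryid", "pt"])
    ther = pd.DataFrame(ther_rows, columns=["primaryid", "dsg_drug_seq", "start_dt"])
    outc = pd.DataFrame(outc_rows, columns=["primaryid", "outc_cod"])
    indi = pd.DataFrame(indi_rows, columns=["primaryid", "indi_drug_seq", "indi_pt"])
    return RawTables(demo=demo, drug=drug, reac=reac, ther=ther, outc=outc, indi=indi)


def expected_retained_ids(tables: RawTables) -> set[str]:
    """Ground-truth deduplication answer: the non-shadow id per caseid.

    Generator primaryids end in 5; shadow duplicates end in 1 and carry a
    strictly older FDA_DT, so the correct retained set is exactly the ids
    ending in 5.
    """
    return {pid for pid in tables.demo["primaryid"] if pid.endswith("5")}
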