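"""Transition-probability estimation from longitudinal claims-like records.

The estimation pipeline mirrors how national claims data are turned into the
per-cycle probabilities of the Markov model:

1. Case classification at an index year. A person whose first diabetes claim
   falls in the index year, with no diabetes claims during the washout years
   (the three full calendar years before the index year), is an *incident*
   case with the claim date as index date. Every other diabetic is an
   *existing prevalent* case indexed at January 1 of the index year. A person
   whose complication history starts with an E-class complication code at (or
   before) diagnosis already has complicated diabetes and is reclassified as
   an existing prevalent case with complications.
2. Person-time. Each person contributes one spell per occupied state, from
   the state's index date to the first exit event or administrative censoring,
   measured in person-days and converted at 365 days/year. Death dates are
   known to the month only and resolve to the last day of the month.
3. Rates to probabilities. Events divided by person-years give a rate r,
   converted to a per-cycle probability via p = 1 - exp(-r t). Unstable
   death-transition estimates are pooled across annual complication cohorts
   (events and person-years summed before dividing) and smoothed by merging
   neighbouring age groups until each pool holds at least ``min_events``
   events.
4. Mortality substitution. Other-cause death probabilities below the general
   population's value for the same sex and age group are replaced by the
   general value, and a zero probability for either death cause in the 30-34
   group is likewise replaced.

Complication-timing assumption: complication diagnoses of the over-60 code
class that predate the diabetes index ("reverse transitions": a stroke or
ischemic heart disease history before the diabetes diagnosis) have no
observable diabetes-to-complication duration. The ``duration_days`` setting
(0 / 180 / 365) places their complication index that many days after the
diabetes index, which shifts person-time between the diabetes and
complication states and is the lever of the published sensitivity analysis.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .ages import AGE_GROUP_LABELS
from .parameters import IncidenceTable, RunConfig, TransitionTable
from .states import TRANSITION_COLUMNS

DAYS_PER_YEAR = 365.0

EVENT_CLASSES = (
    "t2dm_dx",
    "complication_ecode",
    "complication_over60",
    "death_dm",
    "death_other",
    "enrollment",
)


class ClaimsError(ValueError):
    """Invalid claims input or impossible derivation."""


@dataclass(frozen=True)
class ClaimEvent:
    date: dt.date
    event_class: str
    precision: str = "day"  # death events carry "month"

    def __post_init__(self) -> None:
        cls = self.event_class.lower()
        if cls not in EVENT_CLASSES:
            raise ClaimsError(f"unknown event class {self.event_class!r}")
        object.__setattr__(self, "event_class", cls)
        if self.precision not in ("day", "month"):
            raise ClaimsError(f"unknown date precision {self.precision!r}")


@dataclass
class ClaimRecord:
    """One person's claims history (events date-ordered, at most one death)."""

    person_id: Union[int, str]
    sex: str
    birth_date: dt.date
    events: list[ClaimEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.date)
        deaths = [e for e in self.events if e.event_class.startswith("death")]
        if len(deaths) > 1:
            raise ClaimsError(f"person {self.person_id}: more than one death event")


@dataclass(frozen=True)
class CaseStatus:
    person_id: Union[int, str]
    status: str  # "incident" | "existing_prevalent"
    index_date: dt.date
    with_complications: bool = False


@dataclass(frozen=True)
class RateEstimate:
    """An event count over person-time, as rate and per-cycle probability."""

    transition: str
    events: float
    person_years: float
    rate: float
    probability: float
    cycle_length: float = 1.0


def resolve_death_date(date: dt.date, precision: str = "day") -> dt.date:
    """Month-precision death dates resolve to the last day of the month."""
    if precision == "month":
        last = calendar.monthrange(date.year, date.month)[1]
        return dt.date(date.year, date.month, last)
    return date


def rate_to_probability(r: float, t: float = 1.0) -> float:
    """p = 1 - exp(-r t) for a constant hazard r over duration t."""
    if r < 0:
        raise ClaimsError(f"negative rate: {r}")
    if t <= 0:
        raise ClaimsError(f"duration must be positive, got {t}")
    return float(-np.expm1(-r * t))


def probability_to_rate(p: float, t: float = 1.0) -> float:
    """Inverse of :func:`rate_to_probability`: r = -ln(1 - p) / t."""
    if not 0.0 <= p < 1.0:
        raise ClaimsError(f"probability must be in [0, 1), got {p}")
    return float(-np.log1p(-p) / t)


def estimate_rate(
    events: float, person_years: float, cycle_length: float = 1.0, transition: str = ""
) -> RateEstimate:
    if person_years <= 0:
        raise ClaimsError(f"no exposure: person_years={person_years}")
    r = events / person_years
    return RateEstimate(
        transition=transition,
        events=float(events),
        person_years=float(person_years),
        rate=float(r),
        probability=rate_to_probability(r, cycle_length),
        cycle_length=cycle_length,
    )


def pool_cohorts(
    annual_estimates: Sequence[tuple[float, float]],
    cycle_length: float = 1.0,
    transition: str = "",
) -> RateEstimate:
    """Sum events and person-years over annual cohorts, then divide.

    Pooling precedes the rate computation; probabilities are never averaged.
    """
    if len(annual_estimates) == 0:
        raise ClaimsError("nothing to pool")
    events = float(sum(e for e, _ in annual_estimates))
    py = float(sum(p for _, p in annual_estimates))
    return estimate_rate(events, py, cycle_length, transition)


def smooth_by_neighbor(
    estimates: Sequence[RateEstimate], min_events: float
) -> tuple[list[RateEstimate], list[tuple[int, ...]]]:
    """Merge age-neighbouring estimates until every pool has >= min_events.

    ``estimates`` must be in age order. A deficient group merges with its
    adjacent older group (the only deterministic choice when both neighbours
    are equally near), repeatedly, and every constituent of a merged pool
    reports the pooled estimate. If the grand total is still below
    ``min_events`` all groups share one pool (a warning condition, not an
    error). Returns the smoothed list and the merged index clusters.
    """
    clusters: list[list[int]] = [[i] for i in range(len(estimates))]

    def cluster_events(c: list[int]) -> float:
        return sum(estimates[i].events for i in c)

    while True:
        deficient = next(
            (k for k, c in enumerate(clusters) if cluster_events(c) < min_events), None
        )
        if deficient is None or len(clusters) == 1:
            break
        partner = deficient + 1 if deficient + 1 < len(clusters) else deficient - 1
        lo, hi = sorted((deficient, partner))
        clusters[lo] = clusters[lo] + clusters[hi]
        del clusters[hi]

    out: list[Optional[RateEstimate]] = [None] * len(estimates)
    merged: list[tuple[int, ...]] = []
    for c in clusters:
        events = cluster_events(c)
        py = sum(estimates[i].person_years for i in c)
        if py > 0:
            pooled = estimate_rate(
                events, py, estimates[c[0]].cycle_length, estimates[c[0]].transition
            )
        else:
            pooled = RateEstimate(
                estimates[c[0]].transition, 0.0, 0.0, 0.0, 0.0, estimates[c[0]].cycle_length
            )
        if len(c) > 1:
            merged.append(tuple(c))
        for i in c:
            out[i] = pooled
    return list(out), merged  # type: ignore[arg-type]


def substitute_mortality(
    modeled: float, general: float, age_group: str, cause: str = "other"
) -> float:
    """Floor modelled death probabilities with general-population mortality.

    Other-cause death probabilities are never allowed below the general
    population's value (max of the two). In the 30-34 group, a modelled
    probability of exactly zero for either death cause is replaced by the
    general probability.
    """
    if not (0.0 <= modeled <= 1.0 and 0.0 <= general <= 1.0):
        raise ClaimsError("probabilities must be in [0, 1]")
    if cause == "other":
        return max(modeled, general)
    if age_group == "30-34" and modeled == 0.0:
        return general
    return modeled


# ---------------------------------------------------------------------------
# record containers <-> event frame

FRAME_COLUMNS = ("person_id", "sex", "birth_date", "event_date", "event_class", "date_precision")


def records_to_frame(records: Iterable[ClaimRecord]) -> pd.DataFrame:
    """Flatten ClaimRecords to one event per row.

    Every person additionally carries an ``enrollment`` row (their earliest
    observation date is unknown for object records, so the birth-based
    plumbing uses the events alone; persons without events appear only via
    their enrollment row so population denominators remain correct).
    """
    rows = []
    for rec in records:
        rows.append((rec.person_id, rec.sex, rec.birth_date, None, "enrollment", "day"))
        for ev in rec.events:
            rows.append((rec.person_id, rec.sex, rec.birth_date, ev.date, ev.event_class, ev.precision))
    df = pd.DataFrame(rows, columns=list(FRAME_COLUMNS))
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["event_date"] = pd.to_datetime(df["event_date"])
    return df


def load_records(path) -> pd.DataFrame:
    """Read an event-per-row delimited text file of claims records."""
    df = pd.read_csv(path, comment="#")
    missing = set(FRAME_COLUMNS) - set(df.columns)
    if missing:
        raise ClaimsError(f"records file missing columns {sorted(missing)}")
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["event_date"] = pd.to_datetime(df["event_date"], errors="coerce")
    df["event_class"] = df["event_class"].str.lower()
    return df


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


# ---------------------------------------------------------------------------
# per-person summary and classification

def _resolve_dates(df: pd.DataFrame) -> pd.Series:
    """Event dates with month-precision deaths pushed to month end."""
    dates = df["event_date"].copy()
    monthly = df["date_precision"].eq("month") & dates.notna()
    if monthly.any():
        dates.loc[monthly] = dates.loc[monthly] + pd.offsets.MonthEnd(0)
    return dates


def summarise_persons(frame: pd.DataFrame) -> pd.DataFrame:
    """One row per person: first diagnosis, complications, death, washout use.

    Over-60-class complication events in persons younger than 60 at the event
    date do not count as complications.
    """
    df = frame.copy()
    df["resolved_date"] = _resolve_dates(df)
    age_at_event = (df["resolved_date"] - df["birth_date"]).dt.days / 365.25
    is_comp_e = df["event_class"].eq("complication_ecode")
    is_comp_o = df["event_class"].eq("complication_over60") & (age_at_event >= 60)
    is_dx = df["event_class"].eq("t2dm_dx")
    is_death = df["event_class"].isin(("death_dm", "death_other"))

    persons = df.groupby("person_id", sort=False).agg(
        sex=("sex", "first"), birth_date=("birth_date", "first")
    )
    for name, mask in (
        ("first_dx", is_dx),
        ("first_comp_e", is_comp_e),
        ("first_comp_o", is_comp_o),
    ):
        persons[name] = df.loc[mask].groupby("person_id")["resolved_date"].min()
    deaths = df.loc[is_death].set_index("person_id")
    persons["death_date"] = deaths["resolved_date"]
    persons["death_cause"] = deaths["event_class"].map(
        {"death_dm": "dthdm", "death_other": "dthoth"}
    )
    persons["dx_dates_count"] = is_dx.groupby(df["person_id"]).sum()
    return persons


def classify_cases(
    records,
    index_year: int,
    washout_years: int = 3,
    window_start: Optional[dt.date] = None,
) -> list[CaseStatus]:
    """Assign incident / existing-prevalent status at the index year.

    ``window_start`` (when known) must reach back at least ``washout_years``
    full calendar years before the index year, otherwise the washout cannot
    be evaluated and the history is insufficient.
    """
    frame = _as_frame(records)
    statuses_df = classify_frame(frame, index_year, washout_years, window_start)
    return [
        CaseStatus(
            person_id=pid,
            status=row["status"],
            index_date=row["index_date"].date(),
            with_complications=bool(row["with_complications"]),
        )
        for pid, row in statuses_df.iterrows()
    ]


def classify_frame(
    frame: pd.DataFrame,
    index_year: int,
    washout_years: int = 3,
    window_start: Optional[dt.date] = None,
) -> pd.DataFrame:
    washout_start = pd.Timestamp(dt.date(index_year - washout_years, 1, 1))
    jan1 = pd.Timestamp(dt.date(index_year, 1, 1))
    dec31 = pd.Timestamp(dt.date(index_year, 12, 31))
    if window_start is not None and pd.Timestamp(window_start) > washout_start:
        raise ClaimsError(
            f"insufficient history: records start {window_start}, washout needs {washout_start.date()}"
        )

    persons = summarise_persons(frame)
    df = frame.copy()
    df["resolved_date"] = _resolve_dates(df)
    is_dx = df["event_class"].eq("t2dm_dx")
    in_washout = is_dx & (df["resolved_date"] >= washout_start) & (df["resolved_date"] < jan1)
    persons["washout_use"] = in_washout.groupby(df["person_id"]).any().reindex(persons.index, fill_value=False)
    dx_in_index = is_dx & (df["resolved_date"] >= jan1) & (df["resolved_date"] <= dec31)
    persons["first_dx_index_year"] = (
        df.loc[dx_in_index].groupby("person_id")["resolved_date"].min().reindex(persons.index)
    )

    diabetic = persons["first_dx"].notna() & (persons["first_dx"] <= dec31)
    out = persons.loc[diabetic].copy()
    incident = out["first_dx_index_year"].notna() & ~out["washout_use"]
    # E-class complication codes imply diabetes with complications: a case
    # whose complication history starts with one at or before the diabetes
    # index already has complicated (prevalent) diabetes.
    ecode_at_dx = incident & out["first_comp_e"].notna() & (
        out["first_comp_e"] <= out["first_dx_index_year"]
    )
    incident &= ~ecode_at_dx
    out["status"] = np.where(incident, "incident", "existing_prevalent")
    out["index_date"] = np.where(incident, out["first_dx_index_year"], jan1)
    out["index_date"] = pd.to_datetime(out["index_date"])
    first_comp = out[["first_comp_e", "first_comp_o"]].min(axis=1)
    out["with_complications"] = (~incident) & (
        (first_comp < out["index_date"]) | ecode_at_dx
    )
    out["reverse_case"] = incident & out["first_comp_o"].notna() & (
        out["first_comp_o"] < out["index_date"]
    )
    return out


# ---------------------------------------------------------------------------
# person-time

@dataclass(frozen=True)
class Spell:
    state: str  # Di | Dep | Ci | Cep
    start: dt.date
    end: dt.date
    terminal: Optional[str]  # ci | dthdm | dthoth | None (censored)

    @property
    def person_days(self) -> int:
        return (self.end - self.start).days

    @property
    def person_years(self) -> float:
        return self.person_days / DAYS_PER_YEAR


def _person_spells(
    status: str,
    with_complications: bool,
    reverse_case: bool,
    index_date: dt.date,
    first_comp: Optional[dt.date],
    death_date: Optional[dt.date],
    death_cause: Optional[str],
    window_end: dt.date,
    duration_days: int = 0,
) -> list[Spell]:
    spells: list[Spell] = []
    if death_date is not None and death_date < index_date:
        return spells  # not at risk at the index date
    censor = window_end if death_date is None else min(death_date, window_end)
    death_terminal = death_cause if death_date is not None and death_date <= window_end else None

    if status == "existing_prevalent" and with_complications:
        spells.append(Spell("Cep", index_date, censor, death_terminal))
        return spells

    if reverse_case:
        # the complication is diagnosed (before the diabetes index); the
        # assumption only places its index, capped at the end of follow-up,
        # so event counts are invariant and only person-time shifts
        comp_index = min(index_date + dt.timedelta(days=duration_days), censor)
    else:
        comp_index = first_comp if (first_comp is not None and first_comp >= index_date) else None
    src = "Di" if status == "incident" else "Dep"
    if comp_index is not None and comp_index <= censor:
        spells.append(Spell(src, index_date, comp_index, "ci"))
        spells.append(Spell("Ci", comp_index, censor, death_terminal))
    else:
        spells.append(Spell(src, index_date, censor, death_terminal))
    return spells


def compute_person_time(
    status: CaseStatus,
    record: ClaimRecord,
    window_end: dt.date,
    duration_days: int = 0,
) -> dict[str, Spell]:
    """Spells (state, start, end, terminal event) for one classified person.

    Person-days are exact date differences (month-precision death dates
    having been resolved to month end); person-years divide by 365.
    """
    comp = None
    death_date = None
    death_cause = None
    reverse = False
    first_dx = min((e.date for e in record.events if e.event_class == "t2dm_dx"), default=None)
    for ev in record.events:
        resolved = resolve_death_date(ev.date, ev.precision)
        if ev.event_class in ("death_dm", "death_other"):
            death_date = resolved
            death_cause = "dthdm" if ev.event_class == "death_dm" else "dthoth"
        elif ev.event_class == "complication_ecode":
            comp = min(comp, resolved) if comp else resolved
        elif ev.event_class == "complication_over60":
            age = (resolved - record.birth_date).days / 365.25
            if age >= 60:
                comp = min(comp, resolved) if comp else resolved
                if first_dx is not None and resolved < max(first_dx, status.index_date):
                    reverse = status.status == "incident"
    if comp is not None and comp < status.index_date and status.status == "incident":
        reverse = True
    spells = _person_spells(
        status.status,
        status.with_complications,
        reverse,
        status.index_date,
        comp,
        death_date,
        death_cause,
        window_end,
        duration_days,
    )
    out = {}
    for s in spells:
        if s.person_days < 0:
            raise ClaimsError(f"negative duration for person {record.person_id} in {s.state}")
        out[s.state] = s
    return out


# ---------------------------------------------------------------------------
# full derivation

def _age_group_index(start: pd.Series, birth: pd.Series) -> np.ndarray:
    age = np.floor((start - birth).dt.days / 365.25)
    idx = np.clip(((age - 30) // 5).astype(float), 0, 11)
    return idx.astype(int)


_SPELL_TRANSITIONS = {
    "Di": ("di_ci", "di_dthdm", "di_dthoth"),
    "Dep": ("dep_ci", "dep_dthdm", "dep_dthoth"),
    "Ci": ("ci_dthdm", "ci_dthoth"),
    "Cep": ("cep_dthdm", "cep_dthoth"),
}
_TERMINAL_TO_COLUMN = {
    ("Di", "ci"): "di_ci",
    ("Di", "dthdm"): "di_dthdm",
    ("Di", "dthoth"): "di_dthoth",
    ("Dep", "ci"): "dep_ci",
    ("Dep", "dthdm"): "dep_dthdm",
    ("Dep", "dthoth"): "dep_dthoth",
    ("Ci", "dthdm"): "ci_dthdm",
    ("Ci", "dthoth"): "ci_dthoth",
    ("Cep", "dthdm"): "cep_dthdm",
    ("Cep", "dthoth"): "cep_dthoth",
}

DEATH_COLUMNS = ("di_dthdm", "di_dthoth", "dep_dthdm", "dep_dthoth",
                 "ci_dthdm", "ci_dthoth", "cep_dthdm", "cep_dthoth")


def _spell_frame(classified: pd.DataFrame, window_end: pd.Timestamp, duration_days: int) -> pd.DataFrame:
    """Vectorised spell construction for all classified persons."""
    p = classified.copy()
    p = p[p["death_date"].isna() | (p["death_date"] >= p["index_date"])]
    censor = p["death_date"].fillna(window_end).clip(upper=window_end)
    death_terminal = p["death_cause"].where(p["death_date"].notna() & (p["death_date"] <= window_end))

    first_comp = p[["first_comp_e", "first_comp_o"]].min(axis=1)
    comp_index = first_comp.where(first_comp >= p["index_date"])
    rev = p["reverse_case"].fillna(False).astype(bool)
    # reverse cases: complication index assumed duration_days after the
    # diabetes index, capped at censoring (event counts stay invariant)
    comp_index.loc[rev] = np.minimum(
        p.loc[rev, "index_date"] + pd.Timedelta(days=duration_days), censor[rev]
    )
    has_comp = comp_index.notna() & (comp_index <= censor)

    cep = (p["status"] == "existing_prevalent") & p["with_complications"]
    src_state = np.where(cep, "Cep", np.where(p["status"] == "incident", "Di", "Dep"))

    spells = []
    # source-state spell
    end = censor.where(cep | ~has_comp, comp_index)
    terminal = death_terminal.where(cep | ~has_comp, "ci")
    spells.append(pd.DataFrame({
        "person_id": p.index, "sex": p["sex"].values, "birth_date": p["birth_date"].values,
        "state": src_state, "start": p["index_date"].values, "end": end.values,
        "terminal": terminal.values,
    }))
    # complication spell for those who transitioned
    q = p[has_comp & ~cep]
    if len(q):
        spells.append(pd.DataFrame({
            "person_id": q.index, "sex": q["sex"].values, "birth_date": q["birth_date"].values,
            "state": "Ci", "start": comp_index[has_comp & ~cep].values, "end": censor[has_comp & ~cep].values,
            "terminal": death_terminal[has_comp & ~cep].values,
        }))
    out = pd.concat(spells, ignore_index=True)
    out["days"] = (out["end"] - out["start"]).dt.days
    if (out["days"] < 0).any():
        raise ClaimsError("negative duration in spell construction")
    out["age_idx"] = _age_group_index(out["start"], out["birth_date"])
    return out


def build_transition_table(
    records,
    index_year: int,
    config: RunConfig,
    window_end: Optional[dt.date] = None,
    general_mortality: Optional[Mapping[tuple[str, str], float]] = None,
    return_report: bool = False,
):
    """Estimate the full TransitionTable from claims-like records.

    ``window_end`` censors follow-up (default: December 31 of the index
    year); keep it within ``config.tunnel_length`` years of the index so
    incident-state exposure stays inside the incident tunnel.
    ``general_mortality`` maps (sex, age_group) to the general-population
    annual death probability used for the substitution rule.
    """
    frame = _as_frame(records)
    if not len(frame):
        raise ClaimsError("no cases: empty record set")
    classified = classify_frame(frame, index_year, config.washout_years)
    if not len(classified):
        raise ClaimsError("no cases: no diabetic persons at the index year")
    if window_end is None:
        window_end = dt.date(index_year, 12, 31)
    spells = _spell_frame(classified, pd.Timestamp(window_end), config.duration_days)

    warnings: list[str] = []
    sexes = sorted(spells["sex"].unique())
    cells: dict[tuple[str, str], dict[str, float]] = {}
    for sex in sexes:
        sub = spells[spells["sex"] == sex]
        for gi, glabel in enumerate(AGE_GROUP_LABELS):
            cell = sub[sub["age_idx"] == gi]
            probs: dict[str, float] = {}
            for state, cols in _SPELL_TRANSITIONS.items():
                st = cell[cell["state"] == state]
                py = float(st["days"].sum()) / DAYS_PER_YEAR
                for col in cols:
                    terminal = col.split("_", 1)[1] if not col.endswith("ci") else "ci"
                    n_events = float((st["terminal"] == terminal).sum())
                    probs[col] = (n_events, py)
            cells[(sex, glabel)] = probs

    # pool complication-cohort death estimates across complication entry
    # years (events and person-time summed), then convert; for the other
    # transitions the cell totals are already the pooled sums.
    rows = {}
    exposure: dict[tuple[str, str], dict[str, float]] = {}
    for sex in sexes:
        per_col: dict[str, list[RateEstimate]] = {}
        for col in TRANSITION_COLUMNS:
            ests = []
            for glabel in AGE_GROUP_LABELS:
                n_events, py = cells[(sex, glabel)][col]
                if py > 0:
                    ests.append(estimate_rate(n_events, py, config.cycle_length, col))
                else:
                    ests.append(RateEstimate(col, 0.0, 0.0, 0.0, 0.0, config.cycle_length))
            per_col[col] = ests
        # smoothing: unstable death transitions only
        for col in DEATH_COLUMNS:
            smoothed, merged = smooth_by_neighbor(per_col[col], config.min_events)
            per_col[col] = smoothed
            for c in merged:
                labels = [AGE_GROUP_LABELS[i] for i in c]
                warnings.append(f"smoothing merge: {sex} {col} groups {labels}")
        for gi, glabel in enumerate(AGE_GROUP_LABELS):
            rows[(sex, glabel)] = {col: per_col[col][gi].probability for col in TRANSITION_COLUMNS}
            exposure[(sex, glabel)] = {
                col: per_col[col][gi].person_years for col in TRANSITION_COLUMNS
            }

    n_subst = 0
    if general_mortality is not None:
        for (sex, glabel), row in rows.items():
            for col in DEATH_COLUMNS:
                cause = "dm" if col.endswith("dthdm") else "other"
                g = float(general_mortality[(sex, glabel)])
                new = substitute_mortality(row[col], g, glabel, cause)
                if new != row[col]:
                    n_subst += 1
                    warnings.append(f"mortality substitution: {sex} {glabel} {col} {row[col]:.6g} -> {new:.6g}")
                    row[col] = new

    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["sex", "age_group"])
    table = TransitionTable(df)
    if return_report:
        exp_df = pd.DataFrame.from_dict(exposure, orient="index")
        exp_df.index = pd.MultiIndex.from_tuples(exp_df.index, names=["sex", "age_group"])
        return table, {"warnings": warnings, "n_substitutions": n_subst,
                       "n_persons": int(len(classified)), "n_spells": int(len(spells)),
                       "exposure": exp_df.sort_index()}
    return table


def derive_incidence(records, index_year: int, washout_years: int = 3) -> IncidenceTable:
    """Incident counts and rates per (sex, age group) at the index year.

    The denominator for the rate is every observed person alive on January 1
    of the index year, grouped by age on that day.
    """
    frame = _as_frame(records)
    persons = summarise_persons(frame)
    jan1 = pd.Timestamp(dt.date(index_year, 1, 1))
    alive = persons["death_date"].isna() | (persons["death_date"] >= jan1)
    base = persons[alive].copy()
    age_jan1 = (jan1 - base["birth_date"]).dt.days / 365.25
    base = base[age_jan1 >= 30]
    base["age_idx"] = _age_group_index(pd.Series(jan1, index=base.index), base["birth_date"])

    classified = classify_frame(frame, index_year, washout_years)
    inc = classified[classified["status"] == "incident"].copy()
    inc["age_idx"] = _age_group_index(inc["index_date"], inc["birth_date"])

    rows = []
    for sex in sorted(base["sex"].unique()):
        for gi, glabel in enumerate(AGE_GROUP_LABELS):
            n_pop = int(((base["sex"] == sex) & (base["age_idx"] == gi)).sum())
            n_ic = int(((inc["sex"] == sex) & (inc["age_idx"] == gi)).sum())
            ir = n_ic / n_pop * 1000.0 if n_pop else 0.0
            rows.append({"sex": sex, "age_group": glabel, "ic": n_ic, "ir": ir})
    df = pd.DataFrame(rows).set_index(["sex", "age_group"])
    return IncidenceTable(df)
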