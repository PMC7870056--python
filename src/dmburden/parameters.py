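"""Model inputs: transition tables, incidence, disability weights, life tables.

All tabular inputs are plain delimited text files read into pandas; loaders
validate the domain invariants (probability bounds, exit-probability
conservation, complete sex x age coverage, gap-free life tables) and raise
informative errors naming the offending cell.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .ages import AGE_GROUP_LABELS, AgeGroup, group_for_age, group_from_label
from .states import EXIT_COLUMNS, TRANSITION_COLUMNS, StateId

SEXES = ("male", "female")


class ParameterError(ValueError):
    """Invalid or incomplete model input."""


class IncompleteTableError(ParameterError):
    """A (sex, age group) cell required by the model is missing."""


class InvalidProbabilityError(ParameterError):
    """A probability is outside [0, 1] or a state's exits sum beyond 1."""


class LifeTableGapError(ParameterError):
    """The life table does not cover an age reachable in the simulation."""


def _normalise_sex(sex: str) -> str:
    s = str(sex).strip().lower()
    if s in ("m", "male"):
        return "male"
    if s in ("f", "female"):
        return "female"
    raise ParameterError(f"unknown sex {sex!r}")


class TransitionTable:
    """Per-cycle transition probabilities for each (sex, age group).

    Wraps a DataFrame indexed by (sex, age_group label) with the ten
    probability columns of :data:`dmburden.states.TRANSITION_COLUMNS`. For
    every source state the listed exit probabilities must sum to at most 1;
    the residual is the probability of remaining (or, in a tunnel state,
    advancing along the tunnel).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if not isinstance(df.index, pd.MultiIndex):
            raise ParameterError("transition table needs a (sex, age_group) index")
        df.index = df.index.set_names(["sex", "age_group"])
        missing_cols = [c for c in TRANSITION_COLUMNS if c not in df.columns]
        if missing_cols:
            raise IncompleteTableError(f"incomplete table: missing columns {missing_cols}")
        df = df[list(TRANSITION_COLUMNS)].astype(float)
        for sex in sorted({s for s, _ in df.index}):
            present = {g for s, g in df.index if s == sex}
            absent = [g for g in AGE_GROUP_LABELS if g not in present]
            if absent:
                raise IncompleteTableError(f"incomplete table: sex={sex} missing age groups {absent}")
        self._validate_probabilities(df)
        self.df = df.sort_index()

    @staticmethod
    def _validate_probabilities(df: pd.DataFrame) -> None:
        for (sex, group), row in df.iterrows():
            for col in TRANSITION_COLUMNS:
                p = row[col]
                if not np.isfinite(p) or p < 0.0 or p > 1.0:
                    raise InvalidProbabilityError(
                        f"invalid probabilities: {col}={p} out of [0,1] at ({sex}, {group})"
                    )
            for state, cols in EXIT_COLUMNS.items():
                total = float(sum(row[c] for c in cols))
                if total > 1.0 + 1e-12:
                    raise InvalidProbabilityError(
                        f"invalid probabilities: exit sum {total:.6g} > 1 for "
                        f"{state.value} at ({sex}, {group})"
                    )

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(sorted({s for s, _ in self.df.index}))

    def probs(self, sex: str, group: Union[str, AgeGroup]) -> pd.Series:
        label = group.label if isinstance(group, AgeGroup) else group_from_label(group).label
        return self.df.loc[(_normalise_sex(sex), label)]

    def probs_for_age(self, sex: str, age: float) -> pd.Series:
        return self.probs(sex, group_for_age(age))

    def remain_probability(self, sex: str, group: Union[str, AgeGroup], state: StateId) -> float:
        """Residual 1 - sum(exit probabilities) for a living source state."""
        row = self.probs(sex, group)
        return 1.0 - float(sum(row[c] for c in EXIT_COLUMNS[state]))

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write with a sex column; floats round-trip bit-exactly."""
        self.df.reset_index().to_csv(path, index=False)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TransitionTable) and self.df.equals(other.df)


class IncidenceTable:
    """Incident case counts (IC) and rates (IR, per 1,000/year) per cell."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        df.index = df.index.set_names(["sex", "age_group"])
        for col in ("ic", "ir"):
            if col not in df.columns:
                raise IncompleteTableError(f"incomplete table: missing column {col}")
        df = df[["ic", "ir"]].astype(float)
        if (df["ic"] < 0).any():
            raise ParameterError("incident case counts must be >= 0")
        bad = df[(df["ic"] > 0) & (df["ir"] <= 0)]
        if len(bad):
            raise ParameterError(f"undefined denominator: IR <= 0 with IC > 0 at {list(bad.index)}")
        self.df = df.sort_index()

    def ic(self, sex: str, group: str) -> float:
        return float(self.df.loc[(_normalise_sex(sex), group), "ic"])

    def ir(self, sex: str, group: str) -> float:
        return float(self.df.loc[(_normalise_sex(sex), group), "ir"])


def derive_population(inc: IncidenceTable) -> pd.Series:
    """Population denominators implied by IC and IR: pop = IC / IR * 1,000.

    The convention gives population 0 where IC = 0. Values are rounded to the
    nearest person.
    """
    df = inc.df
    pop = pd.Series(0.0, index=df.index, name="population")
    nz = df["ic"] > 0
    pop[nz] = df.loc[nz, "ic"] / df.loc[nz, "ir"] * 1000.0
    return pop.round().astype(np.int64)


def _read_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", skip_blank_lines=True)


def load_transition_table(
    path: Union[str, Path], sex: Optional[str] = None
) -> TransitionTable:
    """Load a transition table from delimited text.

    The file either carries a ``sex`` column or ``sex`` is given for a
    single-sex file (the packaged per-sex fixture layout).
    """
    raw = _read_table(path)
    if "sex" not in raw.columns:
        if sex is None:
            raise ParameterError(f"{path}: no sex column and no sex given")
        raw["sex"] = _normalise_sex(sex)
    raw["sex"] = raw["sex"].map(_normalise_sex)
    raw["age_group"] = raw["age_group"].map(lambda s: group_from_label(str(s)).label)
    return TransitionTable(raw.set_index(["sex", "age_group"]))


def load_incidence_table(path: Union[str, Path], sex: Optional[str] = None) -> IncidenceTable:
    raw = _read_table(path)
    if "sex" not in raw.columns:
        if sex is None:
            raise ParameterError(f"{path}: no sex column and no sex given")
        raw["sex"] = _normalise_sex(sex)
    raw["sex"] = raw["sex"].map(_normalise_sex)
    raw["age_group"] = raw["age_group"].map(lambda s: group_from_label(str(s)).label)
    return IncidenceTable(raw.set_index(["sex", "age_group"]))


def load_fixture_tables() -> tuple[TransitionTable, IncidenceTable]:
    """Load the packaged published transition/incidence tables (both sexes)."""
    frames = []
    for sex in SEXES:
        with resources.as_file(
            resources.files("dmburden.data").joinpath(f"transitions_{sex}.csv")
        ) as p:
            raw = _read_table(p)
        raw["sex"] = sex
        frames.append(raw)
    combined = pd.concat(frames, ignore_index=True)
    combined["age_group"] = combined["age_group"].map(lambda s: group_from_label(str(s)).label)
    indexed = combined.set_index(["sex", "age_group"])
    return TransitionTable(indexed), IncidenceTable(indexed)


@dataclass(frozen=True)
class DisabilityWeight:
    """A disability weight in (0, 1) with interval bounds (95% CI endpoints).

    Bounds default to the point value when an interval is not supplied.
    """

    point: float
    lower: Optional[float] = None
    upper: Optional[float] = None

    def __post_init__(self) -> None:
        lo = self.point if self.lower is None else self.lower
        hi = self.point if self.upper is None else self.upper
        object.__setattr__(self, "lower", float(lo))
        object.__setattr__(self, "upper", float(hi))
        if not (0.0 < self.point < 1.0):
            raise ParameterError(f"disability weight {self.point} outside (0,1)")
        if not (self.lower <= self.point <= self.upper):
            raise ParameterError(
                f"disability weight bounds must bracket the point: "
                f"{self.lower} <= {self.point} <= {self.upper} violated"
            )


@dataclass(frozen=True)
class DisabilityWeightSet:
    """Severity weights for diabetes without and with complications.

    Defaults are the published weights 0.334 (uncomplicated) and 0.663
    (complicated). Interval bounds are configuration inputs; when no interval
    is supplied the bounds collapse to the point values.
    """

    uncomplicated: DisabilityWeight = field(default_factory=lambda: DisabilityWeight(0.334))
    complicated: DisabilityWeight = field(default_factory=lambda: DisabilityWeight(0.663))

    def __post_init__(self) -> None:
        if self.complicated.point <= self.uncomplicated.point:
            raise ParameterError(
                "complicated disability weight must exceed the uncomplicated one"
            )


class LifeTable:
    """Residual life expectancy (years) by sex and single year of age."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        need = {"sex", "age", "rle_years"}
        if not need.issubset(df.columns):
            raise ParameterError(f"life table needs columns {sorted(need)}")
        df["sex"] = df["sex"].map(_normalise_sex)
        df["age"] = df["age"].astype(int)
        df["rle_years"] = df["rle_years"].astype(float)
        if (df["rle_years"] <= 0).any():
            bad = df[df["rle_years"] <= 0].iloc[0]
            raise ParameterError(
                f"residual life expectancy must be > 0 (sex={bad['sex']}, age={bad['age']})"
            )
        self._lookup: dict[tuple[str, int], float] = {
            (r.sex, int(r.age)): float(r.rle_years) for r in df.itertuples()
        }
        self.df = df.sort_values(["sex", "age"]).reset_index(drop=True)

    def rle(self, sex: str, age: int) -> float:
        key = (_normalise_sex(sex), int(age))
        if key not in self._lookup:
            raise LifeTableGapError(f"life table gap at age {int(age)} (sex={key[0]})")
        return self._lookup[key]

    def require_coverage(self, min_age: int, max_age: int, sexes: tuple[str, ...] = SEXES) -> None:
        """Interpolation is never performed; any missing age is an error."""
        for sex in sexes:
            for age in range(min_age, max_age + 1):
                if (sex, age) not in self._lookup:
                    raise LifeTableGapError(f"life table gap at age {age} (sex={sex})")

    def to_csv(self, path: Union[str, Path]) -> None:
        self.df.to_csv(path, index=False)


def load_life_table(
    path: Union[str, Path], min_age: int = 30, max_age: int = 130
) -> LifeTable:
    """Load a (sex, age, rle_years) table and check gap-free coverage."""
    lt = LifeTable(_read_table(path))
    lt.require_coverage(min_age, max_age)
    return lt


@dataclass
class RunConfig:
    """Simulation and valuation settings.

    discount_rate
        Annual rate down-weighting future health years (default 0.05).
    cycle_length
        Markov cycle length in years (1).
    horizon
        Number of cycles simulated (100).
    tunnel_length
        Cycles an incident case spends in the incident tunnel before
        converting to the existing-prevalent state (5).
    duration_days
        Assumed days between the diabetes index and the complication index
        for complication cases diagnosed around diabetes onset; one of
        0 (minimum, same-day), 180 (median) or 365 (maximum). Consumed by
        the claims derivation; fixed published tables already embed one
        assumption.
    yll_method
        "simple" (default) values each death at the full residual life
        expectancy; "annuitized" additionally discounts the lost life years
        from the time of death: (1 - (1+r)^-RLE) / r.
    max_age
        Age at which the simulation endpoint is reached (default 100; set
        None to run the full ``horizon`` regardless of age). The effective
        number of valued cycles is min(horizon, max_age - starting age).
    discount_timing
        "end" (default) discounts each cycle's accrual at its end-of-cycle
        boundary; "start" leaves the first cycle undiscounted.
    start_age_offset
        Years added to a starting group's lower bound to place the cohort's
        entry age (default 1, calibrated against the published per-group
        results; 2 gives the band midpoint).
    """

    discount_rate: float = 0.05
    cycle_length: float = 1.0
    horizon: int = 100
    tunnel_length: int = 5
    duration_days: int = 0
    yll_method: str = "simple"
    max_age: Optional[int] = 100
    discount_timing: str = "end"
    start_age_offset: int = 1
    washout_years: int = 3
    min_events: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ParameterError("discount_rate must be >= 0")
        if not (self.horizon >= self.tunnel_length >= 1):
            raise ParameterError("need horizon >= tunnel_length >= 1")
        if self.cycle_length <= 0:
            raise ParameterError("cycle_length must be > 0")
        if self.duration_days not in (0, 180, 365):
            raise ParameterError("duration_days must be one of 0, 180, 365")
        if self.yll_method not in ("simple", "annuitized"):
            raise ParameterError("yll_method must be 'simple' or 'annuitized'")
        if self.discount_timing not in ("start", "end"):
            raise ParameterError("discount_timing must be 'start' or 'end'")
        if self.max_age is not None and self.max_age < 35:
            raise ParameterError("max_age must be None or >= 35")
        if not (0 <= self.start_age_offset <= 4):
            raise ParameterError("start_age_offset must be within the 5-year band (0..4)")
        if self.washout_years < 1:
            raise ParameterError("washout_years must be >= 1")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ParameterError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)
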