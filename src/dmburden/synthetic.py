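"""Synthetic claims-like records with known ground-truth transition rates.

The generator emulates a national-sample claims extract: per person it draws
competing exponential waiting times through the diabetes natural history
(onset -> incident diabetes -> complication -> death, with conversion to the
prevalent states after a 5-year tunnel), lays the events on a calendar, and
reproduces the data artifacts the derivation rules exist for:

* death dates are coarsened to month precision;
* a configurable share of persons are already diabetic (or complicated)
  before the observation window, with pre-window diagnosis claims and annual
  maintenance claims, so washout classification yields both incident and
  existing-prevalent cases;
* complication events carry an E-class or over-60 code class, optionally at
  the diagnosis day (E-class at onset) or predating the diagnosis (the
  reverse-transition over-60 cases probed by the duration sensitivity).

Hazards are looked up by the person's age group at the window start and held
constant through the follow-up (a semi-Markov simplification, exact when the
profile's rates do not vary with age).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .ages import AGE_GROUPS, AGE_GROUP_LABELS
from .claims import ClaimEvent, ClaimRecord, probability_to_rate, rate_to_probability
from .parameters import SEXES, TransitionTable
from .states import TRANSITION_COLUMNS

RATE_COLUMNS = ("onset",) + TRANSITION_COLUMNS

#: mid-range adult T2DM hazards (per person-year) used by the default profile
DEFAULT_RATES = {
    "onset": 0.012,
    "di_ci": 0.13,
    "di_dthdm": 0.002,
    "di_dthoth": 0.03,
    "dep_ci": 0.11,
    "dep_dthdm": 0.002,
    "dep_dthoth": 0.02,
    "ci_dthdm": 0.003,
    "ci_dthoth": 0.015,
    "cep_dthdm": 0.005,
    "cep_dthoth": 0.02,
}


@dataclass
class SyntheticProfile:
    """Ground truth for the generator.

    ``rates`` holds per (sex, age group) hazards (per person-year) for
    diabetes onset and the ten modelled transitions. ``n_per_cell`` persons
    per (sex, age group) are observed from January 1 of
    ``window_start_year`` for ``window_years`` years.
    """

    rates: pd.DataFrame
    n_per_cell: int = 5000
    frac_prevalent: float = 0.12
    frac_prevalent_complicated: float = 0.25
    frac_ecode: float = 0.7
    frac_ecode_at_onset: float = 0.01
    frac_reverse: float = 0.02
    window_start_year: int = 2004
    window_years: int = 13
    tunnel_years: int = 5
    #: calendar year at which the 5-year age bands are anchored (defaults to
    #: the default index year, so every estimation cell is populated there)
    age_reference_year: Optional[int] = None

    def __post_init__(self) -> None:
        missing = set(RATE_COLUMNS) - set(self.rates.columns)
        if missing:
            raise ValueError(f"profile rates missing columns {sorted(missing)}")
        if (self.rates[list(RATE_COLUMNS)] < 0).any().any():
            raise ValueError("rates must be >= 0")
        if self.n_per_cell <= 0:
            raise ValueError("populations must be > 0")

    @property
    def window_start(self) -> dt.date:
        return dt.date(self.window_start_year, 1, 1)

    @property
    def window_end(self) -> dt.date:
        return dt.date(self.window_start_year + self.window_years - 1, 12, 31)

    @property
    def default_index_year(self) -> int:
        """Latest index year whose follow-up stays inside the incident tunnel."""
        return self.window_start_year + self.window_years - 1 - self.tunnel_years + 1

    @classmethod
    def constant(cls, overrides: Optional[dict] = None, **kwargs) -> "SyntheticProfile":
        """A profile with the same hazards in every (sex, age group) cell."""
        vals = dict(DEFAULT_RATES)
        if overrides:
            unknown = set(overrides) - set(RATE_COLUMNS)
            if unknown:
                raise ValueError(f"unknown rate names {sorted(unknown)}")
            vals.update(overrides)
        idx = pd.MultiIndex.from_product([SEXES, AGE_GROUP_LABELS], names=["sex", "age_group"])
        rates = pd.DataFrame({c: vals[c] for c in RATE_COLUMNS}, index=idx)
        return cls(rates=rates, **kwargs)

    @classmethod
    def from_transition_table(
        cls, table: TransitionTable, onset_rate: float = 0.012, **kwargs
    ) -> "SyntheticProfile":
        """Invert a probability table (r = -ln(1-p)) into a rate profile."""
        rates = table.df.map(lambda p: probability_to_rate(float(p)))
        rates.insert(0, "onset", onset_rate)
        return cls(rates=rates, **kwargs)


def default_profile(**kwargs) -> SyntheticProfile:
    return SyntheticProfile.constant(**kwargs)


def recovery_profile(n_per_cell: int = 16667, **kwargs) -> SyntheticProfile:
    """Profile for parameter-recovery experiments: constant hazards with the
    incident and prevalent variants of each transition set equal, and no
    reverse or at-diagnosis complication cases, so the data-generating
    process matches the estimator's classification assumptions exactly.
    """
    overrides = {
        "di_ci": 0.12, "dep_ci": 0.12,
        "di_dthdm": 0.002, "dep_dthdm": 0.002,
        "di_dthoth": 0.025, "dep_dthoth": 0.025,
        "ci_dthdm": 0.004, "cep_dthdm": 0.004,
        "ci_dthoth": 0.018, "cep_dthoth": 0.018,
    }
    return SyntheticProfile.constant(
        overrides,
        n_per_cell=n_per_cell,
        frac_ecode_at_onset=0.0,
        frac_reverse=0.0,
        **kwargs,
    )


def true_probability_table(profile: SyntheticProfile) -> TransitionTable:
    """The analytic per-cycle table, p = 1 - exp(-r), the derivation recovers."""
    probs = profile.rates[list(TRANSITION_COLUMNS)].map(
        lambda r: rate_to_probability(float(r))
    )
    return TransitionTable(probs)


# ---------------------------------------------------------------------------

_DI, _DEP, _CI, _CEP, _DEAD, _DONE = 0, 1, 2, 3, 4, 5

_PHASE = {
    _DI: (("di_ci", "di_dthdm", "di_dthoth"), (_CI, _DEAD, _DEAD), True),
    _DEP: (("dep_ci", "dep_dthdm", "dep_dthoth"), (_CI, _DEAD, _DEAD), False),
    _CI: (("ci_dthdm", "ci_dthoth"), (_DEAD, _DEAD), True),
    _CEP: (("cep_dthdm", "cep_dthoth"), (_DEAD, _DEAD), False),
}


def _simulate_paths(
    profile: SyntheticProfile,
    sex: str,
    state: np.ndarray,
    t: np.ndarray,
    cell: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Advance every person to death or censoring; constant cell hazards."""
    W = float(profile.window_years)
    L = float(profile.tunnel_years)
    n = state.size
    entry = t.copy()  # time of entry into the current (tunnel) state
    comp_time = np.full(n, np.nan)
    death_time = np.full(n, np.nan)
    death_dm = np.zeros(n, dtype=bool)
    rate_mat = profile.rates.loc[sex, list(RATE_COLUMNS)].to_numpy()  # (12, 11)
    col_of = {c: i for i, c in enumerate(RATE_COLUMNS)}

    for _ in range(8):
        active = (state != _DEAD) & (state != _DONE) & (t < W)
        if not active.any():
            break
        for s, (cols, dests, tunnelled) in _PHASE.items():
            m = active & (state == s)
            if not m.any():
                continue
            idx = np.nonzero(m)[0]
            r = rate_mat[np.ix_(cell[idx], [col_of[c] for c in cols])]
            lam = r.sum(axis=1)
            with np.errstate(divide="ignore"):
                wait = np.where(lam > 0, rng.exponential(1.0, idx.size) / np.where(lam > 0, lam, 1.0), np.inf)
            t_event = t[idx] + wait
            t_cap = entry[idx] + L if tunnelled else np.full(idx.size, np.inf)
            t_stop = np.minimum(t_cap, W)
            happens = t_event < t_stop
            # censoring / tunnel conversion
            conv = ~happens & (t_cap < W)
            done = ~happens & ~conv
            if conv.any():
                j = idx[conv]
                state[j] = _DEP if s == _DI else _CEP
                t[j] = t_cap[conv]
                entry[j] = t_cap[conv]
            if done.any():
                j = idx[done]
                state[j] = _DONE
                t[j] = W
            if happens.any():
                j = idx[happens]
                u = rng.random(j.size) * lam[happens]
                dest_idx = (u[:, None] >= np.cumsum(r[happens], axis=1)).sum(axis=1)
                dest_idx = np.minimum(dest_idx, len(dests) - 1)
                new_state = np.array(dests)[dest_idx]
                tj = t_event[happens]
                t[j] = tj
                entry[j] = tj
                is_dm = np.array([c.endswith("dthdm") for c in cols])[dest_idx]
                dead = new_state == _DEAD
                state[j] = new_state
                comp_here = new_state == _CI
                comp_time[j[comp_here]] = tj[comp_here]
                death_time[j[dead]] = tj[dead]
                death_dm[j[dead]] = is_dm[dead]
    return {"comp_time": comp_time, "death_time": death_time, "death_dm": death_dm}


def generate_population(
    profile: SyntheticProfile, seed: int, as_frame: bool = False
):
    """Generate claims records for every person in the profile.

    Deterministic for a fixed seed. Returns a list of
    :class:`~dmburden.claims.ClaimRecord` or, with ``as_frame=True``, the
    event-per-row DataFrame the derivation consumes directly.
    """
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(profile.window_start)
    end = pd.Timestamp(profile.window_end)
    W = float(profile.window_years)
    frames = []
    for sex in SEXES:
        n_cell = profile.n_per_cell
        n = n_cell * len(AGE_GROUPS)
        cell = np.repeat(np.arange(len(AGE_GROUPS)), n_cell)
        lowers = np.array([g.lower for g in AGE_GROUPS])
        uppers = np.array([g.upper if g.upper is not None else 89 for g in AGE_GROUPS])
        age0 = rng.integers(lowers[cell], uppers[cell] + 1)
        birth_offset = rng.integers(0, 365, n)
        ref_year = profile.age_reference_year or profile.default_index_year
        ref = pd.Timestamp(dt.date(ref_year, 1, 1))
        birth = ref - pd.to_timedelta(np.round(age0 * 365.25).astype(int) + birth_offset, unit="D")

        onset_rate = profile.rates.loc[sex, "onset"].to_numpy()[cell]
        prevalent = rng.random(n) < profile.frac_prevalent
        cep0 = prevalent & (rng.random(n) < profile.frac_prevalent_complicated)
        # pre-window onset, past the incident tunnel
        t_onset = np.where(prevalent, -rng.uniform(profile.tunnel_years, 25.0, n), np.nan)
        with np.errstate(divide="ignore"):
            wait = np.where(onset_rate > 0, rng.exponential(1.0, n) / np.where(onset_rate > 0, onset_rate, 1.0), np.inf)
        t_onset = np.where(prevalent, t_onset, wait)
        has_onset = t_onset < W

        state = np.full(n, _DONE)
        t = np.full(n, W)
        ecode_at_onset = has_onset & ~prevalent & (rng.random(n) < profile.frac_ecode_at_onset)
        comp_time0 = np.full(n, np.nan)
        m = has_onset
        state[m & ~prevalent & ~ecode_at_onset] = _DI
        state[m & ~prevalent & ecode_at_onset] = _CI
        state[m & prevalent & ~cep0] = _DEP
        state[m & prevalent & cep0] = _CEP
        t[m] = np.maximum(t_onset[m], 0.0)
        comp_time0[m & ~prevalent & ecode_at_onset] = t_onset[m & ~prevalent & ecode_at_onset]
        # pre-window complication for the initially complicated
        pc = m & prevalent & cep0
        comp_time0[pc] = t_onset[pc] + rng.uniform(0.0, 1.0, int(pc.sum())) * (0.0 - t_onset[pc])

        paths = _simulate_paths(profile, sex, state, t, cell, rng)
        comp_time = np.where(np.isnan(comp_time0), paths["comp_time"], comp_time0)
        death_time, death_dm = paths["death_time"], paths["death_dm"]

        # reverse-transition cases: an over-60-class complication claim
        # predating an in-window diagnosis (pre-existing IHD/stroke history)
        age_at_onset = age0 + t_onset
        reverse = (
            has_onset & ~prevalent & ~ecode_at_onset
            & (t_onset >= 0) & (age_at_onset >= 60)
            & (rng.random(n) < profile.frac_reverse)
        )
        reverse_lag_days = rng.integers(30, 1096, n)

        pid_prefix = 0 if sex == "male" else 1
        pids = pid_prefix * 10**7 + np.arange(n)

        DAYS = 365.25

        def _dates(tyears: np.ndarray) -> pd.Series:
            return pd.Series(start + pd.to_timedelta(np.round(tyears * DAYS).astype("int64"), unit="D"))

        rows = [pd.DataFrame({
            "person_id": pids, "sex": sex, "birth_date": birth,
            "event_date": start, "event_class": "enrollment", "date_precision": "day",
        })]

        ho = np.nonzero(has_onset)[0]
        onset_date = _dates(t_onset[ho])
        rows.append(pd.DataFrame({
            "person_id": pids[ho], "sex": sex, "birth_date": birth[ho],
            "event_date": onset_date, "event_class": "t2dm_dx", "date_precision": "day",
        }))

        # annual maintenance claims (Jan 15) from the year after onset, while
        # alive and inside the window
        onset_year = onset_date.dt.year.to_numpy()
        first_claim_year = np.maximum(onset_year + 1, profile.window_start_year)
        last_year = np.full(ho.size, profile.window_start_year + profile.window_years - 1)
        death_date_ho = np.where(
            np.isnan(death_time[ho]), np.datetime64("2200-01-01"),
            _dates(np.nan_to_num(death_time[ho])).to_numpy(),
        )
        counts = np.maximum(last_year - first_claim_year + 1, 0)
        rep = np.repeat(np.arange(ho.size), counts)
        yr = np.concatenate(
            [np.arange(f, l + 1) for f, l in zip(first_claim_year, last_year) if l >= f]
        ) if counts.sum() else np.array([], dtype=int)
        claim_date = pd.to_datetime(
            {"year": yr, "month": np.ones(yr.size, dtype=int), "day": np.full(yr.size, 15)}
        )
        keep = claim_date.to_numpy() < death_date_ho[rep]
        rows.append(pd.DataFrame({
            "person_id": pids[ho][rep][keep], "sex": sex, "birth_date": birth[ho][rep][keep],
            "event_date": claim_date[keep], "event_class": "t2dm_dx", "date_precision": "day",
        }))

        hc = np.nonzero(~np.isnan(comp_time))[0]
        comp_date = _dates(comp_time[hc])
        age_at_comp = (comp_date - pd.Series(birth[hc]).reset_index(drop=True)).dt.days / 365.25
        eclass = (age_at_comp.to_numpy() < 60.0) | (rng.random(hc.size) < profile.frac_ecode)
        eclass |= ecode_at_onset[hc]
        rows.append(pd.DataFrame({
            "person_id": pids[hc], "sex": sex, "birth_date": birth[hc],
            "event_date": comp_date,
            "event_class": np.where(eclass, "complication_ecode", "complication_over60"),
            "date_precision": "day",
        }))

        rv = np.nonzero(reverse)[0]
        if rv.size:
            rdate = _dates(t_onset[rv]) - pd.to_timedelta(reverse_lag_days[rv], unit="D")
            rows.append(pd.DataFrame({
                "person_id": pids[rv], "sex": sex, "birth_date": birth[rv],
                "event_date": rdate, "event_class": "complication_over60",
                "date_precision": "day",
            }))

        hd = np.nonzero(~np.isnan(death_time))[0]
        ddate = _dates(death_time[hd])
        rows.append(pd.DataFrame({
            "person_id": pids[hd], "sex": sex, "birth_date": birth[hd],
            "event_date": ddate.dt.to_period("M").dt.to_timestamp(),  # month precision
            "event_class": np.where(death_dm[hd], "death_dm", "death_other"),
            "date_precision": "month",
        }))

        df = pd.concat([r for r in rows if len(r)], ignore_index=True)
        df = df[(df["event_class"] == "enrollment") | (df["event_date"] <= end)]
        frames.append(df)

    frame = pd.concat(frames, ignore_index=True).sort_values(
        ["person_id", "event_date"], kind="stable"
    ).reset_index(drop=True)
    if as_frame:
        return frame
    return frame_to_records(frame)


def frame_to_records(frame: pd.DataFrame) -> list[ClaimRecord]:
    records = []
    for pid, grp in frame.groupby("person_id", sort=True):
        first = grp.iloc[0]
        events = [
            ClaimEvent(row.event_date.date(), row.event_class, row.date_precision)
            for row in grp.itertuples()
            if row.event_class != "enrollment" and pd.notna(row.event_date)
        ]
        records.append(
            ClaimRecord(
                person_id=pid, sex=first["sex"],
                birth_date=first["birth_date"].date(), events=events,
            )
        )
    return records
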