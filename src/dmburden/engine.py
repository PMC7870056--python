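"""Cohort simulation over the expanded tunnel state space.

One incident cohort (mass 1 entering the first incident-diabetes tunnel
state) is propagated for ``horizon`` one-year cycles. Transitions occur at
cycle end; occupancy recorded at index ``t`` is the start-of-cycle occupancy
of cycle ``t``. The cohort ages one year per cycle and the probability row in
force is the one for the age group containing the current integer age (the
85+ row applies indefinitely beyond 85). Both death states are absorbing.

State order (tunnel length L, default 5):

    Di1..DiL, Dep, Ci1..CiL, Cep, DTHdm, DTHoth

Di(k) uses the incident-diabetes exit probabilities with the residual mass
advancing to Di(k+1), or converting to Dep after the L-th cycle; Ci(k) is
analogous via Cep. A Di->Ci transition always enters Ci1: the complication
tunnel clock restarts at complication onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

from .ages import AgeGroup, group_from_label
from .parameters import RunConfig, TransitionTable
from .states import expanded_state_names


class EngineError(ValueError):
    """Inconsistent transition rows (negative residual mass)."""


def discount_factor(cycle: Union[int, np.ndarray], config: RunConfig) -> Union[float, np.ndarray]:
    """(1 + r)^(-cycle); cycle 0 is undiscounted."""
    return (1.0 + config.discount_rate) ** (-np.asarray(cycle, dtype=float))


def build_cycle_matrix(
    table: TransitionTable, sex: str, age: float, tunnel_length: int = 5
) -> np.ndarray:
    """Row-stochastic one-cycle matrix over the expanded state space."""
    row = table.probs_for_age(sex, age)
    L = tunnel_length
    n = 2 * L + 4
    dep, cep, dthdm, dthoth = L, 2 * L + 1, 2 * L + 2, 2 * L + 3
    P = np.zeros((n, n))

    def residual(*ps: float, where: str) -> float:
        res = 1.0 - sum(ps)
        if res < -1e-12:
            raise EngineError(f"invalid row: exits sum to {sum(ps):.6g} > 1 for {where}")
        return max(res, 0.0)

    r_di = residual(row.di_ci, row.di_dthdm, row.di_dthoth, where="Di")
    for k in range(L):
        P[k, L + 1] = row.di_ci          # -> Ci1
        P[k, dthdm] = row.di_dthdm
        P[k, dthoth] = row.di_dthoth
        P[k, k + 1 if k < L - 1 else dep] = r_di
    P[dep, L + 1] = row.dep_ci
    P[dep, dthdm] = row.dep_dthdm
    P[dep, dthoth] = row.dep_dthoth
    P[dep, dep] = residual(row.dep_ci, row.dep_dthdm, row.dep_dthoth, where="Dep")
    r_ci = residual(row.ci_dthdm, row.ci_dthoth, where="Ci")
    for k in range(L + 1, 2 * L + 1):
        P[k, dthdm] = row.ci_dthdm
        P[k, dthoth] = row.ci_dthoth
        P[k, k + 1 if k < 2 * L else cep] = r_ci
    P[cep, dthdm] = row.cep_dthdm
    P[cep, dthoth] = row.cep_dthoth
    P[cep, cep] = residual(row.cep_dthdm, row.cep_dthoth, where="Cep")
    P[dthdm, dthdm] = 1.0
    P[dthoth, dthoth] = 1.0
    return P


@dataclass
class CohortTrace:
    """Per-cycle state occupancy of one simulated incident cohort.

    ``occupancy[t]`` is the start-of-cycle-``t`` distribution over the
    expanded states; ``new_ci``/``new_dthdm``/``new_dthoth[t]`` is the mass
    that entered Ci1 / DTHdm / DTHoth between ``t-1`` and ``t`` (index 0 is
    zero). ``ages[t]`` is the cohort's integer age at cycle ``t``.
    """

    sex: str
    start_group: str
    occupancy: np.ndarray
    new_ci: np.ndarray
    new_dthdm: np.ndarray
    new_dthoth: np.ndarray
    ages: np.ndarray
    tunnel_length: int = 5
    state_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.state_names:
            self.state_names = expanded_state_names(self.tunnel_length)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def _cols(self, names: list[str]) -> np.ndarray:
        idx = [self.state_names.index(n) for n in names]
        return self.occupancy[:, idx].sum(axis=1)

    @property
    def uncomplicated_mass(self) -> np.ndarray:
        L = self.tunnel_length
        return self._cols([f"Di{k}" for k in range(1, L + 1)] + ["Dep"])

    @property
    def complicated_mass(self) -> np.ndarray:
        L = self.tunnel_length
        return self._cols([f"Ci{k}" for k in range(1, L + 1)] + ["Cep"])

    @property
    def alive_mass(self) -> np.ndarray:
        return self.uncomplicated_mass + self.complicated_mass

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=self.state_names)
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df["new_Ci1"] = self.new_ci
        df["new_DTHdm"] = self.new_dthdm
        df["new_DTHoth"] = self.new_dthoth
        return df


def simulate_cohort(
    sex: str,
    start_group: Union[str, AgeGroup],
    table: TransitionTable,
    config: RunConfig,
    start_age: int | None = None,
) -> CohortTrace:
    """Propagate a unit incident cohort for ``config.horizon`` cycles.

    The cohort enters Di1 at ``start_age`` (default: the starting group's
    lower bound plus ``config.start_age_offset``, e.g. 56 for 55-59).
    """
    group = start_group if isinstance(start_group, AgeGroup) else group_from_label(start_group)
    if start_age is None:
        start_age = group.lower + config.start_age_offset
    L = config.tunnel_length
    n = 2 * L + 4
    ci1, dthdm, dthoth = L + 1, n - 2, n - 1
    H = config.horizon
    occ = np.zeros((H + 1, n))
    occ[0, 0] = 1.0
    new_ci = np.zeros(H + 1)
    new_dthdm = np.zeros(H + 1)
    new_dthoth = np.zeros(H + 1)
    ages = start_age + np.arange(H + 1)
    for t in range(H):
        P = build_cycle_matrix(table, sex, ages[t], tunnel_length=L)
        occ[t + 1] = occ[t] @ P
        new_ci[t + 1] = occ[t + 1, ci1]          # Ci1 has no inflow from itself
        new_dthdm[t + 1] = occ[t + 1, dthdm] - occ[t, dthdm]
        new_dthoth[t + 1] = occ[t + 1, dthoth] - occ[t, dthoth]
        total = occ[t + 1].sum()
        if abs(total - 1.0) > 1e-12:
            raise EngineError(f"mass not conserved at cycle {t + 1}: {total!r}")
    return CohortTrace(
        sex=sex,
        start_group=group.label,
        occupancy=occ,
        new_ci=new_ci,
        new_dthdm=new_dthdm,
        new_dthoth=new_dthoth,
        ages=ages,
        tunnel_length=L,
    )
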