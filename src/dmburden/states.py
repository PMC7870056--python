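"""Markov states of the diabetes natural-history model.

Six conceptual states: incident diabetes (Di), existing prevalent diabetes
(Dep), incident complications (Ci), existing prevalent complications (Cep),
death due to diabetes (DTHdm) and death due to other causes (DTHoth). Both
death states are absorbing.

For simulation the two incident states are expanded into 5-cycle tunnels
(Di1..Di5, Ci1..Ci5): a cohort member who spends five cycles in an incident
state without leaving it converts to the corresponding prevalent state, so
incidence-based probabilities apply only during the first five years after
entry.
"""

from __future__ import annotations

from enum import Enum

TUNNEL_LENGTH_DEFAULT = 5


class StateId(str, Enum):
    """The six conceptual model states."""

    DI = "Di"
    DEP = "Dep"
    CI = "Ci"
    CEP = "Cep"
    DTH_DM = "DTHdm"
    DTH_OTH = "DTHoth"

    @property
    def absorbing(self) -> bool:
        return self in (StateId.DTH_DM, StateId.DTH_OTH)


#: The ten estimated transitions, as (source, destination) conceptual states.
TRANSITIONS: tuple[tuple[StateId, StateId], ...] = (
    (StateId.DI, StateId.CI),
    (StateId.DI, StateId.DTH_DM),
    (StateId.DI, StateId.DTH_OTH),
    (StateId.DEP, StateId.CI),
    (StateId.DEP, StateId.DTH_DM),
    (StateId.DEP, StateId.DTH_OTH),
    (StateId.CI, StateId.DTH_DM),
    (StateId.CI, StateId.DTH_OTH),
    (StateId.CEP, StateId.DTH_DM),
    (StateId.CEP, StateId.DTH_OTH),
)

#: Column names used for the ten transition probabilities, in table order.
TRANSITION_COLUMNS: tuple[str, ...] = (
    "di_ci",
    "di_dthdm",
    "di_dthoth",
    "dep_ci",
    "dep_dthdm",
    "dep_dthoth",
    "ci_dthdm",
    "ci_dthoth",
    "cep_dthdm",
    "cep_dthoth",
)

#: Exit columns per source state (used for the exit-sum <= 1 invariant).
EXIT_COLUMNS: dict[StateId, tuple[str, ...]] = {
    StateId.DI: ("di_ci", "di_dthdm", "di_dthoth"),
    StateId.DEP: ("dep_ci", "dep_dthdm", "dep_dthoth"),
    StateId.CI: ("ci_dthdm", "ci_dthoth"),
    StateId.CEP: ("cep_dthdm", "cep_dthoth"),
}


def expanded_state_names(tunnel_length: int = TUNNEL_LENGTH_DEFAULT) -> list[str]:
    """Names of the expanded (tunnel) state space, in matrix order."""
    names = [f"Di{k}" for k in range(1, tunnel_length + 1)]
    names.append("Dep")
    names += [f"Ci{k}" for k in range(1, tunnel_length + 1)]
    names += ["Cep", "DTHdm", "DTHoth"]
    return names
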