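"""Counterfactual prostate-cancer natural history.

Each man may enter a preclinical, screen-detectable state at an age drawn
from a Weibull onset model, then progresses through the 18-state space
(T stage up, Gleason up, M0 -> M1) as a semi-Markov process with
exponential sojourns.  From every state an exponential clinical-diagnosis
clock competes with the progression clocks; the first clock to fire wins.

The trajectory is simulated *without* truncation at the man's other-cause
death age: the counterfactual clinical-diagnosis age, even when it falls
after death, is what defines overdiagnosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .demography import Person
from .states import ALL_STATES, GLEASONS, METASTASES, T_STAGES, PreclinicalState, parse_state

# Transition kinds out of a preclinical state, in fixed draw order.
TRANSITIONS = ("t_up", "gleason_up", "metastasize")

#: Ages beyond this are never reachable alive; progression is abandoned there.
AGE_CAP = 150.0


class NaturalHistoryError(ValueError):
    """Raised for invalid natural-history parameterizations."""


@dataclass(frozen=True)
class NaturalHistoryParams:
    """Onset, progression and clinical-diagnosis rates.

    Parameters
    ----------
    onset_shape, onset_scale
        Weibull parameters of the age at preclinical onset:
        cumulative hazard ``H(a) = (a / scale) ** shape``.  An infinite
        scale disables onset entirely (hazard identically zero).
    onset_fixed_age
        If set, overrides the Weibull model with a degenerate onset at
        exactly this age (used by analytic toy models).
    max_onset_age
        Onsets sampled at or beyond this age are discarded as "no disease";
        by construction nothing downstream can depend on them once the age
        exceeds the life table's maximum.
    entry_state_probs
        Distribution over entry states (labels), normally supported on the
        ``T1_*_M0`` states.
    progression_rates
        ``{state_label: {"t_up": r, "gleason_up": r, "metastasize": r}}``;
        missing keys mean rate 0 (the transition graph is config-driven).
    clinical_dx_rates
        ``{state_label: rate}`` exponential hazard of clinical diagnosis.
    """

    onset_shape: float = 5.0
    onset_scale: float = math.inf
    onset_fixed_age: float | None = None
    max_onset_age: float = 100.0
    entry_state_probs: dict[str, float] = field(default_factory=dict)
    progression_rates: dict[str, dict[str, float]] = field(default_factory=dict)
    clinical_dx_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.onset_fixed_age is None:
            if not (self.onset_shape > 0 and self.onset_scale > 0):
                raise NaturalHistoryError("onset_shape and onset_scale must be positive")
        labels = {s.label for s in ALL_STATES}
        if self.entry_state_probs:
            total = sum(self.entry_state_probs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise NaturalHistoryError(f"entry_state_distribution sums to {total}, not 1")
            for lab, p in self.entry_state_probs.items():
                if lab not in labels:
                    raise NaturalHistoryError(f"unknown entry state {lab!r}")
                if p < 0:
                    raise NaturalHistoryError(f"negative entry probability for {lab!r}")
        for lab, rates in self.progression_rates.items():
            if lab not in labels:
                raise NaturalHistoryError(f"unknown state {lab!r} in progression_rates")
            for kind, r in rates.items():
                if kind not in TRANSITIONS:
                    raise NaturalHistoryError(f"unknown transition {kind!r} from {lab!r}")
                if r < 0:
                    raise NaturalHistoryError(f"negative rate for {lab!r} -> {kind}")
        for lab, r in self.clinical_dx_rates.items():
            if lab not in labels:
                raise NaturalHistoryError(f"unknown state {lab!r} in clinical_dx_rates")
            if r < 0:
                raise NaturalHistoryError(f"negative clinical diagnosis rate for {lab!r}")

    # -- derived lookups -------------------------------------------------
    def entry_labels_and_probs(self) -> tuple[list[str], np.ndarray]:
        labels = [s.label for s in ALL_STATES if s.label in self.entry_state_probs]
        probs = np.array([self.entry_state_probs[lab] for lab in labels])
        return labels, probs

    def rate(self, state: PreclinicalState, kind: str) -> float:
        return float(self.progression_rates.get(state.label, {}).get(kind, 0.0))

    def dx_rate(self, state: PreclinicalState) -> float:
        return float(self.clinical_dx_rates.get(state.label, 0.0))


@dataclass
class LifeHistory:
    """One man's complete counterfactual disease trajectory.

    ``clinical_dx_age`` is recorded even when it exceeds the other-cause
    death age — the overdiagnosis classification needs the counterfactual.
    """

    person: Person
    onset_age: float | None = None
    trajectory: list[tuple[PreclinicalState, float]] = field(default_factory=list)
    clinical_dx_age: float | None = None
    state_at_clinical_dx: PreclinicalState | None = None

    @property
    def other_cause_death_age(self) -> float:
        return self.person.other_cause_death_age

    def __post_init__(self) -> None:
        if (self.onset_age is None) != (len(self.trajectory) == 0):
            raise ValueError("trajectory must be empty exactly when onset_age is none")
        ages = [a for _, a in self.trajectory]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("trajectory entry ages must be strictly increasing")
        if self.clinical_dx_age is not None and self.onset_age is not None:
            if self.clinical_dx_age < self.onset_age:
                raise ValueError("clinical_dx_age precedes onset_age")


def sample_onset_age(params: NaturalHistoryParams, u: float) -> float | None:
    """Inverse-CDF onset age; ``None`` when onset never happens (in scope)."""
    if params.onset_fixed_age is not None:
        age = params.onset_fixed_age
    elif not math.isfinite(params.onset_scale):
        return None
    else:
        age = params.onset_scale * (-math.log1p(-u)) ** (1.0 / params.onset_shape)
    return age if age < params.max_onset_age else None


def _next_state(state: PreclinicalState, kind: str) -> PreclinicalState:
    if kind == "t_up":
        return PreclinicalState(T_STAGES[T_STAGES.index(state.t_stage) + 1], state.gleason, state.metastasis)
    if kind == "gleason_up":
        return PreclinicalState(state.t_stage, GLEASONS[GLEASONS.index(state.gleason) + 1], state.metastasis)
    if kind == "metastasize":
        return PreclinicalState(state.t_stage, state.gleason, METASTASES[1])
    raise ValueError(kind)


def _allowed(state: PreclinicalState) -> list[str]:
    kinds = []
    if state.t_stage != T_STAGES[-1]:
        kinds.append("t_up")
    if state.gleason != GLEASONS[-1]:
        kinds.append("gleason_up")
    if state.metastasis == "M0":
        kinds.append("metastasize")
    return kinds


def simulate_disease_history(
    params: NaturalHistoryParams, person: Person, rng: np.random.Generator
) -> LifeHistory:
    """Competing-risks semi-Markov simulation of one man's disease course."""
    onset = sample_onset_age(params, rng.uniform())
    if onset is None:
        return LifeHistory(person=person)

    labels, probs = params.entry_labels_and_probs()
    if not labels:
        raise NaturalHistoryError("entry_state_distribution is empty")
    idx = int(np.searchsorted(np.cumsum(probs), rng.uniform(), side="right"))
    state = parse_state(labels[min(idx, len(labels) - 1)])

    trajectory: list[tuple[PreclinicalState, float]] = [(state, onset)]
    age = onset
    dx_age: float | None = None
    dx_state: PreclinicalState | None = None
    while age < AGE_CAP:
        kinds = _allowed(state)
        rates = np.array([params.rate(state, k) for k in kinds] + [params.dx_rate(state)])
        total = rates.sum()
        if total <= 0.0:
            break  # absorbing configuration: never clinically diagnosed
        age += rng.exponential(1.0 / total)
        which = int(np.searchsorted(np.cumsum(rates) / total, rng.uniform(), side="right"))
        which = min(which, len(rates) - 1)
        if which == len(kinds):  # clinical diagnosis clock fired
            dx_age, dx_state = age, state
            break
        state = _next_state(state, kinds[which])
        trajectory.append((state, age))

    return LifeHistory(
        person=person,
        onset_age=onset,
        trajectory=trajectory,
        clinical_dx_age=dx_age,
        state_at_clinical_dx=dx_state,
    )


def state_at(history: LifeHistory, age: float) -> PreclinicalState | None:
    """State occupied at ``age`` (half-open ``[entry, next_entry)`` intervals).

    ``None`` before onset and at or after clinical diagnosis.
    """
    if history.onset_age is None or age < history.onset_age:
        return None
    if history.clinical_dx_age is not None and age >= history.clinical_dx_age:
        return None
    current = None
    for st, entry in history.trajectory:
        if entry <= age:
            current = st
        else:
            break
    return current


def simulate_cohort_histories(
    params: NaturalHistoryParams,
    persons: list[Person],
    master_seed: int,
) -> list[LifeHistory]:
    """One :class:`LifeHistory` per man, each from its own keyed substream."""
    from .rng import substream

    return [
        simulate_disease_history(params, p, substream(master_seed, "natural_history", p.id))
        for p in persons
    ]
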