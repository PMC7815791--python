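"""Preclinical disease states.

The natural-history model distinguishes 18 preclinical, screen-detectable
states: the cross product of clinical T stage (T1, T2, T3), Gleason grade
group (<7, =7, >7) and metastatic status (M0, M1).  Disease severity is
partially ordered componentwise and only increases along a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

T_STAGES = ("T1", "T2", "T3")
GLEASONS = ("LT7", "EQ7", "GT7")  # Gleason <7, =7, >7
METASTASES = ("M0", "M1")


@dataclass(frozen=True, order=False)
class PreclinicalState:
    """One of the 18 preclinical states, e.g. ``PreclinicalState("T1", "LT7", "M0")``."""

    t_stage: str
    gleason: str
    metastasis: str

    def __post_init__(self) -> None:
        if self.t_stage not in T_STAGES:
            raise ValueError(f"unknown T stage {self.t_stage!r}")
        if self.gleason not in GLEASONS:
            raise ValueError(f"unknown Gleason class {self.gleason!r}")
        if self.metastasis not in METASTASES:
            raise ValueError(f"unknown metastasis flag {self.metastasis!r}")

    @property
    def label(self) -> str:
        return f"{self.t_stage}_{self.gleason}_{self.metastasis}"

    @property
    def severity(self) -> tuple[int, int, int]:
        """Componentwise severity index used for the monotonicity invariant."""
        return (
            T_STAGES.index(self.t_stage),
            GLEASONS.index(self.gleason),
            METASTASES.index(self.metastasis),
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


ALL_STATES: tuple[PreclinicalState, ...] = tuple(
    PreclinicalState(t, g, m) for t in T_STAGES for g in GLEASONS for m in METASTASES
)

assert len(ALL_STATES) == 18


def parse_state(label: str) -> PreclinicalState:
    """Parse a ``T1_LT7_M0``-style label."""
    parts = label.split("_")
    if len(parts) != 3:
        raise ValueError(f"malformed state label {label!r}")
    return PreclinicalState(*parts)


def is_significant(state: PreclinicalState) -> bool:
    """Clinically significant disease: Gleason score 7 or more.

    Gleason 6 and below counts as clinically insignificant.
    """
    return state.gleason in ("EQ7", "GT7")


def grade_class(state: PreclinicalState) -> str:
    """``"high"`` for clinically significant states, else ``"low"``."""
    return "high" if is_significant(state) else "low"
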