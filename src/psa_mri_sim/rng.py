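"""Purpose-keyed random streams for the counterfactual design.

The three arms (no screening, regular pathway, MRI pathway) are compared
under common random numbers: every draw that is logically shared between
arms — onset and progression, other-cause death, attendance, PSA episode,
compliance, biopsy, misclassification, treatment assignment, the survival
uniform and the cure uniform — is taken from a stream keyed by
``(master_seed, purpose)`` and indexed by man id, never by arm.  Adding an
arm or reordering arm evaluation therefore cannot perturb any draw.

Fixed-size purposes are materialised as arrays (rows = man id).  The
variable-length natural-history simulation gets its own per-man substream
keyed ``(master_seed, purpose, man_id)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Stable numeric codes; changing one silently changes every simulation.
PURPOSES = {
    "other_cause_death": 1,
    "natural_history": 2,
    "attendance": 3,
    "psa": 4,
    "mpmri": 5,
    "compliance": 6,
    "biopsy": 7,
    "misclassification_screen": 8,
    "misclassification_clinical": 9,
    "treatment": 10,
    "survival": 11,
    "cure": 12,
}


def substream(master_seed: int, purpose: str, man_id: int | None = None) -> np.random.Generator:
    """Independent generator for ``(master_seed, purpose[, man_id])``."""
    key = (int(master_seed), PURPOSES[purpose])
    if man_id is not None:
        key = key + (int(man_id),)
    return np.random.default_rng(np.random.SeedSequence(key))


@dataclass(frozen=True)
class CohortDraws:
    """All fixed-size uniforms for a cohort of ``n`` men and ``k`` screen rounds.

    Matrices are ``(n, k)``; vectors are ``(n,)``.  The same object is
    consumed by every arm — this is the common-random-numbers contract.
    """

    other_cause_death: np.ndarray
    attendance: np.ndarray
    psa: np.ndarray
    mpmri: np.ndarray
    compliance: np.ndarray
    biopsy: np.ndarray
    misclassification_screen: np.ndarray
    misclassification_clinical: np.ndarray
    treatment: np.ndarray
    survival: np.ndarray
    cure: np.ndarray

    @property
    def n(self) -> int:
        return self.survival.shape[0]


def draw_cohort_uniforms(master_seed: int, n: int, n_screens: int) -> CohortDraws:
    """Materialise every fixed-size purpose stream for ``n`` men."""
    if n < 1:
        raise ValueError("cohort size must be at least 1")

    def mat(purpose: str) -> np.ndarray:
        return substream(master_seed, purpose).uniform(size=(n, n_screens))

    def vec(purpose: str) -> np.ndarray:
        return substream(master_seed, purpose).uniform(size=n)

    return CohortDraws(
        other_cause_death=vec("other_cause_death"),
        attendance=mat("attendance"),
        psa=mat("psa"),
        mpmri=mat("mpmri"),
        compliance=mat("compliance"),
        biopsy=mat("biopsy"),
        misclassification_screen=mat("misclassification_screen"),
        misclassification_clinical=vec("misclassification_clinical"),
        treatment=vec("treatment"),
        survival=vec("survival"),
        cure=vec("cure"),
    )
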