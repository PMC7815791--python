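"""Screening pathway overlay.

Two diagnostic pathways are compared on top of the same natural history:

* **regular** — elevated PSA (cut-off 3 ng/mL) followed directly by a
  transrectal ultrasound-guided biopsy (TRUSGB);
* **mri** — elevated PSA followed by an mpMRI triage test (PIRADS 3–5
  positive) and, only if positive, an MRI-guided biopsy (MRIGB, no
  systematic biopsy).

PSA positivity is represented per preclinical state (``psa_pos_prob``); a
continuous PSA level is not modelled.  mpMRI and MRIGB sensitivities are
grade-specific (clinically significant = Gleason >= 7).  Grade
misclassification is downgrade-only: a truly significant cancer can be
recorded as insignificant at biopsy, never the reverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .natural_history import LifeHistory, state_at
from .states import PreclinicalState, grade_class

PATHWAYS = ("regular", "mri")


class ScreeningConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ScreeningProtocol:
    """Invitation schedule: every ``interval`` years from ``start_age`` to ``stop_age``."""

    start_age: float = 55.0
    stop_age: float = 64.0
    interval: float = 3.0
    attendance: float = 0.80
    pathway: str = "regular"

    def __post_init__(self) -> None:
        if self.start_age > self.stop_age:
            raise ScreeningConfigError("start_age must not exceed stop_age")
        if self.interval < 1:
            raise ScreeningConfigError("interval must be at least 1 year")
        if not (0.0 <= self.attendance <= 1.0):
            raise ScreeningConfigError("screening.attendance must lie in [0, 1]")
        if self.pathway not in PATHWAYS + ("none",):
            raise ScreeningConfigError(f"unknown pathway {self.pathway!r}")


@dataclass(frozen=True)
class TestParams:
    """Test characteristics of both pathways (all probabilities).

    Defaults carry the published operating characteristics: TRUSGB
    sensitivity 0.90 and biopsy compliance 0.90; mpMRI sensitivity 0.94 for
    high-grade and 0.74 for low-grade disease; MRIGB sensitivity 0.91
    (high) and 0.44 (low); grade misclassification 36.3% for TRUSGB versus
    8.7% for MRIGB; biopsy positive predictive values 22.7% (screen,
    regular), 35.8% (clinical presentation) and 58% (MRI pathway).
    """

    __test__ = False  # not a pytest collectible despite the name

    psa_pos_prob: dict[str, float] = field(default_factory=dict)
    trusgb_sens: float = 0.90
    biopsy_compliance: float = 0.90
    mpmri_sens_low: float = 0.74
    mpmri_sens_high: float = 0.94
    mrigb_sens_low: float = 0.44
    mrigb_sens_high: float = 0.91
    misclass_regular: float = 0.363
    misclass_mrigb: float = 0.087
    ppv_screen_regular: float = 0.227
    ppv_clinical: float = 0.358
    ppv_mri: float = 0.58

    def __post_init__(self) -> None:
        for name in (
            "trusgb_sens", "biopsy_compliance", "mpmri_sens_low", "mpmri_sens_high",
            "mrigb_sens_low", "mrigb_sens_high", "misclass_regular", "misclass_mrigb",
            "ppv_screen_regular", "ppv_clinical", "ppv_mri",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ScreeningConfigError(f"tests.{name} must lie in [0, 1] (got {v})")
        for lab, p in self.psa_pos_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ScreeningConfigError(f"tests.psa_pos_prob[{lab}] must lie in [0, 1]")

    def psa_prob(self, state: PreclinicalState) -> float:
        try:
            return self.psa_pos_prob[state.label]
        except KeyError:
            raise ScreeningConfigError(f"no psa_pos_prob entry for state {state.label}") from None

    def mpmri_sens(self, grade: str) -> float:
        return self.mpmri_sens_high if grade == "high" else self.mpmri_sens_low

    def mrigb_sens(self, grade: str) -> float:
        return self.mrigb_sens_high if grade == "high" else self.mrigb_sens_low

    def with_updates(self, **kwargs) -> "TestParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class EpisodeDraws:
    """Uniforms consumed by one screen episode.

    ``u_psa`` and ``u_comp`` (and ``u_bx``) are shared between pathways when
    the arms run paired — common random numbers.
    """

    u_psa: float
    u_mri: float
    u_comp: float
    u_bx: float


@dataclass
class ScreenOutcome:
    """Detection outcome of one man under one pathway."""

    detected: bool = False
    detection_age: float | None = None
    mode: str = "none"  # screen | clinical | none
    true_grade: str | None = None
    recorded_grade: str | None = None
    state_at_detection: PreclinicalState | None = None
    lead_time: float | None = None  # +inf when clinical dx would never occur
    # episode tallies used for biopsy/QALY accounting
    n_screens_attended: int = 0
    n_psa_positive: int = 0
    n_screen_biopsies: int = 0


@dataclass(frozen=True)
class BiopsyCount:
    screen_biopsies: float
    clinical_biopsies: float

    @property
    def total(self) -> float:
        return self.screen_biopsies + self.clinical_biopsies


def screen_ages(protocol: ScreeningProtocol) -> list[float]:
    """Invitation ages: ``start, start+interval, ...`` up to ``stop_age``."""
    ages = []
    a = float(protocol.start_age)
    while a <= protocol.stop_age + 1e-9:
        ages.append(a)
        a += protocol.interval
    return ages


def screen_episode_detects(
    state: PreclinicalState, pathway: str, tests: TestParams, draws: EpisodeDraws
) -> bool:
    """Does an attended screen of a man in ``state`` end in a positive biopsy?"""
    if draws.u_psa >= tests.psa_prob(state):
        return False
    grade = grade_class(state)
    if pathway == "mri" and draws.u_mri >= tests.mpmri_sens(grade):
        return False
    if draws.u_comp >= tests.biopsy_compliance:
        return False
    sens = tests.mrigb_sens(grade) if pathway == "mri" else tests.trusgb_sens
    return draws.u_bx < sens


def misclassify(true_grade: str, rate: float, u: float) -> str:
    """Downgrade-only grade recording: high -> low with probability ``rate``."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("misclassification rate must lie in [0, 1]")
    if true_grade == "high" and u < rate:
        return "low"
    return true_grade


def simulate_screening(
    history: LifeHistory,
    protocol: ScreeningProtocol,
    tests: TestParams,
    *,
    u_attend: np.ndarray,
    u_psa: np.ndarray,
    u_mri: np.ndarray,
    u_comp: np.ndarray,
    u_bx: np.ndarray,
    u_mis_screen: np.ndarray,
    u_mis_clinical: float,
) -> ScreenOutcome:
    """Overlay the screening protocol on one man's natural history.

    Screens are only held strictly before ``min(clinical_dx_age,
    other_cause_death_age)``; the first detecting episode stops screening.
    Clinical presentation (in either pathway) is diagnosed with certainty at
    ``clinical_dx_age`` and graded by a TRUSGB-characteristics biopsy.
    A negative episode carries no memory to the next round.
    """
    out = ScreenOutcome()
    pathway = protocol.pathway
    dx = history.clinical_dx_age if history.clinical_dx_age is not None else math.inf
    horizon = min(dx, history.other_cause_death_age)

    if pathway in PATHWAYS:
        for k, age in enumerate(screen_ages(protocol)):
            if age >= horizon:
                break
            if u_attend[k] >= protocol.attendance:
                continue
            out.n_screens_attended += 1
            st = state_at(history, age)
            if st is None:
                continue
            if u_psa[k] < tests.psa_prob(st):
                out.n_psa_positive += 1
            grade = grade_class(st)
            mri_pos = pathway != "mri" or u_mri[k] < tests.mpmri_sens(grade)
            if u_psa[k] < tests.psa_prob(st) and mri_pos and u_comp[k] < tests.biopsy_compliance:
                out.n_screen_biopsies += 1
            if not screen_episode_detects(st, pathway, tests, EpisodeDraws(u_psa[k], u_mri[k], u_comp[k], u_bx[k])):
                continue
            rate = tests.misclass_mrigb if pathway == "mri" else tests.misclass_regular
            out.detected = True
            out.mode = "screen"
            out.detection_age = age
            out.state_at_detection = st
            out.true_grade = grade
            out.recorded_grade = misclassify(grade, rate, u_mis_screen[k])
            out.lead_time = (dx - age) if math.isfinite(dx) else math.inf
            return out

    if history.clinical_dx_age is not None and history.clinical_dx_age < history.other_cause_death_age:
        st = history.state_at_clinical_dx
        out.detected = True
        out.mode = "clinical"
        out.detection_age = history.clinical_dx_age
        out.state_at_detection = st
        out.true_grade = grade_class(st)
        # clinical route uses TRUSGB characteristics in both pathways
        out.recorded_grade = misclassify(out.true_grade, tests.misclass_regular, u_mis_clinical)
        out.lead_time = 0.0
    return out


def expected_biopsies(
    screen_detections: float, clinical_detections: float, tests: TestParams, pathway: str
) -> BiopsyCount:
    """Convert detection counts into expected biopsy counts via the PPVs.

    Fractional expected counts are deliberately not rounded; they feed the
    per-1000 scaling directly.
    """
    if screen_detections < 0 or clinical_detections < 0:
        raise ValueError("detection counts must be non-negative")
    ppv_screen = tests.ppv_mri if pathway == "mri" else tests.ppv_screen_regular
    if screen_detections > 0 and ppv_screen <= 0:
        raise ScreeningConfigError("screen PPV must be positive when screen detections occur")
    if clinical_detections > 0 and tests.ppv_clinical <= 0:
        raise ScreeningConfigError("clinical PPV must be positive when clinical detections occur")
    screen_b = screen_detections / ppv_screen if screen_detections > 0 else 0.0
    clinical_b = clinical_detections / tests.ppv_clinical if clinical_detections > 0 else 0.0
    return BiopsyCount(screen_biopsies=screen_b, clinical_biopsies=clinical_b)
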