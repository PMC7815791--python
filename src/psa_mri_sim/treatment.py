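"""Treatment assignment and prostate-cancer mortality.

After detection a man is assigned radical prostatectomy (RP), radiation
therapy (RT), active surveillance (AS) or — always, for metastasised
disease — palliative treatment.  Assignment depends on age band, T stage,
*recorded* Gleason grade and metastasis, so biopsy grade misclassification
propagates into under- or overtreatment.

Survival after a clinical diagnosis is drawn from a parametric baseline
(default: exponential per true grade x metastasis).  RP and RT act as a
proportional hazard (default hazard ratio 0.56, identical for both); AS and
palliative treatment leave survival unchanged.

Screening's mortality benefit is a lead-time-dependent cure: a
screen-detected, non-metastatic man is cured with probability
``c(L) = c_max * (1 - exp(-lambda * L))`` for lead time ``L``.  A cured man
never dies of prostate cancer; an uncured man keeps exactly the death date
and cause he would have had without screening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .natural_history import LifeHistory
from .screening import ScreenOutcome
from .states import PreclinicalState, grade_class

TREATMENTS = ("RP", "RT", "AS", "palliative")


class TreatmentConfigError(ValueError):
    pass


def _row_key(age_band: str, t_stage: str, grade: str, metastasis: str) -> str:
    return f"{age_band}|{t_stage}|{grade}|{metastasis}"


@dataclass(frozen=True)
class TreatmentParams:
    """Assignment table, treatment effects, baseline survival and cure model.

    ``assignment_table`` maps ``"<age_band>|<t_stage>|<grade>|<M>"`` (grade is
    the recorded one) to a distribution over treatments.  Age bands are
    ``"lt<cut>"`` / ``"ge<cut>"`` around ``age_band_cutoff``.
    ``baseline_survival_rates`` maps ``"<true grade>_<M>"`` to an exponential
    rate (per year) of prostate-cancer death after clinical diagnosis.
    """

    assignment_table: dict[str, dict[str, float]] = field(default_factory=dict)
    age_band_cutoff: float = 70.0
    hr_rp: float = 0.56
    hr_rt: float = 0.56
    baseline_survival_rates: dict[str, float] = field(default_factory=dict)
    cure_cmax: float = 0.85
    cure_lambda: float = 0.25
    cure_m1_eligible: bool = False

    def __post_init__(self) -> None:
        for hr_name in ("hr_rp", "hr_rt"):
            hr = getattr(self, hr_name)
            if not (0.0 < hr <= 1.0):
                raise TreatmentConfigError(f"treatment.{hr_name} must lie in (0, 1]")
        if not (0.0 <= self.cure_cmax <= 1.0):
            raise TreatmentConfigError("treatment.cure_cmax must lie in [0, 1]")
        if self.cure_lambda < 0:
            raise TreatmentConfigError("treatment.cure_lambda must be non-negative")
        for key, row in self.assignment_table.items():
            total = sum(row.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise TreatmentConfigError(f"assignment row {key!r} sums to {total}, not 1")
            for tr, p in row.items():
                if tr not in TREATMENTS:
                    raise TreatmentConfigError(f"unknown treatment {tr!r} in row {key!r}")
                if p < 0:
                    raise TreatmentConfigError(f"negative probability in row {key!r}")
            if key.endswith("|M1") and row.get("palliative", 0.0) != 1.0:
                raise TreatmentConfigError(f"M1 row {key!r} must assign palliative with probability 1")
        for key, r in self.baseline_survival_rates.items():
            if r < 0:
                raise TreatmentConfigError(f"negative baseline survival rate for {key!r}")

    def age_band(self, age: float) -> str:
        cut = int(self.age_band_cutoff)
        return f"lt{cut}" if age < self.age_band_cutoff else f"ge{cut}"

    def survival_rate(self, state: PreclinicalState) -> float:
        key = f"{grade_class(state)}_{state.metastasis}"
        try:
            return self.baseline_survival_rates[key]
        except KeyError:
            raise TreatmentConfigError(f"no baseline survival rate for {key!r}") from None


@dataclass
class MortalityOutcome:
    """Death ages and causes in the screen arm and its no-screening counterfactual."""

    pca_death_age_noscreen: float | None
    pca_death_age_screen: float | None
    cured: bool
    death_age_noscreen: float
    death_age_screen: float
    cause_noscreen: str  # prostate_cancer | other
    cause_screen: str


def assign_treatment(
    age: float,
    state: PreclinicalState,
    recorded_grade: str,
    params: TreatmentParams,
    u: float,
) -> str:
    """Categorical draw from the assignment row (CDF order RP < RT < AS < palliative)."""
    key = _row_key(params.age_band(age), state.t_stage, recorded_grade, state.metastasis)
    row = params.assignment_table.get(key)
    if row is None:
        raise TreatmentConfigError(f"no treatment assignment row for {key!r}")
    acc = 0.0
    for tr in TREATMENTS:
        acc += row.get(tr, 0.0)
        if u < acc:
            return tr
    return TREATMENTS[-1]


def pca_survival_after_clinical_dx(
    state: PreclinicalState,
    age: float,
    treatment: str,
    params: TreatmentParams,
    u: float,
) -> float:
    """Years from clinical diagnosis to prostate-cancer death.

    Exponential baseline; RP/RT scale the hazard by their ratio, which for
    the exponential is the inverse-CDF transform ``t / hr``.
    """
    rate = params.survival_rate(state)
    if rate <= 0:
        return math.inf
    t = -math.log1p(-u) / rate
    if treatment == "RP":
        t /= params.hr_rp
    elif treatment == "RT":
        t /= params.hr_rt
    return t


def cure_probability(lead_time: float, params: TreatmentParams) -> float:
    """``c(L) = c_max (1 - e^{-lambda L})``: zero at L=0, saturating at c_max."""
    if lead_time < 0:
        raise ValueError("lead time must be non-negative")
    if math.isinf(lead_time):
        return params.cure_cmax if params.cure_lambda > 0 else 0.0
    return params.cure_cmax * -math.expm1(-params.cure_lambda * lead_time)


def resolve_mortality(
    history: LifeHistory,
    outcome_screen: ScreenOutcome,
    outcome_noscreen: ScreenOutcome,
    params: TreatmentParams,
    *,
    u_treat: float,
    u_surv: float,
    u_cure: float,
) -> MortalityOutcome:
    """Resolve death age and cause in both counterfactual arms of one man.

    The survival uniform ``u_surv`` is shared between arms: an uncured
    screen-detected man dies on exactly the date he would have died without
    screening.  The latent prostate-cancer death date is anchored at the
    *clinical* diagnosis age with the treatment that a clinical presentation
    would have received, so it is identical across arms by construction.
    """
    ocd = history.other_cause_death_age
    dx = history.clinical_dx_age

    latent_pca_death: float | None = None
    if dx is not None:
        # Treatment the man would receive at clinical presentation; the
        # recorded grade comes from the (arm-shared) clinical-route biopsy.
        rec = outcome_noscreen.recorded_grade
        if rec is None:
            # clinical dx would fall after other-cause death; grade the
            # counterfactual presentation by its true state (no biopsy ever
            # happens, so no misclassification draw is consumed).
            rec = grade_class(history.state_at_clinical_dx)
        tr = assign_treatment(dx, history.state_at_clinical_dx, rec, params, u_treat)
        latent_pca_death = dx + pca_survival_after_clinical_dx(
            history.state_at_clinical_dx, dx, tr, params, u_surv
        )

    # --- no-screening arm ---
    pca_ns = latent_pca_death if (dx is not None and dx < ocd) else None
    if pca_ns is not None and pca_ns >= ocd:
        pca_ns_effective = None  # dies of other causes first
    else:
        pca_ns_effective = pca_ns

    # --- screen arm ---
    cured = False
    if outcome_screen.mode == "screen":
        st = outcome_screen.state_at_detection
        if st.metastasis == "M0" or params.cure_m1_eligible:
            cured = u_cure < cure_probability(outcome_screen.lead_time, params)
        pca_s_effective = None if cured else pca_ns_effective
    else:
        pca_s_effective = pca_ns_effective

    death_ns = min(ocd, pca_ns_effective) if pca_ns_effective is not None else ocd
    death_s = min(ocd, pca_s_effective) if pca_s_effective is not None else ocd
    return MortalityOutcome(
        pca_death_age_noscreen=pca_ns_effective,
        pca_death_age_screen=pca_s_effective,
        cured=cured,
        death_age_noscreen=death_ns,
        death_age_screen=death_s,
        cause_noscreen="prostate_cancer" if pca_ns_effective is not None else "other",
        cause_screen="prostate_cancer" if pca_s_effective is not None else "other",
    )
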