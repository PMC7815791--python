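"""Paired three-arm simulation and per-1000 outcome accounting.

The same cohort of life histories is evaluated under three arms — no
screening, the regular PSA->TRUSGB pathway and the PSA->mpMRI->MRIGB
pathway — with every shared random draw held in common, so arm differences
isolate the effect of the pathway.  Aggregates are scaled to a cohort of
1000 men and assembled into the published comparison layout: differences,
percent changes, harm–benefit ratios (overdiagnosed cases per
prostate-cancer death averted) and per-death-averted life-year/QALY gains.

Percent changes follow the convention that reproduces every consistent
printed value: magnitude ``|regular - mri| / max(regular, mri) * 100`` with
the sign of ``mri - regular``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .demography import Person, sample_death_ages
from .natural_history import LifeHistory, simulate_cohort_histories
from .rng import draw_cohort_uniforms
from .screening import (
    ScreenOutcome,
    ScreeningProtocol,
    expected_biopsies,
    screen_ages,
    simulate_screening,
)
from .states import grade_class
from .treatment import assign_treatment, resolve_mortality

ARMS = ("noscreen", "regular", "mri")

#: Sentinel reported when deaths averted are non-positive and a ratio is undefined.
UNDEFINED_RATIO = float("nan")


class UtilityConfigError(ValueError):
    pass


@dataclass(frozen=True)
class UtilityEntry:
    """Utility weight of a health state held for a fixed duration (years)."""

    label: str
    utility: float
    duration: float

    def __post_init__(self) -> None:
        if self.utility > 1.0:
            raise UtilityConfigError(f"utility for {self.label!r} exceeds 1")
        if self.duration <= 0:
            raise UtilityConfigError(f"duration for {self.label!r} must be positive")

    @property
    def loss_if_complete(self) -> float:
        return (1.0 - self.utility) * self.duration


class UtilityTable:
    """Lookup of :class:`UtilityEntry` by label.

    The MRIGB biopsy entry, if absent, is derived from the TRUSGB entry
    with half its disutility at the same duration.
    """

    def __init__(self, entries: list[UtilityEntry]):
        self.entries = {e.label: e for e in entries}
        if "mrigb_biopsy" not in self.entries and "trusgb_biopsy" in self.entries:
            tr = self.entries["trusgb_biopsy"]
            self.entries["mrigb_biopsy"] = UtilityEntry(
                "mrigb_biopsy", 1.0 - 0.5 * (1.0 - tr.utility), tr.duration
            )

    def __getitem__(self, label: str) -> UtilityEntry:
        try:
            return self.entries[label]
        except KeyError:
            raise UtilityConfigError(f"no utility entry for health state {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self.entries


# aliases resolved per pathway at lookup time
_PATHWAY_ALIASES = {
    ("screen_biopsy", "regular"): "trusgb_biopsy",
    ("screen_biopsy", "mri"): "mrigb_biopsy",
    ("clinical_biopsy", "regular"): "trusgb_biopsy",
    ("clinical_biopsy", "mri"): "trusgb_biopsy",
    ("clinical_biopsy", "noscreen"): "trusgb_biopsy",
}


def compute_utility_loss(
    events: list[tuple[str, float]],
    utilities: UtilityTable,
    pathway: str = "regular",
    death_age: float = math.inf,
) -> float:
    """Sum of ``(1 - utility) x duration`` over events, truncated at death.

    Events are ``(health_state_label, start_age)``; a state entered at or
    after death contributes nothing, a state outlasting death contributes
    only the lived fraction.
    """
    total = 0.0
    for label, age in events:
        label = _PATHWAY_ALIASES.get((label, pathway), label)
        entry = utilities[label]
        lived = min(entry.duration, death_age - age)
        if lived > 0:
            total += (1.0 - entry.utility) * lived
    return total


def classify_overdiagnosed(history: LifeHistory, outcome: ScreenOutcome) -> bool:
    """Screen-detected, but clinical diagnosis would never occur in his lifetime."""
    if outcome.mode != "screen":
        return False
    dx = history.clinical_dx_age
    return dx is None or dx > history.other_cause_death_age


def percent_change(regular_value: float, mri_value: float) -> float:
    """Signed percent on the larger-denominator convention (see module docstring)."""
    big = max(regular_value, mri_value)
    if big <= 0:
        if regular_value == mri_value == 0:
            return 0.0
        raise ValueError("percent_change requires at least one positive value")
    magnitude = abs(regular_value - mri_value) / big * 100.0
    return math.copysign(magnitude, mri_value - regular_value) if magnitude else 0.0


@dataclass
class ArmResult:
    """Per-1000 aggregated outcomes of one arm."""

    arm: str
    men_biopsied: float
    insignificant_detected: float
    significant_detected: float
    screen_detected: float
    clinically_detected: float
    overdiagnosed: float
    pca_deaths: float
    life_years: float
    utility_loss: float

    @property
    def total_detected(self) -> float:
        return self.insignificant_detected + self.significant_detected

    @property
    def qalys(self) -> float:
        return self.life_years - self.utility_loss


@dataclass
class PersonArmRecord:
    """Minimal per-man, per-arm record kept for matched comparisons."""

    mode: str
    detection_age: float | None
    lead_time: float | None
    true_grade: str | None
    recorded_grade: str | None
    overdiagnosed: bool
    death_age: float
    cause: str
    utility_loss: float
    n_screens_attended: int
    n_psa_positive: int


@dataclass
class PersonRecord:
    person_id: int
    arms: dict[str, PersonArmRecord]


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED_RATIO


@dataclass
class ComparisonSummary:
    """The two-pathway comparison in the published layout.

    ``rows`` maps metric name to ``{"regular", "mri", "difference",
    "percent_change"}`` where ``difference`` is the printed magnitude
    ``|regular - mri|`` and ``percent_change`` is signed.
    """

    rows: dict[str, dict[str, float]] = field(default_factory=dict)
    deaths_averted_regular: float = 0.0
    deaths_averted_mri: float = 0.0
    harm_benefit_regular: float = UNDEFINED_RATIO
    harm_benefit_mri: float = UNDEFINED_RATIO
    pct_significant_missed: float | None = None


def derive_comparison(values: dict[str, dict[str, float]]) -> ComparisonSummary:
    """Derived-metric arithmetic from per-pathway inputs.

    ``values`` supplies, per metric, ``{"regular": x, "mri": y}`` for the
    base metrics ``men_biopsied``, ``insignificant_detected``,
    ``significant_detected``, ``overdiagnosed``, ``deaths_averted``,
    ``life_years_gained``, ``qalys_gained``.  Harm–benefit and
    per-death-averted ratios are derived, and every row gets the printed
    difference and percent-change convention.  This is exactly the
    computation behind ``psa-mri-sim table2 --from-values``.
    """
    summary = ComparisonSummary()
    vals = {k: dict(v) for k, v in values.items()}
    da = vals.get("deaths_averted")
    if da:
        summary.deaths_averted_regular = da["regular"]
        summary.deaths_averted_mri = da["mri"]
        if "overdiagnosed" in vals:
            summary.harm_benefit_regular = _ratio(vals["overdiagnosed"]["regular"], da["regular"])
            summary.harm_benefit_mri = _ratio(vals["overdiagnosed"]["mri"], da["mri"])
            vals["overdiagnosed_per_death_averted"] = {
                "regular": summary.harm_benefit_regular,
                "mri": summary.harm_benefit_mri,
            }
        if "life_years_gained" in vals:
            vals["ly_gained_per_death_averted"] = {
                p: _ratio(vals["life_years_gained"][p], da[p]) for p in ("regular", "mri")
            }
        if "qalys_gained" in vals:
            vals["qaly_gained_per_death_averted"] = {
                p: _ratio(vals["qalys_gained"][p], da[p]) for p in ("regular", "mri")
            }
    for name, pair in vals.items():
        r, m = pair["regular"], pair["mri"]
        row = {"regular": r, "mri": m, "difference": abs(r - m)}
        try:
            row["percent_change"] = percent_change(r, m)
        except ValueError:
            row["percent_change"] = UNDEFINED_RATIO
        if not (math.isfinite(r) and math.isfinite(m)):
            row["percent_change"] = UNDEFINED_RATIO
        summary.rows[name] = row
    return summary


# ---------------------------------------------------------------------------
# paired simulation
# ---------------------------------------------------------------------------


def _arm_events(
    outcome: ScreenOutcome,
    mort_pca_death: float | None,
    death_age: float,
    treatment: str | None,
    arm: str,
) -> list[tuple[str, float]]:
    """Per-man utility events for one arm (screening-episode and biopsy
    disutilities are handled at the aggregate level)."""
    events: list[tuple[str, float]] = []
    if outcome.n_screens_attended:
        events += [("screening_attendance", 0.0)] * outcome.n_screens_attended
    if arm == "mri" and outcome.n_psa_positive:
        events += [("mpmri", 0.0)] * outcome.n_psa_positive
    if outcome.detected:
        events.append(("diagnosis", outcome.detection_age))
        if treatment is not None:
            events.append((f"treatment_{treatment.lower()}", outcome.detection_age))
    if mort_pca_death is not None:
        events.append(("palliative_therapy", mort_pca_death - 2.5))
        events.append(("terminal_illness", mort_pca_death - 0.5))
    return events


def run_paired_simulation(n: int, config, seed: int | None = None):
    """Simulate the cohort once and evaluate all three arms under CRN.

    Parameters
    ----------
    n
        Cohort size (number of men simulated; results are scaled per 1000).
    config
        A resolved :class:`~psa_mri_sim.config.RunConfig`.
    seed
        Master seed; defaults to ``config.seed``.

    Returns
    -------
    (ArmResult, ArmResult, ArmResult, list[PersonRecord], ComparisonSummary)
        Results for the no-screening, regular and MRI arms, the per-man
        records, and the assembled comparison.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    seed = config.seed if seed is None else int(seed)
    protocol_reg = replace(config.protocol, pathway="regular")
    protocol_mri = replace(config.protocol, pathway="mri")
    protocol_none = replace(config.protocol, pathway="none")
    k = len(screen_ages(config.protocol))
    tests, tparams, utilities = config.tests, config.treatment, config.utilities

    draws = draw_cohort_uniforms(seed, n, k)
    death_ages = sample_death_ages(config.life_table, draws.other_cause_death)
    persons = [Person(i, float(death_ages[i])) for i in range(n)]
    histories = simulate_cohort_histories(config.natural_history, persons, seed)

    records: list[PersonRecord] = []
    for i, hist in enumerate(histories):
        kw = dict(
            u_attend=draws.attendance[i],
            u_psa=draws.psa[i],
            u_mri=draws.mpmri[i],
            u_comp=draws.compliance[i],
            u_bx=draws.biopsy[i],
            u_mis_screen=draws.misclassification_screen[i],
            u_mis_clinical=draws.misclassification_clinical[i],
        )
        out_none = simulate_screening(hist, protocol_none, tests, **kw)
        out_reg = simulate_screening(hist, protocol_reg, tests, **kw)
        out_mri = simulate_screening(hist, protocol_mri, tests, **kw)

        mort_reg = resolve_mortality(
            hist, out_reg, out_none, tparams,
            u_treat=draws.treatment[i], u_surv=draws.survival[i], u_cure=draws.cure[i],
        )
        mort_mri = resolve_mortality(
            hist, out_mri, out_none, tparams,
            u_treat=draws.treatment[i], u_surv=draws.survival[i], u_cure=draws.cure[i],
        )

        arm_rec: dict[str, PersonArmRecord] = {}
        for arm, out, pca_death, death_age, cause in (
            ("noscreen", out_none, mort_reg.pca_death_age_noscreen,
             mort_reg.death_age_noscreen, mort_reg.cause_noscreen),
            ("regular", out_reg, mort_reg.pca_death_age_screen,
             mort_reg.death_age_screen, mort_reg.cause_screen),
            ("mri", out_mri, mort_mri.pca_death_age_screen,
             mort_mri.death_age_screen, mort_mri.cause_screen),
        ):
            treatment = None
            if out.detected:
                treatment = assign_treatment(
                    out.detection_age, out.state_at_detection, out.recorded_grade,
                    tparams, draws.treatment[i],
                )
            events = _arm_events(out, pca_death, death_age, treatment, arm)
            uloss = compute_utility_loss(events, utilities, arm if arm != "noscreen" else "regular", death_age)
            overdx = classify_overdiagnosed(hist, out)
            arm_rec[arm] = PersonArmRecord(
                mode=out.mode,
                detection_age=out.detection_age,
                lead_time=out.lead_time,
                true_grade=out.true_grade,
                recorded_grade=out.recorded_grade,
                overdiagnosed=overdx,
                death_age=death_age,
                cause=cause,
                utility_loss=uloss,
                n_screens_attended=out.n_screens_attended,
                n_psa_positive=out.n_psa_positive,
            )
        records.append(PersonRecord(i, arm_rec))

    results = {arm: summarize_arm(records, arm, tests, utilities) for arm in ARMS}
    summary = compare(results["noscreen"], results["regular"], results["mri"], records)
    return results["noscreen"], results["regular"], results["mri"], records, summary


def summarize_arm(
    records: list[PersonRecord], arm: str, tests, utilities: UtilityTable
) -> ArmResult:
    """Aggregate one arm's per-man records into per-1000 outcomes.

    Biopsy counts (and their disutility) are the PPV-scaled expected values
    derived from detections; everything else is a direct tally.
    """
    n = len(records)
    if n == 0:
        raise ValueError("no records to summarize")
    screen_det = clin_det = insig = sig = overdx = pca_deaths = 0
    life_years = uloss = 0.0
    for rec in records:
        a = rec.arms[arm]
        screen_det += a.mode == "screen"
        clin_det += a.mode == "clinical"
        if a.recorded_grade is not None:
            if a.recorded_grade == "high":
                sig += 1
            else:
                insig += 1
        overdx += a.overdiagnosed
        pca_deaths += a.cause == "prostate_cancer"
        life_years += a.death_age
        uloss += a.utility_loss
    pathway = "mri" if arm == "mri" else "regular"
    biopsies = expected_biopsies(screen_det, clin_det, tests, pathway)
    # aggregate biopsy disutility (PPV-scaled: includes negative biopsies)
    bx_screen = utilities["mrigb_biopsy" if arm == "mri" else "trusgb_biopsy"]
    bx_clin = utilities["trusgb_biopsy"]
    uloss += (
        biopsies.screen_biopsies * bx_screen.loss_if_complete
        + biopsies.clinical_biopsies * bx_clin.loss_if_complete
    )
    scale = 1000.0 / n
    return ArmResult(
        arm=arm,
        men_biopsied=biopsies.total * scale,
        insignificant_detected=insig * scale,
        significant_detected=sig * scale,
        screen_detected=screen_det * scale,
        clinically_detected=clin_det * scale,
        overdiagnosed=overdx * scale,
        pca_deaths=pca_deaths * scale,
        life_years=life_years * scale,
        utility_loss=uloss * scale,
    )


def pct_significant_missed(records: list[PersonRecord]) -> float | None:
    """Recorded-significant screen detections present in the regular arm but
    missed (not screen-detected as significant) in the MRI arm, man-matched."""
    sig_reg = [
        r for r in records
        if r.arms["regular"].mode == "screen" and r.arms["regular"].recorded_grade == "high"
    ]
    if not sig_reg:
        return None
    missed = sum(
        1 for r in sig_reg
        if not (r.arms["mri"].mode == "screen" and r.arms["mri"].recorded_grade == "high")
    )
    return 100.0 * missed / len(sig_reg)


def compare(
    noscreen: ArmResult,
    regular: ArmResult,
    mri: ArmResult,
    records: list[PersonRecord] | None = None,
) -> ComparisonSummary:
    """Assemble the published-layout comparison from the three arm results."""
    values = {
        "men_biopsied": {"regular": regular.men_biopsied, "mri": mri.men_biopsied},
        "insignificant_detected": {
            "regular": regular.insignificant_detected, "mri": mri.insignificant_detected
        },
        "significant_detected": {
            "regular": regular.significant_detected, "mri": mri.significant_detected
        },
        "overdiagnosed": {"regular": regular.overdiagnosed, "mri": mri.overdiagnosed},
        "deaths_averted": {
            "regular": noscreen.pca_deaths - regular.pca_deaths,
            "mri": noscreen.pca_deaths - mri.pca_deaths,
        },
        "life_years_gained": {
            "regular": regular.life_years - noscreen.life_years,
            "mri": mri.life_years - noscreen.life_years,
        },
        "qalys_gained": {
            "regular": regular.qalys - noscreen.qalys,
            "mri": mri.qalys - noscreen.qalys,
        },
    }
    summary = derive_comparison(values)
    if records is not None:
        summary.pct_significant_missed = pct_significant_missed(records)
    return summary
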