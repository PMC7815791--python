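"""Run configuration: YAML parsing, validation and hashing.

A run configuration is a plain nested mapping (YAML on disk) that resolves
into typed, validated parameter objects before any simulation starts.
Validation errors name the offending field path.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import yaml

from .demography import LifeTable, load_life_table
from .natural_history import NaturalHistoryParams
from .outcomes import UtilityEntry, UtilityTable
from .screening import ScreeningProtocol, TestParams
from .treatment import TreatmentParams


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved and validated run configuration."""

    cohort_size: int
    seed: int
    life_table: LifeTable
    natural_history: NaturalHistoryParams
    protocol: ScreeningProtocol
    tests: TestParams
    treatment: TreatmentParams
    utilities: UtilityTable
    raw: dict

    @property
    def config_hash(self) -> str:
        return hash_config(self.raw)


def hash_config(raw: dict) -> str:
    """Content hash of the resolved configuration (order-insensitive)."""
    blob = json.dumps(raw, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _life_table_from_spec(spec: dict) -> LifeTable:
    kind = spec.get("kind", "gompertz_makeham")
    if kind == "gompertz_makeham":
        from . import synthetic

        a = spec.get("makeham_a", synthetic.GM_A)
        b = spec.get("gompertz_b", synthetic.GM_B)
        c = spec.get("gompertz_c", synthetic.GM_C)
        max_age = int(spec.get("max_age", synthetic.LIFE_TABLE_MAX_AGE))
        ages = np.arange(max_age + 1)
        cum = a + b / c * (np.exp(c * (ages + 1)) - np.exp(c * ages))
        qx = 1.0 - np.exp(-cum)
        qx[-1] = 1.0
        return LifeTable(ages=ages, qx=qx)
    if kind == "explicit":
        return LifeTable(ages=np.asarray(spec["ages"]), qx=np.asarray(spec["qx"]))
    if kind == "csv":
        return load_life_table(spec["path"])
    raise ConfigError(f"life_table.kind {kind!r} is not one of gompertz_makeham|explicit|csv")


def resolve_config(raw: dict) -> RunConfig:
    """Validate a raw configuration mapping into a :class:`RunConfig`.

    Every module's own validator runs here; the first violated invariant
    raises :class:`ConfigError` naming the configuration section.
    """
    try:
        cohort_size = int(raw.get("cohort_size", 100_000))
        seed = int(raw.get("seed", 0))
        if cohort_size < 1:
            raise ConfigError("cohort_size must be at least 1")
    except (TypeError, ValueError) as e:
        raise ConfigError(f"cohort_size/seed: {e}") from e

    def section(name: str, builder):
        try:
            return builder(raw.get(name, {}) or {})
        except ConfigError:
            raise
        except (ValueError, KeyError, TypeError) as e:
            raise ConfigError(f"{name}: {e}") from e

    life_table = section("life_table", _life_table_from_spec)

    def build_nh(d: dict) -> NaturalHistoryParams:
        return NaturalHistoryParams(
            onset_shape=float(d.get("onset_shape", 5.0)),
            onset_scale=float(d.get("onset_scale", float("inf"))),
            onset_fixed_age=d.get("onset_fixed_age"),
            max_onset_age=float(d.get("max_onset_age", 100.0)),
            entry_state_probs=dict(d.get("entry_state_distribution", {})),
            progression_rates={k: dict(v) for k, v in d.get("progression_rates", {}).items()},
            clinical_dx_rates=dict(d.get("clinical_dx_rates", {})),
        )

    natural_history = section("natural_history", build_nh)

    def build_protocol(d: dict) -> ScreeningProtocol:
        return ScreeningProtocol(
            start_age=float(d.get("start_age", 55.0)),
            stop_age=float(d.get("stop_age", 64.0)),
            interval=float(d.get("interval", 3.0)),
            attendance=float(d.get("attendance", 0.80)),
            pathway=d.get("pathway", "regular"),
        )

    protocol = section("screening", build_protocol)

    def build_tests(d: dict) -> TestParams:
        known = {
            "psa_pos_prob", "trusgb_sens", "biopsy_compliance", "mpmri_sens_low",
            "mpmri_sens_high", "mrigb_sens_low", "mrigb_sens_high", "misclass_regular",
            "misclass_mrigb", "ppv_screen_regular", "ppv_clinical", "ppv_mri",
        }
        extra = set(d) - known
        if extra:
            raise ConfigError(f"tests: unknown keys {sorted(extra)}")
        return TestParams(**d)

    tests = section("tests", build_tests)

    def build_treatment(d: dict) -> TreatmentParams:
        return TreatmentParams(
            assignment_table={k: dict(v) for k, v in d.get("assignment_table", {}).items()},
            age_band_cutoff=float(d.get("age_band_cutoff", 70.0)),
            hr_rp=float(d.get("hr_rp", 0.56)),
            hr_rt=float(d.get("hr_rt", 0.56)),
            baseline_survival_rates=dict(d.get("baseline_survival_rates", {})),
            cure_cmax=float(d.get("cure_cmax", 0.85)),
            cure_lambda=float(d.get("cure_lambda", 0.25)),
            cure_m1_eligible=bool(d.get("cure_m1_eligible", False)),
        )

    treatment = section("treatment", build_treatment)

    def build_utilities(entries) -> UtilityTable:
        if isinstance(entries, dict):
            entries = entries.get("entries", [])
        return UtilityTable(
            [UtilityEntry(e["label"], float(e["utility"]), float(e["duration"])) for e in entries]
        )

    utilities = section("utilities", build_utilities)

    return RunConfig(
        cohort_size=cohort_size,
        seed=seed,
        life_table=life_table,
        natural_history=natural_history,
        protocol=protocol,
        tests=tests,
        treatment=treatment,
        utilities=utilities,
        raw=raw,
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration file {path} did not parse to a mapping")
    return resolve_config(raw)


def dump_config(raw: dict) -> str:
    """Serialize a raw configuration mapping to YAML (round-trip stable)."""
    return yaml.safe_dump(raw, sort_keys=True, default_flow_style=False)
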