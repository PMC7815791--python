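"""One-way (tornado) and simultaneous threshold sensitivity analyses.

The tornado analysis perturbs each of the four MRI-pathway test
sensitivities to the endpoints of its published 95% CI / range, reruns the
paired simulation under the same master seed, and reports the harm–benefit
ratio (overdiagnosed per death averted) of the MRI pathway at each bound.

The threshold analysis transforms all four sensitivities simultaneously by
a *relative* factor delta — low-grade sensitivities scaled by ``1 + delta``
(capped at 1), high-grade by ``1 - delta`` — and scans QALYs gained per
death averted for a crossing between the two pathways.  At delta = 0.14
this transformation maps 0.94 -> 0.81, 0.91 -> 0.78, 0.74 -> 0.84 and
0.44 -> 0.50 (as printed), which is why the relative reading is used.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .outcomes import UNDEFINED_RATIO, run_paired_simulation
from .screening import TestParams

#: Published 95% CI / range endpoints of the four MRI-pathway sensitivities.
DEFAULT_TORNADO_BOUNDS: dict[str, tuple[float, float]] = {
    "mpmri_sens_high": (0.70, 0.97),
    "mpmri_sens_low": (0.66, 0.81),
    "mrigb_sens_low": (0.26, 0.64),
    "mrigb_sens_high": (0.87, 0.94),
}


@dataclass(frozen=True)
class TornadoResult:
    parameter: str
    low_bound: float
    high_bound: float
    ratio_at_low: float
    ratio_at_high: float
    baseline_ratio: float

    @property
    def width(self) -> float:
        return abs(self.ratio_at_low - self.ratio_at_high)


@dataclass(frozen=True)
class ThresholdResult:
    delta_grid: tuple[float, ...]
    metric_regular: tuple[float, ...]
    metric_mri: tuple[float, ...]
    crossing_delta: float | None


def transform_sensitivities(tests: TestParams, delta: float) -> TestParams:
    """Relative, grade-opposed transformation of the MRI test sensitivities."""
    if not (0.0 <= delta < 1.0):
        raise ValueError("delta must lie in [0, 1)")
    return replace(
        tests,
        mpmri_sens_low=min(tests.mpmri_sens_low * (1.0 + delta), 1.0),
        mrigb_sens_low=min(tests.mrigb_sens_low * (1.0 + delta), 1.0),
        mpmri_sens_high=tests.mpmri_sens_high * (1.0 - delta),
        mrigb_sens_high=tests.mrigb_sens_high * (1.0 - delta),
    )


def _mri_harm_benefit(config, n: int, seed: int) -> float:
    *_, summary = run_paired_simulation(n, config, seed)
    return summary.harm_benefit_mri


def _with_tests(config, tests: TestParams):
    return replace(config, tests=tests)


def tornado(
    config,
    seed: int,
    n: int,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> list[TornadoResult]:
    """One-way scan of the MRI harm–benefit ratio over the sensitivity bounds.

    Every run reuses the same master seed (common random numbers), so a
    zero-width bound reproduces the baseline ratio exactly.  Results are
    sorted by bar width, widest first.
    """
    bounds = DEFAULT_TORNADO_BOUNDS if bounds is None else bounds
    baseline = _mri_harm_benefit(config, n, seed)
    results = []
    for param, (lo, hi) in bounds.items():
        if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
            raise ValueError(f"bounds for {param} must lie in [0, 1]")
        r_lo = _mri_harm_benefit(_with_tests(config, config.tests.with_updates(**{param: lo})), n, seed)
        r_hi = _mri_harm_benefit(_with_tests(config, config.tests.with_updates(**{param: hi})), n, seed)
        results.append(
            TornadoResult(
                parameter=param, low_bound=lo, high_bound=hi,
                ratio_at_low=r_lo, ratio_at_high=r_hi, baseline_ratio=baseline,
            )
        )
    results.sort(key=lambda r: r.width, reverse=True)
    return results


def threshold_scan(config, seed: int, n: int, delta_grid) -> ThresholdResult:
    """Scan QALYs gained per death averted over the simultaneous transformation.

    The regular pathway is unaffected by the MRI sensitivities, but each
    grid point reruns the full paired simulation with the same seed so both
    metrics come from identical draws.  ``crossing_delta`` is the linearly
    interpolated delta where the MRI metric first falls to the regular
    metric; ``None`` when the MRI pathway stays ahead over the whole grid.
    """
    deltas = [float(d) for d in delta_grid]
    if any(b <= a for a, b in zip(deltas, deltas[1:])):
        raise ValueError("delta_grid must be strictly ascending")
    met_reg, met_mri = [], []
    for d in deltas:
        cfg = _with_tests(config, transform_sensitivities(config.tests, d))
        *_, summary = run_paired_simulation(n, cfg, seed)
        row = summary.rows
        met_reg.append(row["qaly_gained_per_death_averted"]["regular"]
                       if "qaly_gained_per_death_averted" in row else UNDEFINED_RATIO)
        met_mri.append(row["qaly_gained_per_death_averted"]["mri"]
                       if "qaly_gained_per_death_averted" in row else UNDEFINED_RATIO)

    crossing = None
    diffs = [m - r for m, r in zip(met_mri, met_reg)]
    for i in range(1, len(deltas)):
        d0, d1 = diffs[i - 1], diffs[i]
        if d0 > 0 >= d1:
            crossing = deltas[i - 1] + (deltas[i] - deltas[i - 1]) * d0 / (d0 - d1)
            break
    return ThresholdResult(
        delta_grid=tuple(deltas),
        metric_regular=tuple(met_reg),
        metric_mri=tuple(met_mri),
        crossing_delta=crossing,
    )
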