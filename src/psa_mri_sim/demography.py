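"""Cohort demography: life tables and other-cause death ages.

Death from causes other than prostate cancer is sampled from an annual life
table of mortality probabilities ``qx``.  The table is understood as
*other-cause* mortality (all causes minus prostate cancer): prostate-cancer
death is modelled separately and must not be double counted.

All ages are continuous years from birth; within the year of death the death
time is uniform on ``[a, a + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class LifeTableError(ValueError):
    """Raised when a life table violates its invariants."""


@dataclass(frozen=True)
class LifeTable:
    """Annual other-cause mortality probabilities for ages ``0..max_age``.

    ``qx[a]`` is the probability of dying in year ``[a, a+1)`` conditional on
    being alive at age ``a``; ``qx[max_age]`` must be 1 so that every
    simulated man receives a finite death age.
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or qx.shape != ages.shape or len(ages) == 0:
            raise LifeTableError("ages and qx must be equal-length 1-d arrays")
        if ages[0] != 0 or np.any(np.diff(ages) != 1):
            bad = int(ages[0]) if ages[0] != 0 else int(ages[np.flatnonzero(np.diff(ages) != 1)[0] + 1])
            raise LifeTableError(f"ages must be contiguous from 0; offending age {bad}")
        out = (qx < 0) | (qx > 1)
        if np.any(out):
            row = int(np.flatnonzero(out)[0])
            raise LifeTableError(f"qx outside [0, 1] at age {ages[row]} (qx={qx[row]})")
        if qx[-1] != 1.0:
            raise LifeTableError(
                f"qx at max_age {ages[-1]} must equal 1 (got {qx[-1]}); death must be certain"
            )

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def survival_curve(self) -> np.ndarray:
        """``S[a] = P(alive at exact age a)`` for ``a = 0..max_age+1``; ``S[0]=1``."""
        return np.concatenate([[1.0], np.cumprod(1.0 - self.qx)])

    def life_expectancy(self) -> float:
        """Mean death age under the uniform within-year convention."""
        s = self.survival_curve()
        p_year = s[:-1] - s[1:]  # P(death in [a, a+1))
        return float(np.sum(p_year * (self.ages + 0.5)))


@dataclass(frozen=True)
class Person:
    """A simulated man: identifier plus his other-cause death age."""

    id: int
    other_cause_death_age: float = field(compare=False)

    def __post_init__(self) -> None:
        if not (self.other_cause_death_age > 0):
            raise ValueError("other_cause_death_age must be positive")


def load_life_table(path) -> LifeTable:
    """Read a life table from a CSV with header ``age,qx`` and validate it."""
    df = pd.read_csv(path)
    for col in ("age", "qx"):
        if col not in df.columns:
            raise LifeTableError(f"life table {path} is missing column {col!r}")
    return LifeTable(ages=df["age"].to_numpy(), qx=df["qx"].to_numpy())


def sample_other_cause_death_age(table: LifeTable, u: float) -> float:
    """Inverse-CDF sample of the death age for a uniform draw ``u`` in (0, 1).

    The discrete annual distribution is inverted and the same draw positions
    the death uniformly within its year, so the result is a deterministic,
    monotone function of ``u``.
    """
    if not (0.0 < u < 1.0):
        raise ValueError("u must lie strictly inside (0, 1)")
    s = table.survival_curve()
    cdf = 1.0 - s  # cdf[a] = P(death before exact age a)
    year = int(np.searchsorted(cdf[1:], u, side="left"))
    lo, hi = cdf[year], cdf[year + 1]
    frac = (u - lo) / (hi - lo) if hi > lo else 0.0
    return float(table.ages[year] + frac)


def build_cohort(n: int, table: LifeTable, seed: int) -> list[Person]:
    """``n`` men with independent life-table death ages; reproducible by seed."""
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xD3A0)))
    us = rng.uniform(size=n)
    return [Person(i, sample_other_cause_death_age(table, u)) for i, u in enumerate(us)]


def sample_death_ages(table: LifeTable, us: np.ndarray) -> np.ndarray:
    """Vectorised :func:`sample_other_cause_death_age` for an array of draws."""
    s = table.survival_curve()
    cdf = 1.0 - s
    years = np.searchsorted(cdf[1:], us, side="left")
    lo = cdf[years]
    hi = cdf[years + 1]
    width = np.where(hi > lo, hi - lo, 1.0)
    frac = np.where(hi > lo, (us - lo) / width, 0.0)
    return table.ages[years] + frac
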