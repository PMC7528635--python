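"""Synthetic CPT cohort generation.

Generates per-child record tables with the statistical structure that the
imbalance-correction pipeline assumes in observational CPT data:

* **across-level imbalance** - non-uniform frequencies of the four control
  factors (age 6-12, gender, day of week, time of day), e.g. most tests on
  Mondays and almost none on Saturdays;
* **within-level imbalance** - the ADHD fraction varies across factor groups,
  including degenerate groups (weekend testing only among controls, afternoon
  and evening testing almost exclusively among controls, a higher ADHD rate in
  boys);
* **diagnosis effects** on all four index z-scores, and a time-of-day trend on
  hyperactivity in both classes.

The four indices are drawn directly on the z-score scale: controls are
standard normal per index, children with ADHD are shifted by the configured
standardized effect sizes, and hyperactivity additionally carries a linear
time-of-day slope.  This makes the configured effects the exact population
values that the generator converges to, which is what the downstream
parameter-recovery checks require.  Trial-level realism lives in
:mod:`cptdetect.session`; see the methods note for why the two generators are
kept separate.

Defaults emulate the published cohort scale: 458 children, 213 with ADHD,
index effect sizes in the 0.5-0.8 SD range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

__all__ = ["CohortConfig", "ClassFractionRule", "simulate_cohort", "INDEX_COLUMNS", "FACTOR_COLUMNS"]

INDEX_COLUMNS = ("z_attention", "z_timeliness", "z_hyperactivity", "z_impulsiveness")
FACTOR_COLUMNS = ("age", "gender", "dow", "tod")

#: encodings used in cohort CSVs: gender 0=boy 1=girl; dow 1..7 (1=Sunday,
#: 6-7 = weekend); tod 1=morning 2=afternoon 3=evening
GENDER_LEVELS = (0, 1)
AGE_LEVELS = tuple(range(6, 13))
DOW_LEVELS = tuple(range(1, 8))
TOD_LEVELS = (1, 2, 3)


@dataclass(frozen=True)
class ClassFractionRule:
    """p(ADHD) override for records matching all listed factor conditions.

    ``where`` maps a factor column to the set of levels it must take, e.g.
    ``{"dow": {6, 7}}`` with ``p=0.0`` sends every weekend record to the
    control class.  Rules are applied in order; the first match wins.
    """

    where: Mapping[str, frozenset]
    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0,1], got {self.p}")

    def matches(self, row: Mapping[str, Any]) -> bool:
        return all(row[k] in v for k, v in self.where.items())


def _default_rules() -> tuple[ClassFractionRule, ...]:
    # weekend tests only among controls; afternoon/evening almost only
    # controls; boys carry a higher ADHD rate than girls on weekday mornings
    return (
        ClassFractionRule({"dow": frozenset({6, 7})}, 0.0),
        ClassFractionRule({"tod": frozenset({2, 3})}, 0.02),
        ClassFractionRule({"gender": frozenset({0})}, 0.80),
        ClassFractionRule({"gender": frozenset({1})}, 0.64),
    )


def _default_frequencies() -> dict[str, dict[int, float]]:
    return {
        "age": {a: 1.0 for a in AGE_LEVELS},
        "gender": {0: 0.583, 1: 0.417},
        # Mondays (dow=2) most frequent, Saturdays (dow=7) rare
        "dow": {1: 0.18, 2: 0.30, 3: 0.16, 4: 0.14, 5: 0.12, 6: 0.07, 7: 0.03},
        # morning-dominated administration
        "tod": {1: 0.70, 2: 0.20, 3: 0.10},
    }


@dataclass
class CohortConfig:
    """Population parameters of the synthetic cohort.

    index_effect_sizes
        Standardized mean shift of each index for the ADHD class, in the order
        attention, timeliness, hyperactivity, impulsiveness.  Negative shifts
        on attention/timeliness (worse performance), positive on
        hyperactivity/impulsiveness.
    tod_hyperactivity_slope
        Additive shift of z_hyperactivity per time-of-day level above morning
        (negative: activity decreases over the day), applied to both classes.
    """

    n_children: int = 458
    adhd_fraction: float = 213 / 458
    level_frequency_map: dict[str, dict[int, float]] = field(default_factory=_default_frequencies)
    class_fraction_map: tuple[ClassFractionRule, ...] = field(default_factory=_default_rules)
    index_effect_sizes: tuple[float, float, float, float] = (-0.8, -0.8, 0.6, 0.5)
    tod_hyperactivity_slope: float = -0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.adhd_fraction <= 1.0:
            raise ValueError("adhd_fraction must be in [0,1]")
        for factor, freqs in self.level_frequency_map.items():
            vals = np.array(list(freqs.values()), dtype=float)
            if (vals < 0).any() or vals.sum() <= 0:
                raise ValueError(f"frequencies for factor '{factor}' not normalizable")


def _sample_factor(rng: np.random.Generator, freqs: Mapping[int, float], n: int) -> np.ndarray:
    levels = np.array(list(freqs.keys()))
    p = np.array(list(freqs.values()), dtype=float)
    return rng.choice(levels, size=n, p=p / p.sum())


def simulate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Draw a cohort record table under the configured imbalance structure.

    Returns a DataFrame with columns child_id, age, gender, dow, tod, the four
    index z-scores and a ``diagnosis`` column coded ``"ADHD"``/``"control"``.
    Deterministic given ``config.seed``.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_children

    cols: dict[str, np.ndarray] = {}
    for factor in FACTOR_COLUMNS:
        cols[factor] = _sample_factor(rng, config.level_frequency_map[factor], n)

    p_adhd = np.full(n, config.adhd_fraction)
    for i in range(n):
        row = {f: cols[f][i] for f in FACTOR_COLUMNS}
        for rule in config.class_fraction_map:
            if rule.matches(row):
                p_adhd[i] = rule.p
                break
    adhd = rng.random(n) < p_adhd

    z = rng.standard_normal((n, 4))
    z[adhd] += np.asarray(config.index_effect_sizes, dtype=float)
    z[:, 2] += config.tod_hyperactivity_slope * (cols["tod"] - 1)

    df = pd.DataFrame(
        {
            "child_id": np.arange(n),
            "age": cols["age"].astype(int),
            "gender": cols["gender"].astype(int),
            "dow": cols["dow"].astype(int),
            "tod": cols["tod"].astype(int),
            **{c: z[:, j] for j, c in enumerate(INDEX_COLUMNS)},
            "diagnosis": np.where(adhd, "ADHD", "control"),
        }
    )
    return df
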