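"""Retrospective factorial audit of cohort imbalance.

Observational CPT cohorts are imbalanced in two distinct ways.  *Across-level*
imbalance: the control factors (age, gender, day of week, time of day) have
very unequal level frequencies.  *Within-level* imbalance: the diagnostic
class composition differs between factor levels, a self-selection-type bias
(e.g. weekend testing occurring only among controls).  Both bias any
classifier trained on the raw table.

The audit sorts records into the cells of the age x gender x DoW x ToD
cross-product, estimates the within-group ADHD effect on a composite
performance score, greedily merges groups whose effects are statistically
indistinguishable, and removes *degenerate* groups — those whose ADHD
fraction is 0 or 1, in which the class effect is unquantifiable.  The
resulting groups carry the ``n_i`` (size) and ``p_i`` (ADHD fraction)
statistics that drive the rebalancing weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FACTOR_COLUMNS, INDEX_COLUMNS

__all__ = [
    "FactorGroup",
    "GroupingResult",
    "assign_groups",
    "chi_square_imbalance",
    "estimate_group_effect",
    "merge_equal_groups",
    "filter_degenerate",
    "audit_cohort",
]

#: composite performance score = unweighted mean of the four index z-scores
def composite_score(records: pd.DataFrame) -> np.ndarray:
    return records[list(INDEX_COLUMNS)].to_numpy().mean(axis=1)


@dataclass
class FactorGroup:
    """One cell (or merged union of cells) of the factor cross-product."""

    key: tuple[tuple[int, int, int, int], ...]  # sorted (age, gender, dow, tod) cells
    member_ids: tuple = ()
    n_i: int = 0
    p_i: float = float("nan")
    effect: float = float("nan")
    effect_se: float = float("nan")

    @property
    def estimable(self) -> bool:
        return np.isfinite(self.effect) and np.isfinite(self.effect_se)


@dataclass
class GroupingResult:
    groups: list[FactorGroup]
    removed_groups: list[FactorGroup] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return sum(g.n_i for g in self.groups)

    @property
    def retained_fraction(self) -> float:
        total = self.n_retained + sum(g.n_i for g in self.removed_groups)
        return self.n_retained / total if total else float("nan")

    def retained_ids(self) -> list:
        out: list = []
        for g in self.groups:
            out.extend(g.member_ids)
        return out


def _group_stats(records: pd.DataFrame, ids: tuple) -> tuple[int, float]:
    sub = records.loc[list(ids)]
    n = len(sub)
    p = float((sub["diagnosis"] == "ADHD").mean()) if n else float("nan")
    return n, p


def assign_groups(records: pd.DataFrame) -> list[FactorGroup]:
    """Partition records into the non-empty cells of the factor cross-product.

    Records are indexed by ``child_id``; every record lands in exactly one
    group.  Raises on records with missing factor values, listing their ids.
    """
    if records.empty:
        return []
    missing = records[list(FACTOR_COLUMNS)].isna().any(axis=1)
    if missing.any():
        bad = records.loc[missing, "child_id"].tolist()
        raise ValueError(f"records with missing factor levels: {bad}")
    idx = records.set_index("child_id")
    groups = []
    for cell, sub in idx.groupby(list(FACTOR_COLUMNS), sort=True):
        ids = tuple(sub.index)
        n, p = len(sub), float((sub["diagnosis"] == "ADHD").mean())
        groups.append(FactorGroup(key=(tuple(int(c) for c in cell),), member_ids=ids, n_i=n, p_i=p))
    return groups


def chi_square_imbalance(records: pd.DataFrame, factor: str) -> tuple[float, int, float]:
    """Chi-square test of diagnosis composition across the levels of a factor.

    Builds the diagnosis x factor-level contingency table and applies the
    chi-square test of independence, with Yates continuity correction for
    2x2 tables (the convention behind the reported gender imbalance
    statistic).  Returns (statistic, dof, p-value).
    """
    table = pd.crosstab(records["diagnosis"], records[factor])
    if table.shape[0] < 2:
        raise ValueError("both diagnosis classes must be present")
    if table.shape[1] < 2:
        raise ValueError(f"factor '{factor}' must have >= 2 observed levels")
    correction = table.shape == (2, 2)
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=correction)
    return float(chi2), int(dof), float(p)


def estimate_group_effect(group: FactorGroup, records: pd.DataFrame) -> FactorGroup:
    """Estimate the within-group ADHD effect on the composite score.

    Effect = mean(composite | ADHD) - mean(composite | control), with the
    unpooled (Welch) standard error.  Groups with fewer than two members in
    either class are flagged inestimable (NaN effect) and bypass the merging
    test; the degenerate filter handles p_i in {0, 1}.
    """
    sub = records.loc[list(group.member_ids)]
    score = composite_score(sub)
    is_adhd = (sub["diagnosis"] == "ADHD").to_numpy()
    n1, n0 = int(is_adhd.sum()), int((~is_adhd).sum())
    if n1 < 2 or n0 < 2:
        group.effect = group.effect_se = float("nan")
        return group
    a, c = score[is_adhd], score[~is_adhd]
    group.effect = float(a.mean() - c.mean())
    group.effect_se = float(np.sqrt(a.var(ddof=1) / n1 + c.var(ddof=1) / n0))
    return group


def _pair_p_value(g1: FactorGroup, g2: FactorGroup) -> float:
    z = (g1.effect - g2.effect) / np.sqrt(g1.effect_se**2 + g2.effect_se**2)
    return float(2.0 * stats.norm.sf(abs(z)))


def _merge_pair(g1: FactorGroup, g2: FactorGroup, records: pd.DataFrame) -> FactorGroup:
    merged = FactorGroup(
        key=tuple(sorted(g1.key + g2.key)),
        member_ids=g1.member_ids + g2.member_ids,
    )
    merged.n_i, merged.p_i = _group_stats(records, merged.member_ids)
    return estimate_group_effect(merged, records)


def merge_equal_groups(
    groups: list[FactorGroup], records: pd.DataFrame, alpha: float = 0.05
) -> GroupingResult:
    """Greedily merge groups whose ADHD effects are statistically equal.

    Repeatedly applies a two-sample z-test to every pair of estimable groups
    and merges the pair with the largest p-value, recomputing the merged
    effect, until no pair has p > alpha.  Inestimable groups (a class with
    fewer than two members) are never candidates.  Ties in p-value are broken
    by the lexicographic order of group keys, making the procedure
    order-stable.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    groups = [estimate_group_effect(g, records) if not g.estimable else g for g in groups]
    groups = sorted(groups, key=lambda g: g.key)
    while True:
        best: tuple[float, int, int] | None = None
        for i in range(len(groups)):
            if not groups[i].estimable:
                continue
            for j in range(i + 1, len(groups)):
                if not groups[j].estimable:
                    continue
                p = _pair_p_value(groups[i], groups[j])
                if p > alpha and (best is None or p > best[0]):
                    best = (p, i, j)
        if best is None:
            break
        _, i, j = best
        merged = _merge_pair(groups[i], groups[j], records)
        groups = [g for k, g in enumerate(groups) if k not in (i, j)]
        groups.append(merged)
        groups.sort(key=lambda g: g.key)
    return GroupingResult(groups=groups)


def absorb_inestimable(
    groups: list[FactorGroup], records: pd.DataFrame
) -> list[FactorGroup]:
    """Attach inestimable groups to the most similar estimable group.

    Sparse cells of the cross-product often contain a single class (or a
    singleton class), so their ADHD effect is unconstrained — they are
    compatible with any effect and the equality test cannot reject a merge.
    Each such group is pooled, in deterministic key order, with the estimable
    group whose class-conditional mean composite score (for the class the
    sparse group actually contains) is nearest.  Pooling sparse cells this
    way keeps their records quantifiable instead of discarding them at the
    degenerate filter.  If no estimable group exists, groups are returned
    unchanged.
    """
    estimable = [g for g in groups if g.estimable]
    inestimable = sorted((g for g in groups if not g.estimable), key=lambda g: g.key)
    if not estimable:
        return groups
    estimable = sorted(estimable, key=lambda g: g.key)

    def class_mean(g: FactorGroup, adhd: bool) -> float:
        sub = records.loc[list(g.member_ids)]
        mask = (sub["diagnosis"] == "ADHD").to_numpy() == adhd
        return float(composite_score(sub)[mask].mean()) if mask.any() else float("nan")

    for g in inestimable:
        sub = records.loc[list(g.member_ids)]
        # majority class of the sparse group drives the similarity match
        adhd = bool((sub["diagnosis"] == "ADHD").mean() >= 0.5)
        target_mean = class_mean(g, adhd)
        dists = [abs(class_mean(h, adhd) - target_mean) for h in estimable]
        j = int(np.nanargmin(dists))
        estimable[j] = _merge_pair(estimable[j], g, records)
    return sorted(estimable, key=lambda g: g.key)


def filter_degenerate(groups: list[FactorGroup]) -> GroupingResult:
    """Remove groups whose ADHD fraction is exactly 0 or 1.

    The class effect is unquantifiable in such groups, and their records are
    excluded from all downstream modelling.
    """
    retained = [g for g in groups if 0.0 < g.p_i < 1.0]
    removed = [g for g in groups if not (0.0 < g.p_i < 1.0)]
    return GroupingResult(groups=retained, removed_groups=removed)


def audit_cohort(
    records: pd.DataFrame,
    alpha: float = 0.05,
    merge: bool = True,
    absorb: bool = True,
) -> GroupingResult:
    """Full audit: group, estimate effects, merge equal groups, absorb sparse
    one-class groups into their nearest estimable group, drop degenerates."""
    groups = assign_groups(records)
    for g in groups:
        estimate_group_effect(g, records)
    if merge:
        groups = merge_equal_groups(groups, records, alpha=alpha).groups
    if absorb:
        groups = absorb_inestimable(groups, records)
    return filter_degenerate(groups)


def audit_report(result: GroupingResult, records: pd.DataFrame) -> dict:
    """JSON-serializable audit summary: group stats and per-factor chi-squares."""
    def desc(g: FactorGroup) -> dict:
        return {
            "cells": [list(c) for c in g.key],
            "n_i": g.n_i,
            "p_i": g.p_i,
            "effect": None if not np.isfinite(g.effect) else g.effect,
            "effect_se": None if not np.isfinite(g.effect_se) else g.effect_se,
        }

    chi = {}
    for factor in FACTOR_COLUMNS:
        try:
            stat, dof, p = chi_square_imbalance(records, factor)
            chi[factor] = {"chi2": stat, "dof": dof, "p": p}
        except ValueError as exc:
            chi[factor] = {"error": str(exc)}
    return {
        "n_records": int(len(records)),
        "n_retained": result.n_retained,
        "retained_fraction": result.retained_fraction,
        "groups": [desc(g) for g in result.groups],
        "removed_groups": [desc(g) for g in result.removed_groups],
        "chi_square": chi,
    }
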