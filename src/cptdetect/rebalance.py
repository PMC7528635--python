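"""Training-set rebalancing by weighted bootstrap oversampling.

The correction inflates the training partition to a fixed size N_tilde by
sampling records with replacement, with per-record probability inverse to the
record's appearance in the data with respect to both factor-group size and
diagnosis composition:

    w = (1 - n_i / N) * (1 - p_i)   for a child with ADHD in group i
    w = (1 - n_i / N) * p_i         for a child without ADHD in group i

where ``n_i`` is the group size, ``p_i`` its ADHD fraction and ``N`` the
total.  The two factors combine multiplicatively; within any group the total
sampling mass of the two classes is then identical
(``n_i * p_i * (1 - p_i) * (1 - n_i/N)`` on both sides), so the expected
class ratio of the inflated table is 1:1 — the within-level imbalance is
removed, and small groups are upweighted against the across-level imbalance.

Two oversampling modes share this sampling plan: plain bootstrap repetition
(rows are copies of real records) and SMOTE-style interpolation (each drawn
seed record is replaced by a convex combination with one of its k nearest
same-class neighbors on the four index z-scores, factor columns copied from
the seed).  Random undersampling of the majority class is provided as the
comparison arm.  The holdout partition is never touched by any of this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .audit import FactorGroup
from .cohort import INDEX_COLUMNS

__all__ = [
    "Partition",
    "SamplingPlan",
    "partition_data",
    "sampling_weights",
    "bootstrap_oversample",
    "smote_oversample",
    "undersample",
]

DEFAULT_INFLATED_SIZE = 5000


@dataclass(frozen=True)
class Partition:
    """A random train/holdout split of record ids; |train| = round(f * N)."""

    train_ids: tuple
    holdout_ids: tuple
    train_fraction: float
    seed: int


@dataclass
class SamplingPlan:
    """Normalized oversampling probabilities over the training records."""

    record_ids: tuple
    probabilities: np.ndarray
    inflated_size: int = DEFAULT_INFLATED_SIZE
    mode: str = "bootstrap-repetition"
    #: group label per training record, used for stratified interpolation
    group_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if (p < 0).any():
            raise ValueError("sampling probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("sampling probabilities must sum to 1")
        if self.inflated_size <= 0:
            raise ValueError("inflated_size must be positive")
        self.probabilities = p


def partition_data(
    records: pd.DataFrame, train_fraction: float = 0.6, seed: int = 0
) -> Partition:
    """Simple random split into training and untouched holdout partitions."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0,1), got {train_fraction}")
    ids = records["child_id"].to_numpy()
    if len(ids) < 5:
        raise ValueError("need at least 5 records to partition")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = round(train_fraction * len(ids))
    return Partition(
        train_ids=tuple(ids[perm[:n_train]]),
        holdout_ids=tuple(ids[perm[n_train:]]),
        train_fraction=train_fraction,
        seed=seed,
    )


def sampling_weights(
    train_records: pd.DataFrame,
    groups: list[FactorGroup],
    inflated_size: int = DEFAULT_INFLATED_SIZE,
    equalize_groups: bool = False,
) -> SamplingPlan:
    """Build the inverse-appearance sampling plan over the training records.

    ``groups`` are the retained audit groups carrying n_i and p_i (computed on
    the full retained cohort, before partitioning).  Every training record
    must belong to one of them; records of degenerate groups must already
    have been filtered out.

    With ``equalize_groups`` the total mass of each group is equalized before
    the class weighting, making group masses uniform as well; by default only
    the stated inverse-appearance formula is applied.
    """
    N = sum(g.n_i for g in groups)
    id_to_group: dict = {}
    for gi, g in enumerate(groups):
        if not (0.0 < g.p_i < 1.0):
            raise ValueError(f"degenerate group {g.key} (p_i={g.p_i}) must be filtered first")
        for rid in g.member_ids:
            id_to_group[rid] = gi

    ids = tuple(train_records["child_id"])
    is_adhd = (train_records["diagnosis"] == "ADHD").to_numpy()
    w = np.empty(len(ids))
    labels = np.empty(len(ids), dtype=int)
    for k, rid in enumerate(ids):
        if rid not in id_to_group:
            raise ValueError(f"training record {rid} not in any retained group")
        g = groups[id_to_group[rid]]
        labels[k] = id_to_group[rid]
        class_factor = (1.0 - g.p_i) if is_adhd[k] else g.p_i
        # a single group spanning all records makes the level factor a common
        # zero scale; by symmetry it then drops out
        level_factor = (1.0 - g.n_i / N) if len(groups) > 1 else 1.0
        w[k] = level_factor * class_factor
    if equalize_groups:
        for gi in np.unique(labels):
            mask = labels == gi
            w[mask] /= w[mask].sum()
    total = w.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero")
    return SamplingPlan(
        record_ids=ids,
        probabilities=w / total,
        inflated_size=inflated_size,
        group_labels=labels,
    )


def bootstrap_oversample(
    plan: SamplingPlan, train_records: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Draw the inflated training table by weighted bootstrap with repetition.

    Returns exactly ``plan.inflated_size`` rows; each row is a copy of a real
    training record with its provenance kept in ``source_id``.
    """
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(plan.record_ids), size=plan.inflated_size, p=plan.probabilities)
    base = train_records.set_index("child_id")
    out = base.loc[[plan.record_ids[i] for i in idx]].reset_index()
    out["source_id"] = out["child_id"]
    return out


def smote_oversample(
    plan: SamplingPlan,
    train_records: pd.DataFrame,
    k_neighbors: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Inflated training table with SMOTE-style neighbor interpolation.

    Each of the ``plan.inflated_size`` rows starts from a seed record drawn
    under the plan; its four index z-scores are replaced by a convex
    combination ``(1 - lam) * seed + lam * neighbor`` with ``lam ~ U(0,1)``
    and the neighbor one of the seed's ``k_neighbors`` nearest same-class
    records within the same factor group.  Factor columns and the label are
    copied from the seed.  A (group, class) stratum with fewer than two
    members falls back to plain repetition.  Provenance columns ``source_id``,
    ``neighbor_id`` and ``lam`` are kept.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    rng = np.random.default_rng(seed)
    base = train_records.set_index("child_id")
    is_adhd = base["diagnosis"] == "ADHD"
    if plan.group_labels is None:
        raise ValueError("plan lacks group labels required for stratified interpolation")

    # neighbor index per (group, class) stratum
    strata: dict[tuple[int, bool], tuple[list, NearestNeighbors | None, np.ndarray]] = {}
    for g in np.unique(plan.group_labels):
        for cls in (True, False):
            members = [
                rid for rid, lab in zip(plan.record_ids, plan.group_labels)
                if lab == g and bool(is_adhd.loc[rid]) == cls
            ]
            X = base.loc[members, list(INDEX_COLUMNS)].to_numpy() if members else np.empty((0, 4))
            if len(members) >= 2:
                nn = NearestNeighbors(n_neighbors=min(k_neighbors + 1, len(members)))
                nn.fit(X)
            else:
                nn = None
            strata[(int(g), cls)] = (members, nn, X)

    draws = rng.choice(len(plan.record_ids), size=plan.inflated_size, p=plan.probabilities)
    rows = []
    for i in draws:
        rid = plan.record_ids[i]
        row = base.loc[rid].copy()
        row["source_id"] = rid
        members, nn, X = strata[(int(plan.group_labels[i]), bool(is_adhd.loc[rid]))]
        if nn is None:
            row["neighbor_id"] = rid
            row["lam"] = 0.0
        else:
            xi = base.loc[rid, list(INDEX_COLUMNS)].to_numpy(dtype=float)
            _, nbrs = nn.kneighbors(xi.reshape(1, -1))
            candidates = [j for j in nbrs[0] if members[j] != rid] or list(nbrs[0])
            j = candidates[rng.integers(len(candidates))]
            lam = rng.random()
            z = (1.0 - lam) * xi + lam * X[j]
            for c, v in zip(INDEX_COLUMNS, z):
                row[c] = v
            row["neighbor_id"] = members[j]
            row["lam"] = lam
        rows.append(row)
    out = pd.DataFrame(rows)
    out.index.name = "child_id"
    return out.reset_index()


def undersample(train_records: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Randomly reduce the majority class to the minority size (exact 1:1).

    Output rows are a subset of the input; no synthetic rows are created.
    """
    rng = np.random.default_rng(seed)
    adhd = train_records[train_records["diagnosis"] == "ADHD"]
    ctrl = train_records[train_records["diagnosis"] == "control"]
    if adhd.empty or ctrl.empty:
        raise ValueError("both classes must be present to undersample")
    n = min(len(adhd), len(ctrl))
    take = lambda df: df.iloc[rng.choice(len(df), size=n, replace=False)]
    out = pd.concat([take(adhd), take(ctrl)]).sample(frac=1.0, random_state=int(rng.integers(2**31)))
    return out.reset_index(drop=True)
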