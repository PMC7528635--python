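"""Repeated-holdout evaluation of the detection pipeline.

Each repetition draws a fresh random 60/40 train/holdout split of the audited
cohort, applies an arm-specific training manipulation (none for the
benchmark; weighted bootstrap or SMOTE oversampling to N_tilde, or random
undersampling, for the corrected arms), fits the arm's model and scores
accuracy, sensitivity and specificity on the untouched holdout.  All arms of
a repetition share the identical partition, so across-arm comparisons are
paired by repetition index.

Summaries report the mean and a 95% normal-approximation interval
(mean +/- 1.96 SD of the per-repetition metrics, clipped to [0, 1]) per arm,
plus pairwise paired t-tests between arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .audit import GroupingResult
from .classify import ModelSpec, fit_model, predict
from .rebalance import (
    bootstrap_oversample,
    partition_data,
    sampling_weights,
    smote_oversample,
    undersample,
)

__all__ = [
    "MetricSet",
    "ArmSpec",
    "EvaluationSummary",
    "ComparisonResult",
    "score_predictions",
    "confidence_interval",
    "paired_t_test",
    "relative_improvement",
    "run_experiment",
    "DEFAULT_ARMS",
]


@dataclass(frozen=True)
class MetricSet:
    """Confusion counts and the derived rates, ADHD as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")


def score_predictions(predicted: np.ndarray, truth: np.ndarray) -> MetricSet:
    """Exact confusion-count arithmetic; labels are 'ADHD'/'control'."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if len(predicted) != len(truth):
        raise ValueError("predicted and true label vectors differ in length")
    pos_p, pos_t = predicted == "ADHD", truth == "ADHD"
    return MetricSet(
        tp=int((pos_p & pos_t).sum()),
        fp=int((pos_p & ~pos_t).sum()),
        tn=int((~pos_p & ~pos_t).sum()),
        fn=int((~pos_p & pos_t).sum()),
    )


def confidence_interval(values: np.ndarray) -> tuple[float, float]:
    """95% normal-approximation interval mean +/- 1.96 SD, clipped to [0,1]."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for an interval")
    m, s = v.mean(), v.std(ddof=1)
    return (max(0.0, m - 1.96 * s), min(1.0, m + 1.96 * s))


@dataclass(frozen=True)
class ComparisonResult:
    arm_a: str
    arm_b: str
    metric: str
    t: float
    p: float
    mean_diff: float


def paired_t_test(a: np.ndarray, b: np.ndarray, arm_a: str = "A", arm_b: str = "B",
                  metric: str = "accuracy") -> ComparisonResult:
    """Paired t-test over repetitions; an exact tie reports t=0, p=1."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        tie = np.allclose(d, 0.0)
        return ComparisonResult(arm_a, arm_b, metric,
                                t=0.0 if tie else float("inf") * np.sign(d.mean()),
                                p=1.0 if tie else 0.0, mean_diff=float(d.mean()))
    t, p = stats.ttest_rel(a, b)
    return ComparisonResult(arm_a, arm_b, metric, t=float(t), p=float(p),
                            mean_diff=float(d.mean()))


def relative_improvement(model_accuracy: float, benchmark_accuracy: float) -> float:
    """Percent improvement over the benchmark, one decimal.

    Both inputs on the percentage scale: (87, 65) -> 33.8 (prints as 34 at
    integer precision), (81, 65) -> 24.6.
    """
    if benchmark_accuracy <= 0:
        raise ValueError("benchmark accuracy must be positive")
    return round(100.0 * (model_accuracy - benchmark_accuracy) / benchmark_accuracy, 1)


@dataclass(frozen=True)
class ArmSpec:
    """One experimental arm: a rebalancing mode plus a model spec."""

    name: str
    rebalance: str  # "none" | "bootstrap" | "smote" | "undersample"
    family: str = "random_forest"
    feature_set: str = "cpt_plus_controls"
    hyperparameters: dict = field(default_factory=dict)


#: the published comparison structure: uncorrected benchmark on CPT scores
#: alone, the corrected model with and without controls, the undersampling
#: alternative, and the network arm
DEFAULT_ARMS = (
    ArmSpec("benchmark", rebalance="none", feature_set="cpt_only"),
    ArmSpec("proposed-cpt-only", rebalance="bootstrap", feature_set="cpt_only"),
    ArmSpec("proposed-with-controls", rebalance="bootstrap", feature_set="cpt_plus_controls"),
    ArmSpec("undersample", rebalance="undersample", feature_set="cpt_plus_controls"),
    ArmSpec("nn-with-controls", rebalance="bootstrap", family="neural_network",
            feature_set="cpt_plus_controls"),
)


@dataclass
class EvaluationSummary:
    """Per-arm metric vectors over R repetitions plus summary statistics."""

    metrics: dict[str, pd.DataFrame]  # arm -> R x (accuracy, sensitivity, specificity)
    repetitions: int
    partition_hashes: list[int] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """Mean and 95% CI per arm and metric, percentages to one decimal."""
        rows = []
        for arm, df in self.metrics.items():
            row: dict = {"arm": arm}
            for metric in ("accuracy", "sensitivity", "specificity"):
                v = df[metric].to_numpy()
                lo, hi = confidence_interval(v)
                row[metric] = round(100 * v.mean(), 1)
                row[f"{metric}_ci"] = (round(100 * lo, 1), round(100 * hi, 1))
            rows.append(row)
        return pd.DataFrame(rows).set_index("arm")

    def compare(self, metric: str = "accuracy", adjust: str | None = None
                ) -> list[ComparisonResult]:
        """Pairwise paired t-tests; ``adjust="holm"`` applies the Holm
        step-down correction to the p-values (unadjusted by default)."""
        arms = list(self.metrics)
        out = []
        for i, a in enumerate(arms):
            for b in arms[i + 1:]:
                out.append(paired_t_test(
                    self.metrics[a][metric].to_numpy(),
                    self.metrics[b][metric].to_numpy(),
                    arm_a=a, arm_b=b, metric=metric,
                ))
        if adjust == "holm":
            order = np.argsort([c.p for c in out])
            m = len(out)
            adj, running = [0.0] * m, 0.0
            for rank, k in enumerate(order):
                running = max(running, (m - rank) * out[k].p)
                adj[k] = min(1.0, running)
            out = [ComparisonResult(c.arm_a, c.arm_b, c.metric, c.t, adj[k], c.mean_diff)
                   for k, c in enumerate(out)]
        elif adjust is not None:
            raise ValueError(f"unknown adjustment '{adjust}'")
        return out


def _rebalanced_training(arm: ArmSpec, train: pd.DataFrame, grouping: GroupingResult,
                         inflated_size: int, seed: int) -> pd.DataFrame:
    if arm.rebalance == "none":
        return train
    if arm.rebalance == "undersample":
        return undersample(train, seed=seed)
    plan = sampling_weights(train, grouping.groups, inflated_size=inflated_size)
    if arm.rebalance == "bootstrap":
        return bootstrap_oversample(plan, train, seed=seed)
    if arm.rebalance == "smote":
        return smote_oversample(plan, train, seed=seed)
    raise ValueError(f"unknown rebalance mode '{arm.rebalance}'")


def run_experiment(
    records: pd.DataFrame,
    grouping: GroupingResult,
    arms: tuple[ArmSpec, ...] = DEFAULT_ARMS,
    repetitions: int = 100,
    train_fraction: float = 0.6,
    inflated_size: int = 5000,
    seed: int = 0,
) -> EvaluationSummary:
    """Run the repeated train/holdout experiment over all arms.

    ``records`` must be the audited (retained) cohort and ``grouping`` the
    audit result carrying group n_i/p_i.  Per repetition all arms share one
    fresh partition; rebalancing touches only the training side.  Aborts if
    any arm fails to fit in more than 10% of repetitions.
    """
    retained = records[records["child_id"].isin(grouping.retained_ids())].reset_index(drop=True)
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(repetitions)]

    vectors: dict[str, list[dict]] = {arm.name: [] for arm in arms}
    failures = {arm.name: 0 for arm in arms}
    hashes = []
    for r, rep_seed in enumerate(rep_seeds):
        part = partition_data(retained, train_fraction=train_fraction, seed=rep_seed)
        hashes.append(hash(part.train_ids))
        train = retained[retained["child_id"].isin(part.train_ids)]
        hold = retained[retained["child_id"].isin(part.holdout_ids)]
        for a, arm in enumerate(arms):
            try:
                training = _rebalanced_training(arm, train, grouping, inflated_size,
                                                seed=rep_seed + 7919 * (a + 1))
                spec = ModelSpec(family=arm.family, feature_set=arm.feature_set,
                                 hyperparameters=arm.hyperparameters,
                                 seed=rep_seed + 104729 * (a + 1))
                model = fit_model(spec, training)
                pred = predict(model, hold)
                ms = score_predictions(pred["predicted"].to_numpy(),
                                       hold["diagnosis"].to_numpy())
                vectors[arm.name].append({
                    "accuracy": ms.accuracy,
                    "sensitivity": ms.sensitivity,
                    "specificity": ms.specificity,
                })
            except ValueError:
                failures[arm.name] += 1
                vectors[arm.name].append({
                    "accuracy": np.nan, "sensitivity": np.nan, "specificity": np.nan,
                })
        for arm in arms:
            if failures[arm.name] > 0.1 * repetitions:
                raise RuntimeError(
                    f"arm '{arm.name}' failed in >10% of repetitions "
                    f"({failures[arm.name]}/{r + 1} so far)"
                )
    metrics = {name: pd.DataFrame(rows) for name, rows in vectors.items()}
    return EvaluationSummary(metrics=metrics, repetitions=repetitions,
                             partition_hashes=hashes)
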