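"""Trial-level simulation of a distractor-embedded continuous performance test.

The simulated task mirrors the structure of a MOXO-style CPT: eight levels of
53 trials each (33 targets, 20 non-targets), every stimulus shown for 0.5, 1 or
3 s and followed by a "void" period of identical duration during which a late
response still counts as correct (but not as timely).  The child is instructed
to press the space bar once, and only once, for each target.

From one session four performance indices are aggregated:

* **attention** - number of target trials answered correctly (space bar pressed
  at any point while the stimulus or its void was on screen); its complement is
  the omission-error count.
* **timeliness** - number of those correct responses given while the stimulus
  itself was still displayed.
* **hyperactivity** - redundant motor output: repeated space-bar presses within
  a trial beyond the first, plus presses of any other key.
* **impulsiveness** - number of non-target trials responded to (commission
  errors).

The simulator is deterministic given a seed and is the ground-truth generator
used throughout the test-suite; response propensities are monotone in the
supplied latent traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SessionSpec",
    "TrialEvent",
    "IndexSet",
    "ChildTraits",
    "simulate_session",
    "aggregate_indices",
    "standardize_indices",
]


@dataclass(frozen=True)
class SessionSpec:
    """Structural parameters of one CPT session."""

    n_levels: int = 8
    trials_per_level: int = 53
    targets_per_level: int = 33
    nontargets_per_level: int = 20
    stimulus_durations: tuple[float, ...] = (0.5, 1.0, 3.0)
    #: probability of each stimulus duration; must keep the expected
    #: stimulus+void occupancy below ``level_duration``
    duration_weights: tuple[float, ...] = (0.7, 0.2, 0.1)
    level_duration: float = 114.15
    distractor_duration_range: tuple[float, float] = (3.5, 14.8)
    distractor_gap: float = 0.5

    def __post_init__(self) -> None:
        if self.targets_per_level + self.nontargets_per_level != self.trials_per_level:
            raise ValueError(
                "targets_per_level + nontargets_per_level must equal trials_per_level "
                f"({self.targets_per_level} + {self.nontargets_per_level} != {self.trials_per_level})"
            )
        if len(self.duration_weights) != len(self.stimulus_durations):
            raise ValueError("duration_weights must match stimulus_durations")
        w = np.asarray(self.duration_weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("duration_weights must be nonnegative and normalizable")
        mean_dur = float(np.dot(w / w.sum(), self.stimulus_durations))
        if 2.0 * mean_dur * self.trials_per_level >= self.level_duration:
            raise ValueError(
                "expected stimulus+void occupancy exceeds level_duration; "
                "lower duration_weights on long stimuli"
            )

    @property
    def total_duration(self) -> float:
        """Total session span in seconds (levels are back to back)."""
        return self.n_levels * self.level_duration


@dataclass
class TrialEvent:
    """One stimulus presentation plus all key presses attributed to it.

    ``responses`` holds ``(key, time)`` pairs with absolute session time;
    presses are attributed to the trial whose stimulus+void window
    ``[onset, onset + 2*duration]`` contains them.
    """

    level_index: int
    trial_index: int
    stimulus_class: str  # "target" | "nontarget"
    stimulus_onset: float
    stimulus_duration: float
    responses: list[tuple[str, float]] = field(default_factory=list)

    @property
    def void_end(self) -> float:
        return self.stimulus_onset + 2.0 * self.stimulus_duration


@dataclass(frozen=True)
class IndexSet:
    """The four per-session CPT performance counts."""

    attention: int
    timeliness: int
    hyperactivity: int
    impulsiveness: int

    def __post_init__(self) -> None:
        if not (0 <= self.timeliness <= self.attention):
            raise ValueError("0 <= timeliness <= attention violated")
        if min(self.attention, self.hyperactivity, self.impulsiveness) < 0:
            raise ValueError("index counts must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.attention, self.timeliness, self.hyperactivity, self.impulsiveness],
            dtype=float,
        )


@dataclass(frozen=True)
class ChildTraits:
    """Latent response propensities; all probabilities, monotone in behaviour.

    respond_target
        probability of answering a target trial at all.
    timely_given_respond
        probability that an answer lands inside the stimulus window rather than
        the void.
    respond_nontarget
        probability of a commission error on a non-target trial.
    extra_press_rate
        Poisson mean of redundant presses (repeats + wrong keys) per trial.
    """

    respond_target: float = 0.9
    timely_given_respond: float = 0.8
    respond_nontarget: float = 0.1
    extra_press_rate: float = 0.1

    def __post_init__(self) -> None:
        for name in ("respond_target", "timely_given_respond", "respond_nontarget"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.extra_press_rate < 0:
            raise ValueError("extra_press_rate must be >= 0")


def _level_schedule(spec: SessionSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw stimulus classes and durations for one level.

    Durations are drawn from the categorical mix and the draw is rejected
    while total stimulus+void time would overflow the level; the slack is
    later distributed as inter-trial gaps so the level spans exactly
    ``level_duration``.
    """
    classes = np.array(
        ["target"] * spec.targets_per_level + ["nontarget"] * spec.nontargets_per_level
    )
    rng.shuffle(classes)
    w = np.asarray(spec.duration_weights, dtype=float)
    w = w / w.sum()
    for _ in range(1000):
        durations = rng.choice(spec.stimulus_durations, size=spec.trials_per_level, p=w)
        if 2.0 * durations.sum() <= spec.level_duration:
            return classes, durations
    raise RuntimeError("could not draw a duration mix fitting the level budget")


def simulate_session(
    traits: ChildTraits,
    spec: SessionSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> list[TrialEvent]:
    """Simulate one full CPT session for a child with the given traits.

    Returns ``spec.n_levels * spec.trials_per_level`` trial events on a
    schedule in which every level spans exactly ``spec.level_duration``
    seconds.  Deterministic given (traits, spec, seed).
    """
    spec = spec or SessionSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    events: list[TrialEvent] = []
    for level in range(1, spec.n_levels + 1):
        level_start = (level - 1) * spec.level_duration
        classes, durations = _level_schedule(spec, rng)
        # spread residual level time as inter-trial gaps (incl. trailing gap)
        slack = spec.level_duration - 2.0 * durations.sum()
        gaps = rng.dirichlet(np.ones(spec.trials_per_level + 1)) * slack
        t = level_start + gaps[0]
        for i, (cls, dur) in enumerate(zip(classes, durations), start=1):
            ev = TrialEvent(
                level_index=level,
                trial_index=i,
                stimulus_class=str(cls),
                stimulus_onset=t,
                stimulus_duration=float(dur),
            )
            _respond(ev, traits, rng)
            events.append(ev)
            t = ev.void_end + gaps[i]
    return events


def _respond(ev: TrialEvent, traits: ChildTraits, rng: np.random.Generator) -> None:
    dur = ev.stimulus_duration
    if ev.stimulus_class == "target":
        if rng.random() < traits.respond_target:
            if rng.random() < traits.timely_given_respond:
                t = ev.stimulus_onset + rng.random() * dur
            else:
                t = ev.stimulus_onset + dur + rng.random() * dur
            ev.responses.append(("spacebar", float(t)))
    else:
        if rng.random() < traits.respond_nontarget:
            t = ev.stimulus_onset + rng.random() * 2.0 * dur
            ev.responses.append(("spacebar", float(t)))
    n_extra = rng.poisson(traits.extra_press_rate)
    for _ in range(n_extra):
        key = "spacebar" if rng.random() < 0.5 else "other"
        t = ev.stimulus_onset + rng.random() * 2.0 * dur
        ev.responses.append((key, float(t)))
    ev.responses.sort(key=lambda kt: kt[1])


def aggregate_indices(events: list[TrialEvent]) -> IndexSet:
    """Aggregate one session's trial events into the four CPT indices.

    A target trial counts toward *attention* if any space-bar press falls in
    its stimulus+void window, and toward *timeliness* if the first such press
    falls inside the stimulus presentation itself.  Every space-bar press
    beyond the first in a trial, and every non-space-bar press, counts toward
    *hyperactivity*.  A non-target trial with at least one space-bar press
    counts toward *impulsiveness*.
    """
    _validate_session(events)
    attention = timeliness = hyper = impuls = 0
    for ev in events:
        sb = [t for k, t in ev.responses if k == "spacebar"]
        other = [t for k, t in ev.responses if k != "spacebar"]
        hyper += len(other) + max(0, len(sb) - 1)
        if not sb:
            continue
        if ev.stimulus_class == "target":
            attention += 1
            if sb[0] <= ev.stimulus_onset + ev.stimulus_duration:
                timeliness += 1
        else:
            impuls += 1
    return IndexSet(attention, timeliness, hyper, impuls)


def _validate_session(events: list[TrialEvent]) -> None:
    seen: set[tuple[int, int]] = set()
    prev_end = -np.inf
    for ev in sorted(events, key=lambda e: e.stimulus_onset):
        key = (ev.level_index, ev.trial_index)
        if key in seen:
            raise ValueError(f"duplicate trial {key}")
        seen.add(key)
        if ev.stimulus_onset < prev_end - 1e-9:
            raise ValueError(
                f"trial {key} overlaps the previous stimulus+void window"
            )
        prev_end = ev.void_end
        for k, t in ev.responses:
            if not (ev.stimulus_onset - 1e-9 <= t <= ev.void_end + 1e-9):
                raise ValueError(f"response at {t} outside window of trial {key}")


def standardize_indices(
    raw: np.ndarray,
    reference_mask: np.ndarray | None = None,
    index_names: tuple[str, ...] = ("attention", "timeliness", "hyperactivity", "impulsiveness"),
) -> np.ndarray:
    """Z-score raw index columns against a reference subset.

    Parameters
    ----------
    raw
        (n, 4) array of raw index values.
    reference_mask
        Boolean mask selecting the normative subset (e.g. the control group);
        ``None`` standardizes against the whole sample.

    The reference subset has mean 0 and SD 1 on every returned column.
    """
    raw = np.asarray(raw, dtype=float)
    ref = raw if reference_mask is None else raw[np.asarray(reference_mask, bool)]
    if ref.shape[0] < 2:
        raise ValueError("reference subset needs at least 2 members")
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=0)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"zero variance in reference for index '{index_names[j]}'")
    return (raw - mu) / sd
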