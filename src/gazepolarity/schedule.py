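"""Constraint-satisfying trial schedules for the two gaze-discrimination tasks.

Two task families are supported:

* A keypress task (human participants): 96 trials in 8 blocks of 12, blocks
  alternating stimulus species, with a within-block level (or level/polarity)
  progression, gaze directions balanced 32/32/32 across the run, no gaze
  direction in more than two successive trials, and no stimulus individual in
  consecutive trials.
* A 3-item visual-search task (chimpanzee participants): 48-trial sessions in
  4 alternating-species blocks; sessions at level >= 1.5 interleave 6 baseline
  (L1) and 6 test trials per block; target locations balanced 16/16/16; each
  of the 6 stimulus individuals per species appears exactly 4 times.

Randomization is a sequential constrained shuffle: items are placed one
position at a time from the candidates the constraints allow, restarting on
dead ends, with a hard attempt cap — constraints are never silently relaxed.
Plans are pure functions of their seed, so a schedule can be regenerated
byte-identically.

The module also implements the adaptive level rule used across sessions
(increment by 0.5 after two successive sessions above 85% in target trials)
and the training-stage pass criterion (over 90% in one session, or at least
80% in two consecutive sessions, separately for both stimulus species).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .eye_image import LEVEL_TABLE, StimulusLevel

__all__ = [
    "TrialSpec",
    "Plan",
    "ExperimentPlan",
    "SessionPlan",
    "AdaptiveState",
    "TrainingStage",
    "ScheduleError",
    "MAX_ATTEMPTS",
    "build_study1_exp1",
    "build_study1_exp2",
    "build_study2_session",
    "update_level",
    "evaluate_training",
    "session_accuracy_for_adaptation",
    "default_stimulus_ids",
]

Species = Literal["chimpanzee", "human"]
SPECIES: tuple[Species, Species] = ("chimpanzee", "human")
DIRECTIONS = ("left", "front", "right")
LOCATIONS = ("left", "center", "right")

MAX_ATTEMPTS = 10_000


class ScheduleError(RuntimeError):
    """Raised when the constrained shuffle exhausts its attempt budget."""


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial."""

    experiment_id: str
    session_id: int
    block: int
    trial_in_block: int
    species: Species
    stimulus_id: str
    level: float
    polarity: Literal["normal", "reversed"]
    gaze_direction: str | None = None
    target_location: str | None = None
    role: Literal["baseline", "test"] = "test"

    def __post_init__(self) -> None:
        if not 1 <= self.trial_in_block <= 12:
            raise ValueError("trial_in_block must lie in [1, 12]")
        if self.role == "baseline" and self.level != 1.0:
            raise ValueError("baseline trials must use level 1")
        if float(self.level) not in LEVEL_TABLE:
            raise ValueError(f"unknown level {self.level}")


@dataclass(frozen=True)
class Plan:
    """An ordered trial list with its provenance (seed, first species)."""

    trials: tuple[TrialSpec, ...]
    seed: int
    first_species: Species

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.trials])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


# Aliases: a whole experiment and a single session share the same structure.
ExperimentPlan = Plan
SessionPlan = Plan


def default_stimulus_ids(n_per_species: int) -> dict[Species, list[str]]:
    return {
        "chimpanzee": [f"chimp{i:02d}" for i in range(1, n_per_species + 1)],
        "human": [f"human{i:02d}" for i in range(1, n_per_species + 1)],
    }


# ---------------------------------------------------------------------------
# Constrained shuffles
# ---------------------------------------------------------------------------


def _has_triple(seq: Sequence) -> bool:
    return any(seq[i] == seq[i - 1] == seq[i - 2] for i in range(2, len(seq)))


def _draw_constrained(
    rng: np.random.Generator,
    pool: list,
    forbidden,
) -> list:
    """Sequential constrained shuffle with restart.

    Items are drawn one position at a time, with probability proportional to
    their remaining multiplicity, from the candidates ``forbidden(seq, item)``
    does not veto; a dead end restarts the whole sequence (bounded by
    ``MAX_ATTEMPTS``).  Dead ends are rare for the designs used here, so the
    draw stays close to a uniform pick from the constraint-satisfying set.
    """
    distinct = list(dict.fromkeys(pool))
    base_counts = [pool.count(v) for v in distinct]
    total = len(pool)
    for _ in range(MAX_ATTEMPTS):
        counts = list(base_counts)
        seq: list = []
        for _pos in range(total):
            cand = [
                k
                for k, v in enumerate(distinct)
                if counts[k] > 0 and not forbidden(seq, v)
            ]
            if not cand:
                break
            weights = np.array([counts[k] for k in cand], dtype=float)
            k = cand[rng.choice(len(cand), p=weights / weights.sum())]
            counts[k] -= 1
            seq.append(distinct[k])
        if len(seq) == total:
            return seq
    raise ScheduleError("could not satisfy the sequential constraints")


def _draw_no_triple(rng: np.random.Generator, pool: list) -> list:
    """Order ``pool`` so that no item occurs in three successive positions."""

    def forbidden(seq, item):
        return len(seq) >= 2 and seq[-1] == item and seq[-2] == item

    return _draw_constrained(rng, pool, forbidden)


def _draw_block_sequences(
    rng: np.random.Generator, pool: list, block_size: int
) -> list:
    """Order ``pool`` so that no item repeats in consecutive positions
    within any contiguous block of ``block_size``."""

    def forbidden(seq, item):
        return len(seq) % block_size != 0 and seq[-1] == item

    return _draw_constrained(rng, pool, forbidden)


def _balanced_pool(values: Sequence, total: int, rng: np.random.Generator) -> list:
    """A pool of ``total`` items drawn as evenly as possible from ``values``.

    When ``total`` is not a multiple of ``len(values)``, the remainder is
    assigned to a random subset (e.g. 48 trials over 10 individuals gives
    eight 5-counts and two 4-counts).
    """
    base, rem = divmod(total, len(values))
    counts = np.full(len(values), base, dtype=int)
    if rem:
        counts[rng.choice(len(values), size=rem, replace=False)] += 1
    pool: list = []
    for v, c in zip(values, counts):
        pool.extend([v] * int(c))
    return pool


def _species_blocks(first_species: Species, n_blocks: int) -> list[Species]:
    other: Species = "human" if first_species == "chimpanzee" else "chimpanzee"
    return [first_species if b % 2 == 0 else other for b in range(n_blocks)]


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def _build_study1(
    seed: int,
    first_species: Species,
    experiment_id: str,
    block_levels: Sequence[float],
    block_polarities: Sequence[str],
    stimulus_ids: Mapping[Species, Sequence[str]] | None,
) -> Plan:
    if first_species not in SPECIES:
        raise ValueError(f"unknown species {first_species!r}")
    ids = stimulus_ids or default_stimulus_ids(10)
    for sp in SPECIES:
        if len(ids[sp]) < 2:
            raise ValueError("need at least two stimulus individuals per species")
    rng = np.random.default_rng(seed)
    n_blocks, block_size = 8, 12
    species_seq = _species_blocks(first_species, n_blocks)

    directions = _draw_no_triple(rng, _balanced_pool(DIRECTIONS, n_blocks * block_size, rng))

    # Per-species stimulus order: balanced counts, no consecutive repeats
    # inside a block (blocks alternate species, so cross-block neighbours
    # always differ anyway).
    stim_seq: dict[Species, list[str]] = {}
    for sp in SPECIES:
        n_sp = species_seq.count(sp) * block_size
        stim_seq[sp] = _draw_block_sequences(
            rng, _balanced_pool(list(ids[sp]), n_sp, rng), block_size
        )

    trials = []
    consumed = {sp: 0 for sp in SPECIES}
    for b, sp in enumerate(species_seq):
        for t in range(block_size):
            k = consumed[sp]
            consumed[sp] += 1
            trials.append(
                TrialSpec(
                    experiment_id=experiment_id,
                    session_id=1,
                    block=b + 1,
                    trial_in_block=t + 1,
                    species=sp,
                    stimulus_id=stim_seq[sp][k],
                    level=float(block_levels[t]),
                    polarity=block_polarities[b],  # type: ignore[arg-type]
                    gaze_direction=directions[b * block_size + t],
                    role="test",
                )
            )
    return Plan(tuple(trials), seed=seed, first_species=first_species)


def build_study1_exp1(
    seed: int,
    first_species: Species = "chimpanzee",
    stimulus_ids: Mapping[Species, Sequence[str]] | None = None,
) -> ExperimentPlan:
    """96-trial keypress experiment, normal polarity, levels L1–L4.

    Eight alternating-species blocks of 12 trials; within each block the
    level steps up every three trials (L1,L1,L1,L2,...,L4), giving 12 trials
    per species x level cell.  Directions are balanced 32/32/32 with no 3-run
    and no stimulus individual repeats in consecutive trials.
    """
    levels = [1, 1, 1, 2, 2, 2, 3, 3, 3, 4, 4, 4]
    return _build_study1(
        seed, first_species, "study1-exp1", levels, ["normal"] * 8, stimulus_ids
    )


def build_study1_exp2(
    seed: int,
    first_species: Species = "chimpanzee",
    stimulus_ids: Mapping[Species, Sequence[str]] | None = None,
) -> ExperimentPlan:
    """96-trial keypress experiment crossing polarity with levels L3–L4.

    Each block presents six L3 then six L4 trials of one species; the block
    polarity pattern is normal, normal, reversed, reversed, repeated — which
    yields 12 trials per species x level x polarity cell.
    """
    levels = [3, 3, 3, 3, 3, 3, 4, 4, 4, 4, 4, 4]
    polarity = ["normal", "normal", "reversed", "reversed"] * 2
    return _build_study1(
        seed, first_species, "study1-exp2", levels, polarity, stimulus_ids
    )


def build_study2_session(
    seed: int,
    level: float,
    polarity: Literal["normal", "reversed"] = "normal",
    first_species: Species = "chimpanzee",
    phase: str | None = None,
    session_id: int = 1,
    stimulus_ids: Mapping[Species, Sequence[str]] | None = None,
) -> SessionPlan:
    """One 48-trial visual-search session at a given adaptive level.

    Four alternating-species blocks of 12.  At level >= 1.5 each block opens
    with six baseline (L1) trials followed by six test trials at the session
    level; at level 1.0 all 48 trials are baseline-format.  Target locations
    are balanced 16/16/16 with no location in more than two successive trials;
    the six stimulus individuals per species each appear exactly four times,
    never in consecutive trials.
    """
    lvl = StimulusLevel.from_value(level).level
    if first_species not in SPECIES:
        raise ValueError(f"unknown species {first_species!r}")
    ids = stimulus_ids or default_stimulus_ids(6)
    rng = np.random.default_rng(seed)
    n_blocks, block_size = 4, 12
    species_seq = _species_blocks(first_species, n_blocks)
    experiment_id = "study2"
    if phase is None:
        phase = "test" if lvl >= 2.5 else "pre-test"

    locations = _draw_no_triple(rng, _balanced_pool(LOCATIONS, n_blocks * block_size, rng))
    stim_seq: dict[Species, list[str]] = {}
    for sp in SPECIES:
        stim_seq[sp] = _draw_block_sequences(rng, _balanced_pool(list(ids[sp]), 24, rng), block_size)

    split = lvl >= 1.5
    trials = []
    consumed = {sp: 0 for sp in SPECIES}
    for b, sp in enumerate(species_seq):
        for t in range(block_size):
            k = consumed[sp]
            consumed[sp] += 1
            if split and t >= 6:
                role, trial_level = "test", lvl
            else:
                role, trial_level = "baseline", 1.0
            trials.append(
                TrialSpec(
                    experiment_id=f"{experiment_id}-{phase}",
                    session_id=session_id,
                    block=b + 1,
                    trial_in_block=t + 1,
                    species=sp,
                    stimulus_id=stim_seq[sp][k],
                    level=trial_level,
                    polarity=polarity,
                    target_location=locations[b * block_size + t],
                    role=role,
                )
            )
    return Plan(tuple(trials), seed=seed, first_species=first_species)


# ---------------------------------------------------------------------------
# Adaptive level rule / training criterion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdaptiveState:
    """Across-session staircase state: level rises, never falls."""

    current_level: float = 1.0
    accuracy_history: tuple[float, ...] = ()
    threshold: float = 0.85
    consecutive_required: int = 2
    step: float = 0.5
    max_level: float = 4.0


def update_level(state: AdaptiveState, session_target_accuracy: float) -> AdaptiveState:
    """Apply one session's target-trial accuracy to the staircase.

    The level increments by ``step`` iff the two most recent sessions at the
    current level both exceeded the 85% threshold (strict), capped at L4;
    the history resets after each increment.
    """
    acc = float(session_target_accuracy)
    if not 0.0 <= acc <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    hist = state.accuracy_history + (acc,)
    if (
        len(hist) >= state.consecutive_required
        and all(a > state.threshold for a in hist[-state.consecutive_required :])
        and state.current_level < state.max_level
    ):
        new_level = round((state.current_level + state.step) * 2) / 2
        return replace(state, current_level=min(new_level, state.max_level), accuracy_history=())
    return replace(state, accuracy_history=hist)


def session_accuracy_for_adaptation(responses: pd.DataFrame) -> float:
    """Accuracy the staircase evaluates: all trials at an L1 session,
    otherwise the test trials only."""
    if (responses["level"] == 1.0).all():
        return float(responses["correct"].mean())
    return float(responses.loc[responses["role"] == "test", "correct"].mean())


_STAGE_TARGET_IRIS = {1: None, 2: 38.0, 3: 30.0, 4: 20.0, 5: 20.0, 6: 20.0}
_STAGE_N_STIMULI = {1: 2, 2: 2, 3: 2, 4: 2, 5: 4, 6: 6}


@dataclass(frozen=True)
class TrainingStage:
    """One of the six shaping stages leading into the search task.

    Stage 1 uses a target with no iris at all; stages 2–4 move the target
    iris from 38° through 30° to the final 20° eccentricity; stages 5 and 6
    grow the stimulus roster from 2 to 4 and then 6 individuals per species.
    """

    stage: int
    target_iris_deg: float | None
    n_stimulus_individuals_per_species: int
    pass_single: float = 0.90
    pass_double: float = 0.80

    @classmethod
    def make(cls, stage: int) -> "TrainingStage":
        if stage not in _STAGE_TARGET_IRIS:
            raise ValueError("training stage must lie in 1..6")
        return cls(stage, _STAGE_TARGET_IRIS[stage], _STAGE_N_STIMULI[stage])


def evaluate_training(
    stage: TrainingStage, accuracies: Mapping[str, Sequence[float]]
) -> Literal["pass", "continue"]:
    """Apply the stage-pass criterion to per-species session accuracies.

    A stage is passed only when EACH species' trial series satisfies either
    branch: latest session strictly above 90%, or the latest two consecutive
    sessions both at or above 80%.
    """
    for sp in SPECIES:
        seq = list(accuracies[sp])
        if not seq:
            raise ValueError(f"no sessions recorded for {sp} trials")
        single = seq[-1] > stage.pass_single
        double = len(seq) >= 2 and seq[-1] >= stage.pass_double and seq[-2] >= stage.pass_double
        if not (single or double):
            return "continue"
    return "pass"
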