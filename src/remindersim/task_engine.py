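"""Symbolic engine for the optimal-reminders task.

The optimal-reminders task asks participants to drag 25 numbered circles to
the bottom of a box in sequence.  Ten of the circles are "special": each one
carries a delayed intention (drag it to a particular coloured edge when its
turn comes).  Participants can fulfil these intentions from internal memory,
earning the full reward per remembered target, or they can set an external
reminder, earning a smaller offered value per target.  Sessions interleave
free-choice trials (the participant picks a strategy given the offer) with
forced-internal and forced-external trials used to estimate each strategy's
accuracy.

This module reproduces the task's combinatorial structure exactly — target
placement into 10 adjacent bins over sequence positions 7..25, the offer
schedules of the between-participants (experiment 1) and within-participants
(experiment 2) designs, and the strict alternation of choice and forced
trials — while abstracting away the browser mechanics (dragging, fade
timing, screen geometry).  A trial outcome is a vector of independent
Bernoulli hits, one per target, with success probability set by the strategy
in use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .agents import AgentParams

GAIN = "gain"
LOSS = "loss"
FRAMINGS = (GAIN, LOSS)

CHOICE = "choice"
FORCED_INTERNAL = "forced_internal"
FORCED_EXTERNAL = "forced_external"

INTERNAL = "internal"
EXTERNAL = "external"


class ConfigurationError(ValueError):
    """Raised when a task configuration violates the task's structure."""


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of one experiment's task.

    ``trials_total`` counts the trials of a single session block: choice
    trials (one per offer value) strictly interleaved with forced trials
    that alternate between the internal and external strategy.
    """

    experiment: int
    circles_total: int = 25
    visible_concurrent: int = 6
    n_targets: int = 10
    target_position_range: tuple[int, int] = (7, 25)
    offer_values: tuple[int, ...] = ()
    trials_total: int = 0
    full_reward: int = 10

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ConfigurationError(f"experiment must be 1 or 2, got {self.experiment!r}")
        lo, hi = self.target_position_range
        span = hi - lo + 1
        if span != 2 * self.n_targets - 1:
            raise ConfigurationError(
                f"target position range {self.target_position_range} spans {span} positions; "
                f"expected {2 * self.n_targets - 1} for {self.n_targets} targets "
                "(9 bins of length two plus 1 bin of length one)"
            )
        if hi > self.circles_total:
            raise ConfigurationError("target positions cannot exceed the circle count")
        n_choice = len(self.offer_values)
        if n_choice < 1 or len(set(self.offer_values)) != n_choice:
            raise ConfigurationError("offer_values must be a non-empty set of distinct integers")
        if self.trials_total != 2 * n_choice - 1:
            raise ConfigurationError(
                f"trials_total must equal {2 * n_choice - 1} (choice trials interleaved with "
                f"alternating forced trials), got {self.trials_total}"
            )

    @classmethod
    def for_experiment(cls, experiment: int) -> "TaskConfig":
        if experiment == 1:
            return cls(experiment=1, offer_values=tuple(range(1, 10)), trials_total=17)
        if experiment == 2:
            return cls(experiment=2, offer_values=tuple(range(2, 9)), trials_total=13)
        raise ConfigurationError(f"experiment must be 1 or 2, got {experiment!r}")

    @property
    def n_choice_trials(self) -> int:
        return len(self.offer_values)

    @property
    def n_forced_trials(self) -> int:
        return self.trials_total - self.n_choice_trials

    @classmethod
    def from_json(cls, text: str) -> "TaskConfig":
        """Build a config from a JSON document, rejecting unknown keys."""
        data = json.loads(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown TaskConfig keys: {sorted(unknown)}")
        for key in ("target_position_range", "offer_values"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(
            {
                "experiment": self.experiment,
                "circles_total": self.circles_total,
                "visible_concurrent": self.visible_concurrent,
                "n_targets": self.n_targets,
                "target_position_range": list(self.target_position_range),
                "offer_values": list(self.offer_values),
                "trials_total": self.trials_total,
                "full_reward": self.full_reward,
            }
        )


@dataclass(frozen=True)
class TrialPlan:
    """Schedule of a single trial before any behaviour is simulated."""

    trial_index: int
    trial_type: str
    framing: str
    offer_raw: int | None
    target_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.trial_type not in (CHOICE, FORCED_INTERNAL, FORCED_EXTERNAL):
            raise ValueError(f"bad trial_type {self.trial_type!r}")
        if self.framing not in FRAMINGS:
            raise ValueError(f"bad framing {self.framing!r}")
        if self.trial_type == CHOICE and self.offer_raw is None:
            raise ValueError("choice trials require an offer value")
        if self.trial_type != CHOICE and self.offer_raw is not None:
            raise ValueError("forced trials carry no offer value")
        pos = self.target_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("target positions must be strictly increasing")


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated trial: which strategy ran, and per-target hits."""

    strategy_used: str
    outcomes: tuple[int, ...]  # 1 = hit, 0 = miss, ordered by target position

    def __post_init__(self) -> None:
        if self.strategy_used not in (INTERNAL, EXTERNAL):
            raise ValueError(f"bad strategy {self.strategy_used!r}")
        if any(o not in (0, 1) for o in self.outcomes):
            raise ValueError("outcomes must be 0/1")

    @property
    def n_hits(self) -> int:
        return int(sum(self.outcomes))


def _draw_binned_positions(
    rng: np.random.Generator, config: TaskConfig
) -> tuple[list[tuple[int, int]], list[int]]:
    """Draw target positions and return both the bin layout and the draw.

    The 2*k-1 admissible sequence positions are partitioned into k adjacent
    bins: k-1 of length two and one of length one whose slot is uniform over
    the k bins.  One position is then drawn uniformly within each bin, so
    every bin contributes exactly one target.
    """
    lo, hi = config.target_position_range
    if hi - lo + 1 != 2 * config.n_targets - 1:
        raise ConfigurationError("target position range has the wrong size")
    short_bin = int(rng.integers(config.n_targets))
    bins: list[tuple[int, int]] = []
    positions: list[int] = []
    start = lo
    for b in range(config.n_targets):
        length = 1 if b == short_bin else 2
        bins.append((start, length))
        positions.append(start + int(rng.integers(length)))
        start += length
    return bins, positions


def generate_target_positions(rng: np.random.Generator, config: TaskConfig) -> list[int]:
    """Draw the sequence positions of the special circles for one trial.

    Returns ``config.n_targets`` distinct, sorted integers inside
    ``config.target_position_range`` (positions 7..25 in both experiments:
    the six circles already on screen at trial start cannot be targets).
    """
    _, positions = _draw_binned_positions(rng, config)
    return positions


def _transform_offer(value: int, framing: str, experiment: int) -> int:
    """Map a gain-scale offer to the raw value shown under the given framing."""
    if framing == GAIN:
        return value
    if experiment == 1:
        return value - 10  # gains 1..9 shown as losses -9..-1
    return 10 - value  # experiment 2: points lost, 2..8


def _block_plans(
    config: TaskConfig,
    framing: str,
    rng: np.random.Generator,
    start_index: int,
    forced_start: str,
) -> list[TrialPlan]:
    offers = [
        _transform_offer(int(v), framing, config.experiment)
        for v in rng.permutation(list(config.offer_values))
    ]
    forced_cycle = {FORCED_EXTERNAL: FORCED_INTERNAL, FORCED_INTERNAL: FORCED_EXTERNAL}
    plans: list[TrialPlan] = []
    next_forced = forced_start
    offer_iter = iter(offers)
    for i in range(config.trials_total):
        idx = start_index + i
        if i % 2 == 0:  # odd 1-based trial within the block -> free choice
            plans.append(
                TrialPlan(
                    trial_index=idx,
                    trial_type=CHOICE,
                    framing=framing,
                    offer_raw=next(offer_iter),
                    target_positions=tuple(generate_target_positions(rng, config)),
                )
            )
        else:
            plans.append(
                TrialPlan(
                    trial_index=idx,
                    trial_type=next_forced,
                    framing=framing,
                    offer_raw=None,
                    target_positions=tuple(generate_target_positions(rng, config)),
                )
            )
            next_forced = forced_cycle[next_forced]
    return plans


def build_session_plan(
    experiment: int,
    framing_assignment,
    rng: np.random.Generator,
    config: TaskConfig | None = None,
) -> list[TrialPlan]:
    """Build the ordered trial schedule of one participant's session.

    Experiment 1: ``framing_assignment`` is a single framing (``"gain"`` or
    ``"loss"``, assigned between participants); the session is one block of
    17 trials whose odd positions are choice trials carrying a random
    permutation of the nine offers (shown as −9..−1 under loss framing) and
    whose even positions alternate forced-external/forced-internal with a
    uniformly random starting type.

    Experiment 2: ``framing_assignment`` is the ordered pair of framings
    (block order, counterbalanced by the caller); each framing gets a block
    of 13 trials (7 choice with a permutation of offers 2..8, 6 forced
    alternating).  The forced starting type is random for the first block
    and reversed for the second.
    """
    if config is None:
        config = TaskConfig.for_experiment(experiment)
    if config.experiment != experiment:
        raise ConfigurationError("config does not match the requested experiment")

    forced_start = FORCED_EXTERNAL if rng.integers(2) == 0 else FORCED_INTERNAL
    if experiment == 1:
        if framing_assignment not in FRAMINGS:
            raise ConfigurationError(f"bad framing assignment {framing_assignment!r}")
        return _block_plans(config, framing_assignment, rng, 1, forced_start)
    if experiment == 2:
        order = tuple(framing_assignment)
        if sorted(order) != sorted(FRAMINGS):
            raise ConfigurationError(
                f"experiment 2 needs both framings in order, got {framing_assignment!r}"
            )
        other_start = FORCED_INTERNAL if forced_start == FORCED_EXTERNAL else FORCED_EXTERNAL
        first = _block_plans(config, order[0], rng, 1, forced_start)
        second = _block_plans(config, order[1], rng, 1 + config.trials_total, other_start)
        return first + second
    raise ConfigurationError(f"experiment must be 1 or 2, got {experiment!r}")


def simulate_trial(
    agent: "AgentParams",
    plan: TrialPlan,
    rng: np.random.Generator,
    strategy: str | None = None,
) -> TrialResult:
    """Simulate one trial's target outcomes for the given agent.

    Each target is an independent Bernoulli hit with probability
    ``agent.p_internal`` (internal strategy) or ``agent.p_external``
    (external strategy).  Forced trials imply their strategy; choice trials
    must arrive with the strategy already resolved by the agent's choice
    policy.
    """
    if plan.trial_type == FORCED_INTERNAL:
        strategy = INTERNAL
    elif plan.trial_type == FORCED_EXTERNAL:
        strategy = EXTERNAL
    elif strategy not in (INTERNAL, EXTERNAL):
        raise ValueError("choice trials require a resolved strategy")
    p = agent.p_internal if strategy == INTERNAL else agent.p_external
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"hit probability {p} outside [0, 1]")
    hits = (rng.random(len(plan.target_positions)) < p).astype(int)
    return TrialResult(strategy_used=strategy, outcomes=tuple(int(h) for h in hits))


def session_to_frame(
    participant_id: str,
    experiment: int,
    plans: Sequence[TrialPlan],
    results: Sequence[TrialResult],
) -> pd.DataFrame:
    """Serialize one simulated session to the tidy trial-table layout."""
    if len(plans) != len(results):
        raise ValueError("plans and results must align")
    rows = []
    for plan, result in zip(plans, results):
        rows.append(
            {
                "participant_id": participant_id,
                "experiment": experiment,
                "framing": plan.framing,
                "trial_index": plan.trial_index,
                "trial_type": plan.trial_type,
                "offer_raw": plan.offer_raw,
                "target_positions": ";".join(str(p) for p in plan.target_positions),
                "strategy_used": result.strategy_used,
                "n_hits": result.n_hits,
            }
        )
    return pd.DataFrame(rows)
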