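"""Synthetic participants for the optimal-reminders task.

An agent is a small generative model of one participant: how well they
remember targets with internal memory (``p_internal``) and with reminders
(``p_external``), what accuracy they *believe* they achieve with each
strategy (``conf_internal``/``conf_external``, percent), and how they choose
between strategies on free-choice trials.  Choice follows a lapse-augmented
logistic in the gain-equivalent offer value: the agent prefers reminders
when the offer exceeds its subjective indifference point, which shifts
upward by ``framing_shift`` points under loss framing (fewer reminders when
the offer is framed as a cost — the mechanism behind the framing effect the
analysis is built to detect).

Population defaults are calibrated to the group-level picture the task
reliably produces: roughly two-thirds accuracy from memory, near-ceiling
accuracy with reminders (the practice gate guarantees at least 80%), and
underconfident metacognitive reports.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields as dataclass_fields
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .task_engine import EXTERNAL, FRAMINGS, INTERNAL, LOSS


class InfeasibleSpecError(ValueError):
    """Raised when a population distribution cannot produce legal values."""


# ---------------------------------------------------------------------------
# distribution primitives


@dataclass(frozen=True)
class TruncNormal:
    """Normal(loc, scale) truncated to [low, high]; scale 0 degenerates to loc."""

    loc: float
    scale: float
    low: float = -math.inf
    high: float = math.inf

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise InfeasibleSpecError("scale must be non-negative")
        if self.low > self.high:
            raise InfeasibleSpecError(f"empty truncation interval [{self.low}, {self.high}]")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.scale == 0:
            if not (self.low <= self.loc <= self.high):
                raise InfeasibleSpecError(
                    f"degenerate location {self.loc} outside [{self.low}, {self.high}]"
                )
            return np.full(n, float(self.loc))
        a = (self.low - self.loc) / self.scale
        b = (self.high - self.loc) / self.scale
        return sps.truncnorm.rvs(a, b, loc=self.loc, scale=self.scale, size=n, random_state=rng)


@dataclass(frozen=True)
class LogNormal:
    """exp(Normal(mu, sigma)), optionally truncated; sigma 0 degenerates to exp(mu)."""

    mu: float
    sigma: float
    low: float = 0.0
    high: float = math.inf

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sigma < 0:
            raise InfeasibleSpecError("sigma must be non-negative")
        if self.sigma == 0:
            value = math.exp(self.mu)
            if not (self.low <= value <= self.high):
                raise InfeasibleSpecError("degenerate lognormal outside truncation bounds")
            return np.full(n, value)
        out = np.empty(n)
        filled = 0
        for _ in range(1000):
            draw = rng.lognormal(self.mu, self.sigma, size=n - filled)
            keep = draw[(draw >= self.low) & (draw <= self.high)]
            out[filled : filled + keep.size] = keep
            filled += keep.size
            if filled == n:
                return out
        raise InfeasibleSpecError("lognormal truncation bounds reject nearly all mass")


@dataclass(frozen=True)
class Beta:
    """Beta(a, b), rescaled to [low, high]."""

    a: float
    b: float
    low: float = 0.0
    high: float = 1.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.a <= 0 or self.b <= 0:
            raise InfeasibleSpecError("beta shape parameters must be positive")
        return self.low + (self.high - self.low) * rng.beta(self.a, self.b, size=n)


_DIST_TYPES = {"truncnorm": TruncNormal, "lognorm": LogNormal, "beta": Beta}
_DIST_NAMES = {v: k for k, v in _DIST_TYPES.items()}


def _dist_to_dict(dist) -> dict:
    d = {"dist": _DIST_NAMES[type(dist)]}
    for f in dataclass_fields(dist):
        d[f.name] = getattr(dist, f.name)
    return d


def _dist_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("dist")
    cls = _DIST_TYPES[kind]
    known = {f.name for f in dataclass_fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise InfeasibleSpecError(f"unknown {kind} keys: {sorted(unknown)}")
    return cls(**d)


# ---------------------------------------------------------------------------
# agents


@dataclass(frozen=True)
class AgentParams:
    """Generative description of one synthetic participant.

    ``subjective_ip`` lives on the gain-equivalent 1–9 point scale; under
    loss framing the effective indifference point is
    ``subjective_ip + framing_shift``.
    """

    p_internal: float
    p_external: float
    conf_internal: float
    conf_external: float
    subjective_ip: float
    framing_shift: float
    choice_slope: float
    lapse: float

    def __post_init__(self) -> None:
        for name in ("p_internal", "p_external"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("conf_internal", "conf_external"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if not 1.0 <= self.subjective_ip <= 9.0:
            raise ValueError(f"subjective_ip={self.subjective_ip} outside the 1–9 offer scale")
        if self.choice_slope <= 0:
            raise ValueError("choice_slope must be positive")
        if not 0.0 <= self.lapse <= 0.5:
            raise ValueError("lapse must lie in [0, 0.5]")


@dataclass(frozen=True)
class PopulationSpec:
    """Distributional recipe for sampling a cohort of agents.

    Confidence is generated relative to true accuracy
    (``conf = clip(100·p + offset, 0, 100)``) so that the population-level
    metacognitive bias is controlled directly by the offset distributions.
    The subjective indifference point is, by default, the agent's own
    normative indifference point plus an offset (``ip_policy="oip_offset"``);
    with ``ip_policy="confidence"`` it derives instead from the ratio of the
    agent's confidence reports, which couples underconfidence to reminder
    overuse.
    """

    n_agents: int
    seed: int | None = None
    p_internal: TruncNormal = TruncNormal(0.65, 0.12, 0.0, 1.0)
    p_external: TruncNormal = TruncNormal(0.95, 0.04, 0.8, 1.0)
    conf_internal_offset: TruncNormal = TruncNormal(-7.0, 25.0, -100.0, 100.0)
    conf_external_offset: TruncNormal = TruncNormal(-11.0, 14.0, -100.0, 100.0)
    subjective_ip_offset: TruncNormal = TruncNormal(-1.5, 1.2, -8.0, 8.0)
    framing_shift: TruncNormal = TruncNormal(1.0, 0.8, 0.0, math.inf)
    choice_slope: LogNormal = LogNormal(math.log(1.5), 0.3, 1e-3, math.inf)
    lapse: Beta = Beta(1.0, 19.0, 0.0, 0.5)
    ip_policy: str = "oip_offset"
    full_reward: float = 10.0
    ip_bounds: tuple[float, float] = (1.0, 9.0)

    def __post_init__(self) -> None:
        if self.n_agents <= 0:
            raise InfeasibleSpecError("n_agents must be positive")
        if self.ip_policy not in ("oip_offset", "confidence"):
            raise InfeasibleSpecError(f"unknown ip_policy {self.ip_policy!r}")

    _DIST_FIELDS = (
        "p_internal",
        "p_external",
        "conf_internal_offset",
        "conf_external_offset",
        "subjective_ip_offset",
        "framing_shift",
        "choice_slope",
        "lapse",
    )

    def to_dict(self) -> dict:
        out = {
            "n_agents": self.n_agents,
            "seed": self.seed,
            "ip_policy": self.ip_policy,
            "full_reward": self.full_reward,
            "ip_bounds": list(self.ip_bounds),
        }
        for name in self._DIST_FIELDS:
            out[name] = _dist_to_dict(getattr(self, name))
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PopulationSpec":
        data = dict(data)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise InfeasibleSpecError(f"unknown PopulationSpec keys: {sorted(unknown)}")
        for name in cls._DIST_FIELDS:
            if name in data and isinstance(data[name], dict):
                data[name] = _dist_from_dict(data[name])
        if "ip_bounds" in data:
            data["ip_bounds"] = tuple(data["ip_bounds"])
        return cls(**data)

    @classmethod
    def from_json(cls, text: str) -> "PopulationSpec":
        return cls.from_dict(json.loads(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def true_oip(p_internal: float, p_external: float, full_reward: float = 10.0,
             bounds: tuple[float, float] = (1.0, 9.0)) -> float:
    """Normative indifference point implied by an agent's true accuracies."""
    if p_external <= 0:
        raise ValueError("p_external must be positive")
    return float(np.clip(full_reward * p_internal / p_external, *bounds))


def sample_population(
    spec: PopulationSpec, rng: np.random.Generator | None = None
) -> list[AgentParams]:
    """Draw ``spec.n_agents`` agents; seeded and reproducible via ``spec.seed``."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_agents
    p_i = spec.p_internal.sample(rng, n)
    p_e = spec.p_external.sample(rng, n)
    conf_i = np.clip(100.0 * p_i + spec.conf_internal_offset.sample(rng, n), 0.0, 100.0)
    conf_e = np.clip(100.0 * p_e + spec.conf_external_offset.sample(rng, n), 0.0, 100.0)
    lo, hi = spec.ip_bounds
    if spec.ip_policy == "confidence":
        ratio = conf_i / np.maximum(conf_e, 1e-9)
        base = np.clip(spec.full_reward * ratio, lo, hi)
    else:
        base = np.clip(spec.full_reward * p_i / np.maximum(p_e, 1e-9), lo, hi)
    sip = np.clip(base + spec.subjective_ip_offset.sample(rng, n), lo, hi)
    shift = spec.framing_shift.sample(rng, n)
    slope = spec.choice_slope.sample(rng, n)
    lapse = np.clip(spec.lapse.sample(rng, n), 0.0, 0.5)
    return [
        AgentParams(
            p_internal=float(p_i[k]),
            p_external=float(p_e[k]),
            conf_internal=float(conf_i[k]),
            conf_external=float(conf_e[k]),
            subjective_ip=float(sip[k]),
            framing_shift=float(shift[k]),
            choice_slope=float(slope[k]),
            lapse=float(lapse[k]),
        )
        for k in range(n)
    ]


def population_to_frame(agents: Sequence[AgentParams]):
    """One row per agent, one column per parameter."""
    import pandas as pd

    return pd.DataFrame(
        [{f.name: getattr(a, f.name) for f in dataclass_fields(AgentParams)} for a in agents]
    )


def choice_probability(agent: AgentParams, offer_equiv: float, framing: str) -> float:
    """Probability the agent chooses reminders at a gain-equivalent offer.

    ``lapse/2 + (1 − lapse) · logistic(slope · (offer − s_f))`` where ``s_f``
    is the subjective indifference point, shifted by ``framing_shift`` under
    loss framing.  Strictly increasing in the offer.
    """
    if framing not in FRAMINGS:
        raise ValueError(f"bad framing {framing!r}")
    s_f = agent.subjective_ip + (agent.framing_shift if framing == LOSS else 0.0)
    core = 1.0 / (1.0 + math.exp(-agent.choice_slope * (offer_equiv - s_f)))
    return agent.lapse / 2.0 + (1.0 - agent.lapse) * core


def decide_strategy(
    agent: AgentParams, offer_equiv: float, framing: str, rng: np.random.Generator
) -> str:
    """Resolve one free-choice trial: reminders (external) or own memory."""
    p = choice_probability(agent, offer_equiv, framing)
    return EXTERNAL if rng.random() < p else INTERNAL


def report_confidence(
    agent: AgentParams,
    strategy: str,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
) -> float:
    """The agent's pre-task confidence report (percent) for a strategy.

    Optional bounded reporting noise; by default the report equals the
    agent's confidence parameter exactly.
    """
    if strategy == INTERNAL:
        value = agent.conf_internal
    elif strategy == EXTERNAL:
        value = agent.conf_external
    else:
        raise ValueError(f"bad strategy {strategy!r}")
    if noise_sd > 0.0:
        if rng is None:
            raise ValueError("reporting noise requires an rng")
        value = float(np.clip(value + rng.normal(0.0, noise_sd), 0.0, 100.0))
    return float(value)
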