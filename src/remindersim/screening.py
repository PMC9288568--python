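"""Preregistered participant-exclusion rules, with reason codes.

Between-participants design (rules a–e): floor checks on forced-trial
accuracies, an ordering check (internal accuracy must not beat external),
a negative offer-choice point-biserial correlation (random strategy
selection), and a 2.5-SD outlier rule on the reminder bias.  The
within-participants design replaces the SD rule with three scaled-MAD rules
(e–g) on the mean reminder bias, the gain–loss bias difference, and the
internal metacognitive bias.

Distributional rules are applied once, non-iteratively, with group
statistics computed over the participants that survive the deterministic
rules (a)–(d); an ``iterate`` switch re-applies them to convergence for
sensitivity checks.  MAD units use the 1.4826 consistency constant (a raw
MAD is available via ``mad_constant=1.0``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task_engine import CHOICE, EXTERNAL
from .measures import equivalent_gain_value

MAD_CONSTANT = 1.4826


@dataclass(frozen=True)
class ExclusionReport:
    participant_id: str
    excluded: bool
    reasons: tuple[str, ...]
    diagnostics: dict

    def __post_init__(self) -> None:
        if self.excluded != bool(self.reasons):
            raise ValueError("excluded flag must match non-empty reasons")


def point_biserial(offers, choices) -> float:
    """Pearson correlation between offer values and binary strategy choices.

    Returns NaN (a flagged non-value that never triggers exclusion) when
    either vector is constant.
    """
    x = np.asarray(offers, dtype=float)
    y = np.asarray(choices, dtype=float)
    if x.shape != y.shape:
        raise ValueError("offers and choices must have equal length")
    if x.size < 2:
        raise ValueError("need at least two trials")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("choices must be binary")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def mad_units(values, constant: float = MAD_CONSTANT) -> np.ndarray:
    """Deviation of each value from the median, in scaled-MAD units."""
    x = np.asarray(values, dtype=float)
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    scaled = constant * mad
    dev = np.abs(x - med)
    if scaled == 0:
        return np.where(dev == 0, 0.0, np.inf)
    return dev / scaled


def _choice_correlation(trials: pd.DataFrame, experiment: int) -> float:
    ch = trials[trials["trial_type"] == CHOICE]
    offers = [
        equivalent_gain_value(o, f, experiment)
        for o, f in zip(ch["offer_raw"].astype(float), ch["framing"])
    ]
    picks = (ch["strategy_used"] == EXTERNAL).astype(int).to_numpy()
    return point_biserial(offers, picks)


def _deterministic_rules(
    pid: str,
    meas: pd.DataFrame,
    trials: pd.DataFrame,
    experiment: int,
    acc_fi_floor: float,
    acc_fe_floor: float,
) -> tuple[list[str], dict]:
    """Rules (a)–(d), shared by both designs (accuracies averaged over framings)."""
    reasons: list[str] = []
    mean_fi = float(meas["acc_fi"].mean())
    mean_fe = float(meas["acc_fe"].mean())
    diagnostics = {"mean_acc_fi": mean_fi, "mean_acc_fe": mean_fe}
    if mean_fi < acc_fi_floor:
        reasons.append("a")
    if mean_fe < acc_fe_floor:
        reasons.append("b")
    if (meas["acc_fi"] > meas["acc_fe"]).any():
        reasons.append("c")
    r = _choice_correlation(trials, experiment)
    diagnostics["point_biserial"] = r
    if not math.isnan(r) and r < 0:
        reasons.append("d")
    return reasons, diagnostics


def apply_exclusions_exp1(
    measures: pd.DataFrame,
    trials: pd.DataFrame,
    sd_threshold: float = 2.5,
    acc_fi_floor: float = 0.10,
    acc_fe_floor: float = 0.70,
    include_failed_in_group_stats: bool = False,
    iterate: bool = False,
) -> list[ExclusionReport]:
    """Between-participants exclusion pipeline (rules a–e).

    Rule (e) flags reminder-bias scores more than ``sd_threshold`` group
    standard deviations from the group mean, with group statistics computed
    over participants surviving (a)–(d) unless
    ``include_failed_in_group_stats`` is set.
    """
    if measures.empty:
        raise ValueError("empty cohort")
    base: dict[str, tuple[list[str], dict]] = {}
    for pid, meas in measures.groupby("participant_id", sort=True):
        t = trials[trials["participant_id"] == pid]
        base[pid] = _deterministic_rules(pid, meas, t, 1, acc_fi_floor, acc_fe_floor)

    bias = measures.set_index("participant_id")["reminder_bias"]
    pool = list(bias.index) if include_failed_in_group_stats else [
        pid for pid, (reasons, _) in base.items() if not reasons
    ]
    # group statistics come from the (a)-(d) survivors; the deviation rule
    # itself is evaluated for every participant, the rules being independent
    flagged: set[str] = set()
    deviations: dict[str, float] = {}
    while True:
        group = bias.loc[[p for p in pool if p not in flagged]]
        mean, sd = float(group.mean()), float(group.std(ddof=1))
        deviations = {
            pid: (abs(float(bias[pid]) - mean) / sd if sd > 0 else float("nan"))
            for pid in bias.index
        }
        new = {
            pid
            for pid, dev in deviations.items()
            if pid not in flagged and not math.isnan(dev) and dev > sd_threshold
        }
        if not new:
            break
        flagged |= new
        if not iterate:
            break

    reports = []
    for pid, (reasons, diag) in base.items():
        diag = dict(diag)
        diag["bias_deviation_sd"] = deviations.get(pid, float("nan"))
        reasons = list(reasons)
        if pid in flagged:
            reasons.append("e")
        reports.append(
            ExclusionReport(pid, excluded=bool(reasons), reasons=tuple(reasons), diagnostics=diag)
        )
    return reports


def apply_exclusions_exp2(
    measures: pd.DataFrame,
    trials: pd.DataFrame,
    mad_threshold: float = 3.0,
    mad_constant: float = MAD_CONSTANT,
    acc_fi_floor: float = 0.10,
    acc_fe_floor: float = 0.70,
    include_failed_in_group_stats: bool = False,
) -> list[ExclusionReport]:
    """Within-participants exclusion pipeline (rules a–g).

    Expects two measure rows per participant (gain and loss) carrying a
    ``metacog_internal_bias`` column.  Rules (e)–(g) flag scores beyond
    ``mad_threshold`` scaled-MAD units on, respectively, the mean reminder
    bias, the gain−loss bias difference, and the internal metacognitive
    bias, each computed over participants surviving (a)–(d).
    """
    if measures.empty:
        raise ValueError("empty cohort")
    wide = measures.pivot(index="participant_id", columns="framing", values="reminder_bias")
    if wide.isna().any().any() or not {"gain", "loss"} <= set(wide.columns):
        raise ValueError("each participant needs measures in both framing conditions")
    if "metacog_internal_bias" not in measures.columns:
        raise ValueError("experiment-2 screening needs the internal metacognitive bias")

    base: dict[str, tuple[list[str], dict]] = {}
    for pid, meas in measures.groupby("participant_id", sort=True):
        t = trials[trials["participant_id"] == pid]
        base[pid] = _deterministic_rules(pid, meas, t, 2, acc_fi_floor, acc_fe_floor)

    mean_bias = wide.mean(axis=1)
    diff_bias = wide["gain"] - wide["loss"]
    meta = measures.groupby("participant_id")["metacog_internal_bias"].first()

    pool = list(base) if include_failed_in_group_stats else [
        pid for pid, (reasons, _) in base.items() if not reasons
    ]
    # median and MAD from the (a)-(d) survivors; every participant is then
    # scored against them, the rules being independent
    scores = {"e": mean_bias, "f": diff_bias, "g": meta}
    units: dict[str, pd.Series] = {}
    for code, series in scores.items():
        ref = series.loc[pool].to_numpy()
        med = float(np.median(ref))
        scaled = mad_constant * float(np.median(np.abs(ref - med)))
        dev = (series - med).abs()
        units[code] = dev / scaled if scaled > 0 else dev.map(lambda d: 0.0 if d == 0 else np.inf)

    reports = []
    for pid, (reasons, diag) in base.items():
        reasons = list(reasons)
        diag = dict(diag)
        diag["mean_reminder_bias"] = float(mean_bias[pid])
        diag["bias_difference"] = float(diff_bias[pid])
        diag["metacog_internal_bias"] = float(meta[pid])
        for code in ("e", "f", "g"):
            value = float(units[code][pid])
            diag[f"mad_units_{code}"] = value
            if value > mad_threshold:
                reasons.append(code)
        reports.append(
            ExclusionReport(pid, excluded=bool(reasons), reasons=tuple(reasons), diagnostics=diag)
        )
    return reports


def kept_ids(reports: list[ExclusionReport]) -> list[str]:
    return [r.participant_id for r in reports if not r.excluded]


def reports_to_frame(reports: list[ExclusionReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "participant_id": r.participant_id,
            "excluded": r.excluded,
            "reasons": "".join(r.reasons),
        }
        row.update(r.diagnostics)
        rows.append(row)
    return pd.DataFrame(rows)


def reason_counts(reports: list[ExclusionReport]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in reports:
        for code in r.reasons:
            counts[code] = counts.get(code, 0) + 1
    return counts
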