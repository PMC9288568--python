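"""Per-participant outcome measures of the optimal-reminders task.

Five behavioural variables are computed per participant and framing
condition:

* ``ACC_FI`` / ``ACC_FE`` — mean target accuracy on forced-internal and
  forced-external trials (proportion of special circles handled correctly).
* ``OIP`` — the optimal indifference point: the reminder offer at which an
  unbiased participant should be indifferent between strategies, defined by
  ``OIP · ACC_FE = full_reward · ACC_FI`` and clamped to the offer range so
  it is commensurable with the actual indifference point.
* ``AIP`` — the actual indifference point: the 50% crossing of a sigmoid
  fitted by maximum likelihood to the binary strategy choices (1 =
  reminders) over the gain-equivalent offers, clamped to the offer range.
* reminder bias — ``OIP − AIP``; positive means the participant uses
  reminders more than their own accuracies justify.

The within-participants design adds two metacognitive variables: the
difference between predicted accuracy (percent) and actual accuracy for
each strategy, negative values indicating underconfidence.

Loss-framed offers are mapped to their gain equivalents before any
indifference-point arithmetic so that the two framings share one scale:
``raw + 10`` for the between-participants design (offers shown as −9..−1)
and ``10 − raw`` for the within-participants design (offers shown as points
lost, 2..8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, ndtr

from .task_engine import (
    CHOICE,
    EXTERNAL,
    FORCED_EXTERNAL,
    FORCED_INTERNAL,
    GAIN,
    LOSS,
    TrialPlan,
    TrialResult,
)

OFFER_BOUNDS = {1: (1.0, 9.0), 2: (2.0, 8.0)}
SLOPE_CAP = 50.0
SLOPE_FLOOR = 0.01


@dataclass(frozen=True)
class PsychometricFit:
    """Result of fitting the two-parameter choice sigmoid.

    ``location`` is the actual indifference point after clamping to the
    offer bounds; ``location_raw`` is the unclamped maximizer.  Degenerate
    response patterns (all-reminders / all-memory) resolve directly to the
    lower / upper bound.
    """

    location: float
    location_raw: float
    slope: float
    log_likelihood: float
    converged: bool
    n_choices: int
    degenerate: bool = False


@dataclass(frozen=True)
class ParticipantMeasures:
    participant_id: str
    framing: str
    acc_fi: float
    acc_fe: float
    oip: float
    aip: float
    reminder_bias: float
    metacog_internal_bias: float | None = None
    metacog_external_bias: float | None = None


def accuracy(session: Iterable[tuple[TrialPlan, TrialResult]], trial_type: str) -> float:
    """Total hits over total targets across all trials of the given forced type."""
    hits = 0
    targets = 0
    for plan, result in session:
        if plan.trial_type == trial_type:
            hits += result.n_hits
            targets += len(plan.target_positions)
    if targets == 0:
        raise ValueError(f"no trials of type {trial_type!r}")
    return hits / targets


def equivalent_gain_value(offer_raw: float, framing: str, experiment: int) -> float:
    """Map a raw displayed offer onto the gain-equivalent point scale."""
    lo, hi = OFFER_BOUNDS[experiment]
    if framing == GAIN:
        if not lo <= offer_raw <= hi:
            raise ValueError(f"gain offer {offer_raw} outside [{lo}, {hi}]")
        return float(offer_raw)
    if framing != LOSS:
        raise ValueError(f"bad framing {framing!r}")
    if experiment == 1:
        if not -9 <= offer_raw <= -1:
            raise ValueError(f"loss offer {offer_raw} outside [-9, -1]")
        return float(offer_raw + 10)
    if not lo <= offer_raw <= hi:
        raise ValueError(f"loss offer {offer_raw} outside [{lo}, {hi}]")
    return float(10 - offer_raw)


def compute_oip(
    acc_fi: float,
    acc_fe: float,
    full_reward: float = 10.0,
    bounds: tuple[float, float] = (1.0, 9.0),
) -> float:
    """Optimal indifference point, clamped to the offer bounds."""
    if not 0.0 <= acc_fi <= 1.0 or not 0.0 <= acc_fe <= 1.0:
        raise ValueError("accuracies must lie in [0, 1]")
    if acc_fe == 0.0:
        raise ValueError("forced-external accuracy of zero leaves the optimal point undefined")
    return float(np.clip(full_reward * acc_fi / acc_fe, *bounds))


def reminder_bias(oip: float, aip: float) -> float:
    """OIP − AIP; positive = over-reliance on reminders."""
    return oip - aip


def metacognitive_bias(confidence_pct: float, accuracy_prop: float) -> float:
    """Confidence (percent) minus actual accuracy; positive = overconfidence."""
    if not 0.0 <= confidence_pct <= 100.0:
        raise ValueError("confidence must lie in [0, 100]")
    if not 0.0 <= accuracy_prop <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    return confidence_pct - 100.0 * accuracy_prop


def _link_cdf(z: np.ndarray, link: str) -> np.ndarray:
    if link == "logistic":
        return expit(z)
    if link in ("normal", "probit"):
        return ndtr(z)
    raise ValueError(f"unknown link {link!r}")


def _nll_terms(z: np.ndarray, y_is_one: bool, link: str) -> np.ndarray:
    """-log P(choice | z) in an underflow-free form, so near-separable data
    keep a resolvable likelihood surface instead of a float-flat plateau."""
    if link == "logistic":
        # -log sigma(z) = softplus(-z); -log(1 - sigma(z)) = softplus(z)
        return np.logaddexp(0.0, -z if y_is_one else z)
    if link in ("normal", "probit"):
        from scipy.stats import norm

        return -(norm.logcdf(z) if y_is_one else norm.logsf(z))
    raise ValueError(f"unknown link {link!r}")


def _nll(loc: float, log_slope: float, x: np.ndarray, y: np.ndarray, link: str) -> float:
    z = math.exp(log_slope) * (x - loc)
    ones = y == 1.0
    return float(_nll_terms(z[ones], True, link).sum() + _nll_terms(z[~ones], False, link).sum())


def fit_aip(
    choices: Sequence[tuple[float, int]],
    bounds: tuple[float, float],
    link: str = "logistic",
    slope_cap: float = SLOPE_CAP,
    slope_floor: float = SLOPE_FLOOR,
) -> PsychometricFit:
    """Maximum-likelihood fit of the choice sigmoid; returns the bounded AIP.

    ``choices`` pairs each gain-equivalent offer with the binary choice
    (1 = reminders, 0 = own memory).  The location is optimized over a box
    extending past the offer bounds and then clamped; the slope is
    constrained to ``[slope_floor, slope_cap]`` so that perfectly separable
    response patterns (a single observation per offer makes these common)
    resolve to the likelihood-maximizing location at the slope cap — the
    midpoint of the step interval.  A coarse likelihood-grid scan seeds a
    quasi-Newton polish, which keeps the fit effectively global.
    """
    if len(choices) == 0:
        raise ValueError("choices must be non-empty")
    x = np.asarray([c[0] for c in choices], dtype=float)
    y = np.asarray([c[1] for c in choices], dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("choices must be coded 0/1")
    lo, hi = bounds
    n = len(choices)

    if y.min() == y.max():
        # always-reminders: indifference at or below the smallest offer;
        # always-memory: the mirror case.
        loc = lo if y[0] == 1.0 else hi
        ll = -_nll(loc, math.log(slope_cap), x, y, link)
        return PsychometricFit(
            location=float(loc),
            location_raw=float(loc),
            slope=slope_cap,
            log_likelihood=ll,
            converged=True,
            n_choices=n,
            degenerate=True,
        )

    ones = y == 1.0
    x0_max, x1_min = x[~ones].max(), x[ones].min()
    if x0_max < x1_min:
        # perfectly separable responses: the likelihood climbs as the slope
        # grows, so the slope sits at its cap and the location tie-break is
        # the likelihood maximizer there - the midpoint of the step interval
        loc_raw = (x0_max + x1_min) / 2.0
        return PsychometricFit(
            location=float(np.clip(loc_raw, lo, hi)),
            location_raw=float(loc_raw),
            slope=slope_cap,
            log_likelihood=-_nll(loc_raw, math.log(slope_cap), x, y, link),
            converged=True,
            n_choices=n,
        )

    loc_lo, loc_hi = lo - 5.0, hi + 5.0
    ls_lo, ls_hi = math.log(slope_floor), math.log(slope_cap)

    # coarse grid over (location, log slope) to seed the polish
    locs = np.linspace(lo - 2.0, hi + 2.0, 41)
    log_slopes = np.log(np.geomspace(max(slope_floor, 0.05), slope_cap, 9))
    z = np.exp(log_slopes)[None, :, None] * (x[None, None, :] - locs[:, None, None])
    nll_grid = (
        _nll_terms(z[:, :, ones], True, link).sum(axis=2)
        + _nll_terms(z[:, :, ~ones], False, link).sum(axis=2)
    )
    i, j = np.unravel_index(int(np.argmin(nll_grid)), nll_grid.shape)
    start = (float(locs[i]), float(log_slopes[j]))
    best_nll = float(nll_grid[i, j])
    best = start
    converged = False

    res = minimize(
        lambda th: _nll(th[0], th[1], x, y, link),
        start,
        method="L-BFGS-B",
        bounds=[(loc_lo, loc_hi), (ls_lo, ls_hi)],
    )
    if np.isfinite(res.fun) and res.fun <= best_nll + 1e-12:
        best = (float(res.x[0]), float(res.x[1]))
        best_nll = float(res.fun)
        converged = bool(res.success)

    loc_raw, log_slope = best
    return PsychometricFit(
        location=float(np.clip(loc_raw, lo, hi)),
        location_raw=loc_raw,
        slope=float(math.exp(log_slope)),
        log_likelihood=-best_nll,
        converged=converged,
        n_choices=n,
    )


def _n_targets(target_positions: str) -> int:
    return target_positions.count(";") + 1


def measures_from_trials(
    trials: pd.DataFrame,
    experiment: int,
    participants: pd.DataFrame | None = None,
    link: str = "logistic",
    pool_accuracy: bool = True,
) -> pd.DataFrame:
    """Compute the per-participant × framing measure table from tidy trials.

    ``participants`` (needed for the within-participants design's
    metacognitive measures) carries one row per participant with
    ``conf_internal`` and ``conf_external`` columns — the single pre-task
    confidence reports.  With ``pool_accuracy`` (default) those reports are
    compared against forced-trial accuracy pooled across both framing
    blocks, matching a one-off rating elicited before the task.
    """
    bounds = OFFER_BOUNDS[experiment]
    trials = trials.copy()
    trials["n_targets"] = trials["target_positions"].map(_n_targets)

    rows = []
    for (pid, framing), grp in trials.groupby(["participant_id", "framing"], sort=True):
        fi = grp[grp["trial_type"] == FORCED_INTERNAL]
        fe = grp[grp["trial_type"] == FORCED_EXTERNAL]
        if fi.empty or fe.empty:
            raise ValueError(f"participant {pid!r} lacks forced trials under {framing!r}")
        acc_fi = fi["n_hits"].sum() / fi["n_targets"].sum()
        acc_fe = fe["n_hits"].sum() / fe["n_targets"].sum()

        ch = grp[grp["trial_type"] == CHOICE]
        offers = [
            equivalent_gain_value(o, framing, experiment) for o in ch["offer_raw"].astype(float)
        ]
        picks = (ch["strategy_used"] == EXTERNAL).astype(int).tolist()
        fit = fit_aip(list(zip(offers, picks)), bounds=bounds, link=link)
        oip = compute_oip(acc_fi, acc_fe, bounds=bounds)
        rows.append(
            {
                "participant_id": pid,
                "framing": framing,
                "acc_fi": acc_fi,
                "acc_fe": acc_fe,
                "oip": oip,
                "aip": fit.location,
                "aip_raw": fit.location_raw,
                "aip_slope": fit.slope,
                "fit_converged": fit.converged,
                "reminder_bias": reminder_bias(oip, fit.location),
            }
        )
    out = pd.DataFrame(rows)

    if participants is not None and {"conf_internal", "conf_external"} <= set(participants.columns):
        conf = participants.set_index("participant_id")[["conf_internal", "conf_external"]]
        if pool_accuracy:
            pooled = (
                trials[trials["trial_type"].isin([FORCED_INTERNAL, FORCED_EXTERNAL])]
                .groupby(["participant_id", "trial_type"])
                .apply(
                    lambda g: g["n_hits"].sum() / g["n_targets"].sum(), include_groups=False
                )
                .unstack("trial_type")
            )
            acc_i = out["participant_id"].map(pooled[FORCED_INTERNAL])
            acc_e = out["participant_id"].map(pooled[FORCED_EXTERNAL])
        else:
            acc_i = out["acc_fi"]
            acc_e = out["acc_fe"]
        out["metacog_internal_bias"] = (
            out["participant_id"].map(conf["conf_internal"]) - 100.0 * acc_i
        )
        out["metacog_external_bias"] = (
            out["participant_id"].map(conf["conf_external"]) - 100.0 * acc_e
        )
    return out
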