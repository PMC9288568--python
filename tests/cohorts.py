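"""Hand-constructed toy cohorts with known exclusion outcomes.

Each builder returns ``(measures, trials, expected_reasons)`` where
``expected_reasons`` maps participant id -> the exact set of exclusion
reason codes that participant must trigger.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _choice_trials(pid: str, offers, picks, framing: str = "gain") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": pid,
            "experiment": 1,
            "framing": framing,
            "trial_index": np.arange(1, len(offers) + 1),
            "trial_type": "choice",
            "offer_raw": offers,
            "strategy_used": ["external" if c else "internal" for c in picks],
            "n_hits": 8,
        }
    )


def _sane_picks(offers, cutoff=5):
    return [1 if o >= cutoff else 0 for o in offers]


def build_exp1_cohort():
    """20 participants: one each failing rules b, c, d, e; the rest clean.

    Clean reminder-bias scores sit in a tight band around 1 so that the
    single wild score (bias 40) is the only one beyond 2.5 group SDs.
    """
    offers = list(range(1, 10))
    rows, trials, expected = [], [], {}
    clean_bias = [0.6, 0.8, 1.0, 1.2, 1.4, 0.7, 0.9, 1.1, 1.3, 0.5,
                  1.5, 0.65, 0.85, 1.05, 1.25, 1.45]
    pid_i = 0

    def add(pid, acc_fi, acc_fe, bias, picks, reasons):
        rows.append(
            {
                "participant_id": pid,
                "framing": "gain",
                "acc_fi": acc_fi,
                "acc_fe": acc_fe,
                "oip": min(9.0, 10.0 * acc_fi / acc_fe),
                "aip": min(9.0, 10.0 * acc_fi / acc_fe) - bias,
                "reminder_bias": bias,
            }
        )
        trials.append(_choice_trials(pid, offers, picks))
        expected[pid] = set(reasons)

    for bias in clean_bias:
        pid_i += 1
        add(f"c{pid_i:02d}", 0.65, 0.95, bias, _sane_picks(offers), set())
    add("x_b", 0.40, 0.60, 1.0, _sane_picks(offers), {"b"})
    add("x_c", 0.90, 0.85, 1.0, _sane_picks(offers), {"c"})
    add("x_d", 0.65, 0.95, 1.0, [1 if o <= 4 else 0 for o in offers], {"d"})
    add("x_e", 0.65, 0.95, 40.0, _sane_picks(offers), {"e"})
    return pd.DataFrame(rows), pd.concat(trials, ignore_index=True), expected


def build_exp2_cohort():
    """12 participants x 2 framings with rules d–g each triggered exactly once.

    ``x_dg`` fails both the choice-correlation rule and the metacognitive
    MAD rule, so both codes must be recorded.
    """
    offers = list(range(2, 9))
    rows, trials, expected = [], [], {}
    clean_bias = [(0.3, 0.5), (0.6, 0.4), (0.5, 0.7), (0.7, 0.3), (0.2, 0.6),
                  (0.45, 0.75), (0.55, 0.45), (0.65, 0.55)]

    def add(pid, bias_gain, bias_loss, metabias, picks_fn, reasons):
        for framing, bias in (("gain", bias_gain), ("loss", bias_loss)):
            rows.append(
                {
                    "participant_id": pid,
                    "framing": framing,
                    "acc_fi": 0.65,
                    "acc_fe": 0.95,
                    "oip": 6.8,
                    "aip": 6.8 - bias,
                    "reminder_bias": bias,
                    "metacog_internal_bias": metabias,
                }
            )
            raw = offers if framing == "gain" else [10 - o for o in offers]
            equiv = offers
            t = _choice_trials(pid, raw, picks_fn(equiv), framing)
            t["experiment"] = 2
            trials.append(t)
        expected[pid] = set(reasons)

    for i, (bg, bl) in enumerate(clean_bias, start=1):
        add(f"c{i:02d}", bg, bl, -7.0 + i, _sane_picks, set())
    add("x_e", 30.0, 30.0, -3.0, _sane_picks, {"e"})
    add("x_f", 20.25, -19.75, -4.0, _sane_picks, {"f"})
    add("x_g", 0.5, 0.5, -90.0, _sane_picks, {"g"})
    add("x_dg", 0.5, 0.5, 80.0, lambda eq: [1 if o <= 4 else 0 for o in eq], {"d", "g"})
    return pd.DataFrame(rows), pd.concat(trials, ignore_index=True), expected
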