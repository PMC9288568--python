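"""Compute per-participant measures from the simulated cohorts.

For each participant and framing condition: forced-trial accuracies, the
optimal indifference point (OIP), the fitted actual indifference point
(AIP), the reminder bias (OIP - AIP), and - for the within-participants
experiment - the metacognitive biases against pooled forced accuracy.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd  # noqa: E402

from remindersim import measures_from_trials  # noqa: E402

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for experiment in (1, 2):
        trials = pd.read_csv(RESULTS / f"exp{experiment}_trials.csv",
                             float_precision="round_trip")
        participants = pd.read_csv(RESULTS / f"exp{experiment}_participants.csv",
                                   float_precision="round_trip")
        measures = measures_from_trials(trials, experiment, participants=participants)
        out = RESULTS / f"exp{experiment}_measures.csv"
        measures.to_csv(out, index=False, float_format="%.17g")
        by_framing = measures.groupby("framing")[["acc_fi", "acc_fe", "oip", "aip",
                                                  "reminder_bias"]].mean()
        print(f"experiment {experiment} -> {out.name}")
        print(by_framing.round(3).to_string())


if __name__ == "__main__":
    main()
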