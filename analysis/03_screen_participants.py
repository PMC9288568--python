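"""Apply the preregistered exclusion rules and log the reason counts.

Experiment 1 uses rules a-e (accuracy floors, accuracy ordering, negative
offer-choice correlation, 2.5-SD reminder-bias outliers); experiment 2 uses
rules a-g with 3-scaled-MAD outlier screening on the mean bias, the bias
difference, and the internal metacognitive bias.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd  # noqa: E402

from remindersim import apply_exclusions_exp1, apply_exclusions_exp2, kept_ids  # noqa: E402
from remindersim.screening import reason_counts, reports_to_frame  # noqa: E402

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for experiment in (1, 2):
        trials = pd.read_csv(RESULTS / f"exp{experiment}_trials.csv",
                             float_precision="round_trip")
        measures = pd.read_csv(RESULTS / f"exp{experiment}_measures.csv",
                               float_precision="round_trip")
        apply = apply_exclusions_exp1 if experiment == 1 else apply_exclusions_exp2
        reports = apply(measures, trials)
        frame = reports_to_frame(reports)
        out = RESULTS / f"exp{experiment}_exclusions.csv"
        frame.to_csv(out, index=False, float_format="%.17g")
        kept = len(kept_ids(reports))
        print(
            f"experiment {experiment}: kept {kept}/{len(reports)}; "
            f"exclusions by reason {reason_counts(reports) or '{}'} -> {out.name}"
        )


if __name__ == "__main__":
    main()
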