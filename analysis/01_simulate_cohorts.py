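"""Simulate both framing experiments' cohorts and write the tidy tables.

Experiment 1: 141 synthetic participants, each randomly assigned to gain or
loss framing, performing one 17-trial session.  Experiment 2: 300 synthetic
participants, each performing counterbalanced gain and loss blocks of 13
trials with pre-task confidence reports.  Outputs land under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from remindersim import RunConfig, simulate_cohort  # noqa: E402

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = {1: 11, 2: 22}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    for experiment in (1, 2):
        config = RunConfig(experiment=experiment, seed=SEED[experiment])
        participants, trials = simulate_cohort(config)
        pdir = RESULTS / f"exp{experiment}_participants.csv"
        tdir = RESULTS / f"exp{experiment}_trials.csv"
        participants.to_csv(pdir, index=False, float_format="%.17g")
        trials.to_csv(tdir, index=False, float_format="%.17g")
        (RESULTS / f"exp{experiment}_config.json").write_text(config.to_json())
        n_choice = int((trials["trial_type"] == "choice").sum())
        print(
            f"experiment {experiment}: simulated {len(participants)} participants, "
            f"{len(trials)} trials ({n_choice} free-choice) -> {tdir.name}"
        )


if __name__ == "__main__":
    main()
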