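"""Run the full inferential battery on each screened cohort.

Experiment 1: accuracy and bias mixed ANOVAs, one-tailed per-framing bias
tests, OIP-AIP correlations and their independent comparison.  Experiment
2: within-subjects accuracy ANOVA, bias tests, the paired framing contrast,
correlation comparisons, metacognitive tests, and the random-intercept
model-selection ladder.  Reports are written as JSON.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd  # noqa: E402

from remindersim import RunConfig, analyze_cohort  # noqa: E402

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for experiment in (1, 2):
        config = RunConfig.from_json((RESULTS / f"exp{experiment}_config.json").read_text())
        trials = pd.read_csv(RESULTS / f"exp{experiment}_trials.csv",
                             float_precision="round_trip")
        participants = pd.read_csv(RESULTS / f"exp{experiment}_participants.csv",
                                   float_precision="round_trip")
        report, _, _ = analyze_cohort(trials, participants, config)
        out = RESULTS / f"exp{experiment}_report.json"
        out.write_text(json.dumps(report, indent=2, sort_keys=True))

        analyses = report["analyses"]
        print(f"experiment {experiment} -> {out.name}")
        if experiment == 1:
            inter = next(r for r in analyses["bias_anova"]["rows"]
                         if r["effect"] == "ip_type:framing")
            print(f"  framing x indifference-point interaction: "
                  f"F(1,{inter['df2']:.0f}) = {inter['F']:.2f}, p = {inter['p']:.4f}, "
                  f"partial eta^2 = {inter['partial_eta_sq']:.3f}")
            for framing in ("gain", "loss"):
                t = analyses["bias_tests"][framing]
                print(f"  {framing} bias: t({t['df']}) = {t['statistic']:.2f}, "
                      f"p = {t['p_value']:.2e}, d_z = {t['effect_size']:.2f}")
        else:
            paired = analyses["bias_framing_paired"]
            print(f"  gain vs loss bias: t({paired['df']}) = {paired['statistic']:.2f}, "
                  f"p = {paired['p_value']:.2e}, d_z = {paired['effect_size']:.2f}")
            for cmp in analyses["model_selection"]["comparisons"]:
                print(f"  LRT (+{cmp['k1'] - cmp['k0']} term): chi2({cmp['df']}) = "
                      f"{cmp['chi_square']:.2f}, p = {cmp['p_value']:.4f}, "
                      f"AIC {cmp['aic0']:.1f} -> {cmp['aic1']:.1f}")


if __name__ == "__main__":
    main()
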