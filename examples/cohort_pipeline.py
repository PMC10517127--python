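"""Simulate a small three-group cohort and run the full analysis pipeline.

Writes images + covariates to a temporary directory, measures every eye
(quality gate, obstructive + contralateral quadrants, vascular metrics),
and prints the group comparison, regression, and duration sub-analysis.
"""

import tempfile
from pathlib import Path

import pandas as pd

from perivasc import RunConfig, SyntheticConfig, run_analyze, run_report, simulate_to_dir

config = SyntheticConfig(seed=7, side_px=160, n_per_group=(15, 10, 15))

with tempfile.TemporaryDirectory() as tmp:
    sim_dir = Path(tmp) / "cohort"
    simulate_to_dir(config, sim_dir)

    run_config = RunConfig(input_dir=sim_dir)
    results, exclusions = run_analyze(run_config)
    covariates = pd.read_csv(sim_dir / "covariates.csv", comment="#")
    report = run_report(results, covariates, run_config)

print(f"analyzed {results['eye_id'].nunique()} eyes, excluded {len(exclusions)}")

t1 = report["table1"].set_index("metric")
row = t1.loc["corrected_reflectivity"]
print(
    "\ncorrected reflectivity by group (mean +/- SD):"
    f"\n  recurrent {row['recurrent_mean']:.3f} +/- {row['recurrent_sd']:.3f}"
    f"\n  indolent  {row['indolent_mean']:.3f} +/- {row['indolent_sd']:.3f}"
    f"\n  control   {row['control_mean']:.3f} +/- {row['control_sd']:.3f}"
    f"\n  omnibus ANOVA P = {row['anova_p']:.2e}"
)

paired = report["summary"]["paired_quadrant_test"]
print(
    f"\npaired obstructive vs contralateral: mean difference "
    f"{paired['mean_difference']:+.3f}, P = {paired['p']:.3g}"
)

print("\nregression screen on disease eyes (univariate standardized beta):")
print(
    report["table2"][["predictor", "univariate_beta", "univariate_p"]]
    .to_string(index=False)
)
# Group means near 1.31 / 1.22 / 1.19, a positive obstructive-minus-
# contralateral difference, and a positive injections/year beta reflect the
# planted disease structure being recovered by the measurement chain.
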