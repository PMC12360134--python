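#!/usr/bin/env python
"""Cross-speed comparison of every kinematic variable.

For each variable, gate on Levene + Shapiro-Wilk, run the chosen
repeated-measures or aligned-rank ANOVA (speed effect, individuals as
blocks), and summarize per-speed means +/- SD with Tukey letter groups.
Reads results/analysis/trial_summaries.csv (run 01 first); writes the test
table, pairwise contrasts and the per-speed summary.
"""

from pathlib import Path

import pandas as pd

from undulokin import group_stats

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"

VARIABLES = ["tbf", "amplitude", "wave_speed", "wavelength", "k_max",
             "k_max_loc", "fin_effort", "body_angle", "angle_of_attack"]


def main() -> None:
    table = pd.read_csv(OUT / "trial_summaries.csv")
    report = group_stats.analyze_table(table, VARIABLES)
    report.tests.to_csv(OUT / "stats_tests.csv", index=False)
    report.letters.to_csv(OUT / "stats_letters.csv", index=False)
    pd.concat([c.assign(variable=v) for v, c in report.contrasts.items()],
              ignore_index=True).to_csv(OUT / "stats_contrasts.csv",
                                        index=False)
    speed_summary = group_stats.summary_table(table)
    speed_summary.to_csv(OUT / "speed_summary.csv", index=False)

    print("per-variable speed effects "
          f"(df = {report.tests.df_num.iloc[0]}, "
          f"{report.tests.df_den.iloc[0]}):")
    for r in report.tests.itertuples():
        verdict = "significant" if r.p < report.alpha else "ns"
        print(f"  {r.variable:>16}: {r.method:<9} F = {r.F:7.2f}  "
              f"p = {r.p:.3g}  [{verdict}]")
    sig = report.tests.query("p < @report.alpha")["variable"].tolist()
    print(f"speed modulates: {', '.join(sig)}")
    print(f"wrote {OUT / 'speed_summary.csv'}")


if __name__ == "__main__":
    main()
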