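#!/usr/bin/env python
"""PCA of the independent swimming variables.

Projects the 51 trials onto principal axes of the 8 independent kinematic
variables (angle of attack, body angle, tail amplitude, max curvature and
its location, Reynolds number, tail beat frequency, wave speed), orienting
PC1 to increase with swimming speed, and reports per-axis variance and
variable contributions. Reads results/analysis/trial_summaries.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from undulokin import group_stats

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    table = pd.read_csv(OUT / "trial_summaries.csv")
    pca = group_stats.pca_contributions(table)
    axes = [f"PC{i+1}" for i in range(len(pca.percent_variance))]
    pd.DataFrame(pca.loadings, index=pca.variables, columns=axes) \
        .to_csv(OUT / "pca_loadings.csv")
    pd.DataFrame(pca.contributions, index=pca.variables, columns=axes) \
        .to_csv(OUT / "pca_contributions.csv")
    pd.DataFrame({"axis": axes, "percent_variance": pca.percent_variance}) \
        .to_csv(OUT / "pca_variance.csv", index=False)
    pd.DataFrame(pca.scores, columns=axes).assign(trial=list(pca.row_index)) \
        .to_csv(OUT / "pca_scores.csv", index=False)

    pc12 = pca.percent_variance[:2].sum()
    print(f"first two axes carry {pc12:.1f}% of total variance")
    contrib = pd.Series(pca.contributions[:, 0], index=pca.variables)
    top = contrib[contrib > 10].sort_values(ascending=False)
    print("variables contributing >10% to PC1:")
    for name, v in top.items():
        print(f"  {name:>16}: {v:.1f}%")
    load = pd.Series(pca.loadings[:, 0], index=pca.variables)
    sign = "oppose" if load["body_angle"] * load["tbf"] < 0 else "align with"
    print(f"body angle loadings {sign} tail beat frequency on PC1 "
          f"(the speed axis): posture flattens as the tail beats faster")
    print(f"wrote {OUT / 'pca_contributions.csv'}")


if __name__ == "__main__":
    main()
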