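"""Cohort statistics: group comparisons, correlations, regressions.

Reads results/cohort.csv and results/ai.csv, runs the full statistical
battery — demographics tests, four-group comparisons of every asymmetry
index (automatic ANOVA/Kruskal-Wallis path with Dunn-Bonferroni post
hoc), Pearson correlations of the AIs with age and HbA1c, and the
covariate-adjusted HbA1c regressions — and writes the report tables
under results/.
"""

import sys
from pathlib import Path

import pandas as pd

from octa_asym import io as oio
from octa_asym.asym import AI_COLUMNS
from octa_asym.pipeline import analyze_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")


def main() -> None:
    cohort = oio.read_cohort_csv(OUT / "cohort.csv")
    ai = oio.read_ai_csv(OUT / "ai.csv")
    table = cohort.drop(columns=[c for c in AI_COLUMNS if c in cohort]) \
        .merge(ai, on="patient_id")
    report = analyze_cohort(table, seed=SEED)
    for name in ("table1", "table2", "correlations", "regressions"):
        report[name].to_csv(OUT / f"{name}.csv", index=False)
    (OUT / "analysis_log.txt").write_text("\n".join(report["log"]) + "\n")

    t2 = report["table2"].set_index("outcome")
    print("four-group comparison of AI outcomes "
          "(method, omnibus p, PDR-vs-NPDR adjusted p):")
    for col in AI_COLUMNS:
        row = t2.loc[col]
        print(f"  {col:8s} {row['method']:22s} "
              f"p={row['omnibus_p']:.2e}  "
              f"PDR-NPDR p={row['p NPDR vs PDR']:.3f}")
    corr = report["correlations"]
    hba1c = corr[(corr["x"] == "hba1c") & (corr["p"] < 0.05)]
    print("significant HbA1c correlations:")
    print(hba1c.round(3).to_string(index=False))
    print("adjusted HbA1c regressions (beta [95% CI], p):")
    print(report["regressions"].round(3).to_string(index=False))
    print(f"wrote report tables under {OUT}/")


if __name__ == "__main__":
    main()
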