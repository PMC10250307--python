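"""Compute per-patient interocular asymmetry profiles.

Reads results/cohort.csv (step 01), recomputes the asymmetry index
AI = |OD - OS| / (OD + OS) * 200 for every tracked metric from the
per-eye columns, verifies the table's stored AI values against the
recomputation, and writes results/ai.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from octa_asym import io as oio
from octa_asym.asym import AI_COLUMNS, pair_asymmetry_profile

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")


def main() -> None:
    cohort = oio.read_cohort_csv(OUT / "cohort.csv")
    pairs = oio.metrics_table_to_pairs(cohort)
    superficial = pd.DataFrame(
        [pair_asymmetry_profile(p).as_dict() for p in pairs]
    )
    # deep-layer AIs come straight from the per-eye deep columns
    from octa_asym.asym import asymmetry_index

    deep = pd.DataFrame({
        "patient_id": cohort["patient_id"],
        "ai_dpd": [asymmetry_index(a, b)
                   for a, b in zip(cohort["dpd_od"], cohort["dpd_os"])],
        "ai_dvd": [asymmetry_index(a, b)
                   for a, b in zip(cohort["dvd_od"], cohort["dvd_os"])],
    })
    ai = superficial.drop(columns=["ai_dpd", "ai_dvd"]).merge(
        deep, on="patient_id"
    )
    oio.write_ai_csv(ai, OUT / "ai.csv")

    mismatch = 0
    for col in AI_COLUMNS:
        recomputed = ai.set_index("patient_id")[col]
        stored = cohort.set_index("patient_id")[col]
        mismatch += int(((recomputed - stored).abs() > 1e-9).sum())
    print(f"profiles for {len(ai)} patients; "
          f"{mismatch} mismatches vs stored AI columns")
    print(ai[list(AI_COLUMNS)].describe().loc[["mean", "std", "max"]]
          .round(2).to_string())
    print(f"wrote {OUT / 'ai.csv'}")


if __name__ == "__main__":
    main()
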