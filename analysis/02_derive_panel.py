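#!/usr/bin/env python
"""Step 2 — derive per-subject vitamin D and bone indices.

Reads results/cohort.csv, computes calculated free/bioavailable 25OHD under
both affinity schemes, VMR, deficiency, categories and DXA Z-scores, and
writes results/cohort_derived.csv.
"""

import warnings
from pathlib import Path

from vitdfree.indices import derive_table
from vitdfree.io import read_cohort

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(OUT / "cohort.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        derived = derive_table(cohort)
    derived.to_csv(OUT / "cohort_derived.csv", index=False, lineterminator="\n")

    print(f"derived panel -> {OUT / 'cohort_derived.csv'}")
    for col, unit in [("con_free_pg_ml", "pg/mL"), ("spe_free_pg_ml", "pg/mL"),
                      ("con_bioa_ng_ml", "ng/mL"), ("spe_bioa_ng_ml", "ng/mL"),
                      ("vmr_x100", "")]:
        s = derived[col]
        print(f"  {col}: {s.mean():.2f} +/- {s.std():.2f} {unit}")
    print(f"  vitamin D deficiency: {derived.deficient.mean():.1%}")
    print(f"  BMI categories: {derived.bmi_category.value_counts().to_dict()}")


if __name__ == "__main__":
    main()
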