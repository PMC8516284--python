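#!/usr/bin/env python
"""Step 4 — bone-outcome regressions and injected-effect recovery.

At the study's n=146 the BMI-stratified regressions are noisy, so this step
additionally simulates a large cohort (n = 5000) to show that the adjusted
regression recovers the injected normal-weight slope (0.030 BMC_TB Z per
ng/mL total 25OHD) and that the interaction scan detects the opposite-sign
slope in overweight/obese children.  Writes results/bone_recovery.csv.
"""

import warnings
from pathlib import Path

import pandas as pd

from vitdfree.cohort import default_params, simulate_cohort
from vitdfree.indices import derive_table
from vitdfree.stats import adjusted_regression, interaction_scan

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 7, n: int = 5000) -> None:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df = derive_table(simulate_cohort(default_params(n=n), seed=seed))

    rows = []
    for stratum, mask in (("normal", df.bmi_category == "normal"),
                          ("overweight_obese", df.bmi_category != "normal")):
        res = adjusted_regression(df[mask], "bmc_tb_z", "total_25ohd_ng_ml")
        rows.append({"stratum": stratum, "beta": res.beta, "se": res.se,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "p": res.p, "r2": res.r2, "n": res.n})
        print(f"{stratum}: beta = {res.beta:.4f} (SE {res.se:.4f}), "
              f"95% CI [{res.ci_low:.4f}, {res.ci_high:.4f}], "
              f"R2 = {res.r2:.3f}, n = {res.n}")
    inter = interaction_scan(df, "bmc_tb_z", "total_25ohd_ng_ml")
    print(f"BMI x total 25OHD interaction: beta = "
          f"{inter['beta_interaction']:.4f}, p = {inter['p_interaction']:.2g}")

    OUT.mkdir(exist_ok=True)
    out = pd.DataFrame(rows)
    out["interaction_p"] = inter["p_interaction"]
    out.to_csv(OUT / "bone_recovery.csv", index=False, lineterminator="\n")
    print(f"-> {OUT / 'bone_recovery.csv'}")


if __name__ == "__main__":
    main()
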