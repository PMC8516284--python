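"""Age- and sex-matched DXA reference values for pediatric Z-scores.

A Z-score standardizes a measured body-composition or bone value against
the mean and SD of healthy same-age, same-sex children:

    Z = (measured - reference_mean) / reference_SD

National normative tables are licensed publications and are not bundled;
the packaged table (``data/reference_synthetic.csv``) is a SYNTHETIC
reference with smooth, physiologically plausible age trends covering ages
5–13.5 y for both sexes.  It exists so the pipeline and its tests are fully
runnable; swap in a real normative CSV of the same schema for substantive
use.

Schema: one row per (sex, age) grid point, columns ``sex`` (M/F),
``age_years``, then ``<measure>_mean`` / ``<measure>_sd`` for each of
``fm`` (kg), ``lm`` (kg), ``bmc_tb`` (g), ``bmd_tb``, ``bmd_ls``,
``bmd_tblh`` (g/cm^2).  Lookup interpolates linearly in age within each sex.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MEASURES", "ReferenceTable", "build_synthetic_reference"]

MEASURES = ("fm", "lm", "bmc_tb", "bmd_tb", "bmd_ls", "bmd_tblh")

AGE_GRID = np.arange(5.0, 13.51, 0.5)

# anchor (value at age 5, value at age 13.5) per measure; girls get a small
# offset on lean/bone measures reflecting later pediatric dimorphism
_TRENDS = {
    "fm": (6.0, 13.0),
    "lm": (13.0, 33.0),
    "bmc_tb": (700.0, 1900.0),
    "bmd_tb": (0.78, 1.02),
    "bmd_ls": (0.55, 0.88),
    "bmd_tblh": (0.62, 0.95),
}
_GIRL_SCALE = {"fm": 1.08, "lm": 0.90, "bmc_tb": 0.95,
               "bmd_tb": 0.98, "bmd_ls": 1.00, "bmd_tblh": 0.97}
_CV = {"fm": 0.30, "lm": 0.14, "bmc_tb": 0.15,
       "bmd_tb": 0.07, "bmd_ls": 0.09, "bmd_tblh": 0.08}


def build_synthetic_reference() -> pd.DataFrame:
    """Construct the synthetic reference table (the packaged CSV's source)."""
    rows = []
    for sex in ("M", "F"):
        for age in AGE_GRID:
            t = (age - AGE_GRID[0]) / (AGE_GRID[-1] - AGE_GRID[0])
            row: dict[str, object] = {"sex": sex, "age_years": round(float(age), 2)}
            for m, (lo, hi) in _TRENDS.items():
                # mildly convex growth: faster accrual toward puberty
                mean = lo + (hi - lo) * (0.6 * t + 0.4 * t**2)
                if sex == "F":
                    mean *= _GIRL_SCALE[m]
                row[f"{m}_mean"] = round(mean, 4)
                row[f"{m}_sd"] = round(max(mean * _CV[m], 1e-6), 4)
            rows.append(row)
    return pd.DataFrame(rows)


class ReferenceTable:
    """(age, sex) → mean/SD lookup for the DXA measures, linear in age."""

    def __init__(self, table: pd.DataFrame):
        required = {"sex", "age_years"} | {
            f"{m}_{s}" for m in MEASURES for s in ("mean", "sd")
        }
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"reference table missing columns: {sorted(missing)}")
        sd_cols = [f"{m}_sd" for m in MEASURES]
        if (table[sd_cols] <= 0).any().any():
            raise ValueError("reference SDs must all be positive")
        self._by_sex = {
            sex: grp.sort_values("age_years").reset_index(drop=True)
            for sex, grp in table.groupby("sex")
        }

    @classmethod
    def load(cls, path: str | Path | None = None) -> "ReferenceTable":
        """Load from CSV; ``None`` loads the packaged synthetic table
        (cached — the instance is read-only)."""
        if path is None:
            return _load_packaged()
        return cls(pd.read_csv(path))

    @property
    def age_range(self) -> tuple[float, float]:
        lo = min(g["age_years"].iloc[0] for g in self._by_sex.values())
        hi = max(g["age_years"].iloc[-1] for g in self._by_sex.values())
        return float(lo), float(hi)

    def lookup(self, sex: str, age: float, measure: str) -> tuple[float, float]:
        """Interpolated (mean, sd) for one measure; age clipped to the grid."""
        if measure not in MEASURES:
            raise ValueError(f"unknown measure {measure!r}; expected {MEASURES}")
        if sex not in self._by_sex:
            raise ValueError(f"sex {sex!r} not covered by the reference table")
        g = self._by_sex[sex]
        ages = g["age_years"].to_numpy()
        a = float(np.clip(age, ages[0], ages[-1]))
        mean = float(np.interp(a, ages, g[f"{measure}_mean"].to_numpy()))
        sd = float(np.interp(a, ages, g[f"{measure}_sd"].to_numpy()))
        return mean, sd

    def z(self, sex: str, age: float, measure: str, value: float) -> float:
        mean, sd = self.lookup(sex, age, measure)
        return (value - mean) / sd

    def from_z(self, sex: str, age: float, measure: str, z: float) -> float:
        """Inverse of :meth:`z`: raw value at a given Z (used by the
        synthetic cohort generator)."""
        mean, sd = self.lookup(sex, age, measure)
        return mean + z * sd


@lru_cache(maxsize=1)
def _load_packaged() -> "ReferenceTable":
    src = resources.files("vitdfree.data") / "reference_synthetic.csv"
    with resources.as_file(src) as p:
        return ReferenceTable(pd.read_csv(p))
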