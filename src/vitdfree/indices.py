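"""Per-subject derived quantities and categorical classifications.

Everything computed from a subject's measured row: the vitamin D metabolite
ratio (VMR), the deficiency flag, BMI category, dietary-reference-intake
(DRI) adequacy, the regular-activity flag, total-body-less-head BMD, DXA
Z-scores, and the calculated free/bioavailable 25OHD under both the
constant and the genotype-specific affinity schemes.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .binding import (
    BindingScheme,
    ConcentrationPanel,
    free_25ohd,
    free_25ohd_exact,
    specific_scheme,
)
from .config import BindingConfig, Thresholds
from .reference import ReferenceTable

__all__ = [
    "vmr", "classify_deficiency", "z_score", "bmi_percentile_from_z",
    "classify_bmi", "intake_meets_dri", "regular_activity", "bmd_tblh",
    "derive_panel", "derive_table", "DERIVED_COLUMNS",
]

TBLH_REGIONS = ("trunk", "upper_limbs", "lower_limbs")

#: Stable column order of the derived panel.
DERIVED_COLUMNS = [
    "spe_bioa_ng_ml", "con_bioa_ng_ml", "spe_free_pg_ml", "con_free_pg_ml",
    "vmr_x100", "deficient", "bmi_category", "dri_vitd_met", "dri_ca_met",
    "regular_activity", "bmc_tb_z", "bmd_tb_z", "bmd_ls_z",
    "bmd_tblh_g_cm2", "bmd_tblh_z",
]


def vmr(d24_25ohd3: float, total: float) -> float:
    """Vitamin D metabolite ratio, 100 x 24,25(OH)2D3 / total 25OHD.

    The ratio indexes CYP24A1 catabolic activity; it is conventionally
    reported multiplied by 100.  Undefined (NaN, with a warning) when total
    is zero or missing.
    """
    if pd.isna(d24_25ohd3) or pd.isna(total):
        return float("nan")
    if total <= 0:
        warnings.warn("VMR undefined for non-positive total 25OHD; emitting NaN",
                      stacklevel=2)
        return float("nan")
    if d24_25ohd3 < 0:
        raise ValueError("24,25(OH)2D3 must be non-negative")
    return 100.0 * d24_25ohd3 / total


def classify_deficiency(total: float, cutoff_ng_ml: float = 20.0):
    """Vitamin D deficiency: total 25OHD strictly below the cut-off (ng/mL)."""
    if pd.isna(total):
        return None
    if total < 0:
        raise ValueError("total 25OHD must be non-negative")
    return bool(total < cutoff_ng_ml)


def z_score(x: float, ref_mean: float, ref_sd: float) -> float:
    """Standard Z-score (measured - reference mean) / reference SD."""
    if ref_sd <= 0:
        raise ValueError("reference SD must be positive")
    if pd.isna(x):
        return float("nan")
    return (x - ref_mean) / ref_sd


def bmi_percentile_from_z(bmi_z: float) -> float:
    """BMI percentile from a BMI Z-score via the normal CDF (0–100)."""
    if pd.isna(bmi_z):
        return float("nan")
    return 100.0 * float(norm.cdf(bmi_z))


def classify_bmi(bmi_percentile: float, overweight: float = 85.0,
                 obese: float = 95.0) -> str | None:
    """Normal (< 85th), overweight (85th–95th) or obese (>= 95th percentile)."""
    if pd.isna(bmi_percentile):
        return None
    if not 0.0 <= bmi_percentile <= 100.0:
        raise ValueError(f"percentile out of [0, 100]: {bmi_percentile}")
    if bmi_percentile >= obese:
        return "obese"
    if bmi_percentile >= overweight:
        return "overweight"
    return "normal"


# DRI bands: (age_low, age_high_inclusive) on floored age -> threshold
_VITD_DRI = [((0, 11), 200.0), ((12, 18), 400.0)]
_CA_DRI = {  # keyed by sex; bands on floored age
    "M": [((6, 8), 700.0), ((9, 11), 800.0), ((12, 14), 1000.0)],
    "F": [((6, 8), 700.0), ((9, 11), 800.0), ((12, 14), 900.0)],
}


def intake_meets_dri(nutrient: str, intake: float, age: float, sex: str):
    """Whether a daily intake meets the age/sex dietary reference intake.

    Vitamin D (IU/day): 200 for ages <= 11 y, 400 for 12–18 y.  Calcium
    (mg/day): 700 at 6–8 y, 800 at 9–11 y, 1000/900 (boys/girls) at 12–14 y.
    Age is floored to whole years before banding.  Ages just outside the
    calcium bands (5 y, > 14 y) map to the nearest band with a warning; ages
    outside the vitamin D bands raise.
    """
    if pd.isna(intake):
        return None
    if intake < 0:
        raise ValueError("intake must be non-negative")
    yrs = math.floor(age)
    nutrient = nutrient.lower()
    if nutrient in ("vitd", "vitamin_d", "vitamind"):
        if yrs < 0 or yrs > 18:
            raise ValueError(f"age {age} outside the covered vitamin D DRI bands")
        for (lo, hi), dri in _VITD_DRI:
            if lo <= yrs <= hi:
                return bool(intake >= dri)
        raise AssertionError("unreachable")
    if nutrient in ("ca", "calcium"):
        sex = _norm_sex(sex)
        bands = _CA_DRI[sex]
        if yrs < 6:
            warnings.warn(f"age {age} below calcium DRI bands; using the 6-8 y band",
                          stacklevel=2)
            yrs = 6
        elif yrs > 14:
            warnings.warn(f"age {age} above calcium DRI bands; using the 12-14 y band",
                          stacklevel=2)
            yrs = 14
        for (lo, hi), dri in bands:
            if lo <= yrs <= hi:
                return bool(intake >= dri)
        raise AssertionError("unreachable")
    raise ValueError(f"unknown nutrient {nutrient!r}; expected 'vitD' or 'Ca'")


def regular_activity(days_per_week: float, min_per_day: float):
    """Moderate/vigorous activity >= 60 min/day on >= 3 days/week."""
    if pd.isna(days_per_week) or pd.isna(min_per_day):
        return None
    return bool(days_per_week >= 3 and min_per_day >= 60)


def bmd_tblh(bmc_by_region: dict, area_by_region: dict) -> float:
    """Total-body-less-head BMD: summed BMC of trunk + limbs over summed area.

    Excludes the skull by construction; regions are trunk, upper_limbs and
    lower_limbs (BMC in g, areas in cm^2).
    """
    missing = [r for r in TBLH_REGIONS
               if r not in bmc_by_region or r not in area_by_region]
    if missing:
        raise ValueError(f"missing regions: {missing}")
    areas = [float(area_by_region[r]) for r in TBLH_REGIONS]
    bmcs = [float(bmc_by_region[r]) for r in TBLH_REGIONS]
    if any(a <= 0 for a in areas):
        raise ValueError("all region areas must be strictly positive")
    if any(b < 0 for b in bmcs):
        raise ValueError("region BMC must be non-negative")
    return sum(bmcs) / sum(areas)


def _norm_sex(sex) -> str:
    s = str(sex).strip().upper()
    if s in ("M", "MALE", "BOY", "B"):
        return "M"
    if s in ("F", "FEMALE", "GIRL", "G"):
        return "F"
    raise ValueError(f"cannot interpret sex {sex!r}")


def _free_bioa(record: pd.Series, scheme: BindingScheme, exact: bool):
    """(free pg/mL, bioavailable ng/mL) or (nan, nan) on missing analytes."""
    vals = [record.get("total_25ohd_ng_ml"), record.get("vdbp_ug_ml"),
            record.get("albumin_g_dl")]
    if any(pd.isna(v) for v in vals):
        return float("nan"), float("nan")
    panel = ConcentrationPanel(*[float(v) for v in vals])
    res = free_25ohd_exact(panel, scheme) if exact else free_25ohd(panel, scheme)
    return res.free_25ohd, res.bioavailable_25ohd


def derive_panel(
    record: pd.Series | dict,
    binding: BindingConfig,
    reference: ReferenceTable,
    thresholds: Thresholds | None = None,
) -> pd.Series:
    """Compute the full derived panel for one subject row.

    ``spe_*`` uses the mean allele affinity of the subject's Gc diplotype,
    ``con_*`` the genotype-constant scheme; missing inputs propagate to NaN
    in the affected outputs only.
    """
    if isinstance(record, dict):
        record = pd.Series(record)
    thresholds = thresholds or Thresholds()
    exact = binding.mode == "exact"
    out: dict[str, object] = {}

    con = binding.constant_scheme()
    con_free, con_bioa = _free_bioa(record, con, exact)
    dip = record.get("diplotype")
    if pd.isna(dip) if not isinstance(dip, str) else False:
        spe_free = spe_bioa = float("nan")
    else:
        spe = specific_scheme(str(dip), binding.allele_k_dbp, con)
        spe_free, spe_bioa = _free_bioa(record, spe, exact)
    out["spe_bioa_ng_ml"] = spe_bioa
    out["con_bioa_ng_ml"] = con_bioa
    out["spe_free_pg_ml"] = spe_free
    out["con_free_pg_ml"] = con_free

    out["vmr_x100"] = vmr(record.get("d24_25ohd3_ng_ml", float("nan")),
                          record.get("total_25ohd_ng_ml", float("nan")))
    out["deficient"] = classify_deficiency(
        record.get("total_25ohd_ng_ml", float("nan")),
        thresholds.deficiency_ng_ml)
    out["bmi_category"] = classify_bmi(
        bmi_percentile_from_z(record.get("bmi_z", float("nan"))),
        thresholds.bmi_overweight_pct, thresholds.bmi_obese_pct)
    age, sex = record.get("age_years"), record.get("sex")
    out["dri_vitd_met"] = intake_meets_dri(
        "vitD", record.get("vitd_intake_iu_day", float("nan")), age, sex)
    out["dri_ca_met"] = intake_meets_dri(
        "Ca", record.get("ca_intake_mg_day", float("nan")), age, sex)
    out["regular_activity"] = regular_activity(
        record.get("activity_days_week", float("nan")),
        record.get("activity_min_day", float("nan")))

    sexn = _norm_sex(sex)
    for meas, col in (("bmc_tb", "bmc_tb_g"), ("bmd_tb", "bmd_tb_g_cm2"),
                      ("bmd_ls", "bmd_ls_g_cm2")):
        val = record.get(col, float("nan"))
        out[f"{meas}_z"] = (reference.z(sexn, float(age), meas, float(val))
                            if pd.notna(val) else float("nan"))
    try:
        tblh = bmd_tblh(
            {r: record[f"bmc_{r}_g"] for r in TBLH_REGIONS},
            {r: record[f"area_{r}_cm2"] for r in TBLH_REGIONS})
    except (KeyError, ValueError, TypeError):
        tblh = float("nan")
    if pd.notna(tblh) and not any(
            pd.isna(record.get(f"bmc_{r}_g")) or pd.isna(record.get(f"area_{r}_cm2"))
            for r in TBLH_REGIONS):
        out["bmd_tblh_g_cm2"] = tblh
        out["bmd_tblh_z"] = reference.z(sexn, float(age), "bmd_tblh", tblh)
    else:
        out["bmd_tblh_g_cm2"] = float("nan")
        out["bmd_tblh_z"] = float("nan")

    return pd.Series(out)[DERIVED_COLUMNS]


def derive_table(
    cohort: pd.DataFrame,
    binding: BindingConfig | None = None,
    reference: ReferenceTable | None = None,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Derived panel for every row, joined onto the input columns."""
    binding = binding or BindingConfig()
    reference = reference or ReferenceTable.load()
    if cohort.empty:
        empty = pd.DataFrame(columns=list(cohort.columns) + DERIVED_COLUMNS)
        return empty
    derived = cohort.apply(
        lambda row: derive_panel(row, binding, reference, thresholds), axis=1)
    return pd.concat([cohort.reset_index(drop=True),
                      derived.reset_index(drop=True)], axis=1)
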