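"""Seeded synthetic-cohort generator.

Produces per-subject tables with the statistical structure the analysis
pipeline assumes — a pediatric cross-sectional cohort (ages 5–13.5 y) with
seasonally and developmentally patterned vitamin D status, six Gc (VDBP)
diplotypes at realistic frequencies, an iPTH level negatively coupled to
vitamin D status, and DXA bone Z-scores whose dependence on total 25OHD
differs by BMI category (positive in normal-weight children, negative in
overweight/obese ones).

Total 25OHD is generated log-normally with additive log-scale effects for
winter season, puberty and overweight/obese status.  Because the three
indicators are sampled independently, each stratum's arithmetic mean can be
fixed analytically: the intercept is chosen so the summer stratum mean hits
its target exactly, and each effect is the log ratio of its two stratum
targets.  Every other analyte hangs off this backbone (see
:func:`default_params` for the calibration values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

from .binding import ConcentrationPanel, GcDiplotype, all_diplotypes, free_25ohd
from .config import BindingConfig
from .reference import ReferenceTable

__all__ = ["CohortParams", "default_params", "sample_diplotypes",
           "simulate_cohort", "COHORT_COLUMNS"]

COHORT_COLUMNS = [
    "id", "sex", "age_years", "season", "pubertal",
    "height_z", "weight_z", "bmi_z", "diplotype",
    "total_25ohd_ng_ml", "d24_25ohd3_ng_ml", "vdbp_ug_ml", "albumin_g_dl",
    "measured_free_pg_ml", "ipth_pg_ml", "ca_mg_dl", "p_mg_dl", "alp_iu_l",
    "vitd_intake_iu_day", "ca_intake_mg_day", "daylight_hours_week",
    "activity_days_week", "activity_min_day", "fm_z", "lm_z",
    "bmc_tb_g", "bmd_tb_g_cm2", "bmd_ls_g_cm2",
    "bmc_trunk_g", "bmc_upper_limbs_g", "bmc_lower_limbs_g",
    "area_trunk_cm2", "area_upper_limbs_cm2", "area_lower_limbs_cm2",
]

_DIPLOTYPE_ORDER = [str(d) for d in all_diplotypes()]


@dataclass
class CohortParams:
    """Generative parameters of the synthetic cohort.

    Defaults are the study conditions the pipeline is validated against;
    every field can be overridden (see :func:`default_params`).
    """

    n: int = 146
    p_male: float = 75 / 146
    p_summer: float = 79 / 146
    p_pubertal: float = 42 / 146
    age_mean: float = 9.5
    age_sd: float = 1.9
    age_range: tuple[float, float] = (5.0, 13.5)
    # diplotype frequencies (observed counts / 146: 46, 29, 29, 15, 13, 14)
    diplotype_freqs: dict[str, float] = field(default_factory=lambda: {
        "Gc1f/Gc1f": 46 / 146, "Gc1f/Gc1s": 29 / 146, "Gc1f/Gc2": 29 / 146,
        "Gc1s/Gc1s": 15 / 146, "Gc1s/Gc2": 13 / 146, "Gc2/Gc2": 14 / 146,
    })
    # binder concentrations
    vdbp_mean: float = 226.5      # ug/mL, cohort-wide target
    vdbp_sd: float = 37.8
    vdbp_gc22_shift: float = -30.0  # Gc2/Gc2 runs lower
    albumin_mean: float = 4.3     # g/dL
    albumin_sd: float = 0.25
    # total 25OHD: log-normal backbone, stratum arithmetic-mean targets (ng/mL)
    total_mean_summer: float = 22.7
    total_mean_winter: float = 16.3
    total_mean_prepubertal: float = 20.9
    total_mean_pubertal: float = 17.1
    total_mean_normal_weight: float = 21.1
    total_mean_overweight_obese: float = 15.9
    total_log_sd: float = 0.28    # residual SD on the log scale
    # metabolite ratio and downstream analytes
    vmr_mean: float = 5.6         # x100 scale
    vmr_sd: float = 2.0
    ipth_mean: float = 22.8
    ipth_sd: float = 10.6
    ipth_total_corr: float = -0.35
    total_sd_marginal: float = 6.5  # used to size the iPTH coupling
    measured_free_scale: float = 0.55
    measured_free_total_corr: float = 0.655
    # chemistry
    ca_mean: float = 9.7; ca_sd: float = 0.4
    p_mean: float = 5.2; p_sd: float = 0.6
    alp_mean: float = 250.6; alp_sd: float = 59.4
    # anthropometry / lifestyle
    bmi_z_mean: float = 0.2
    bmi_z_sd: float = 1.3
    fm_z_mean: float = 1.6; fm_z_sd: float = 2.7
    lm_z_mean_male: float = -0.1; lm_z_sd_male: float = 1.5
    lm_z_mean_female: float = -1.1; lm_z_sd_female: float = 1.7
    vitd_intake_mean: float = 670.2; vitd_intake_sd: float = 431.1
    ca_intake_mean: float = 630.7; ca_intake_sd: float = 278.3
    daylight_mean: float = 3.3; daylight_sd: float = 2.6
    p_regular_activity: float = 0.509
    # bone structural model (on the Z scale)
    bone_slope_normal: float = 0.030      # BMC_TB_Z per ng/mL total 25OHD
    bone_slope_overweight: float = -0.030
    bone_slopes: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        # measure -> (normal-weight slope, overweight/obese slope)
        "bmc_tb": (0.030, -0.030),
        "bmd_tb": (0.030, -0.030),
        "bmd_ls": (0.014, -0.014),
        "bmd_tblh": (0.012, -0.012),
    })
    bone_fm_loading: float = 0.15
    bone_lm_loading: float = 0.35
    bone_age_loading: float = 0.02
    bone_sex_loading: float = 0.05
    bone_resid_sd: float = 0.61   # sized for adjusted R^2 ~ 0.6 (BMC_TB_Z)
    bone_z_mean: float = -0.2
    # missingness (study counts out of 146, applied as rates)
    miss_vitd_intake: float = 32 / 146
    miss_ca_intake: float = 40 / 146
    miss_activity_daylight: float = 30 / 146
    miss_chemistry: float = 3 / 146
    seed: int = 0

    def validate(self) -> None:
        freqs = np.array([self.diplotype_freqs[d] for d in _DIPLOTYPE_ORDER])
        if abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
            raise ValueError("diplotype frequencies must be a simplex summing to 1")
        for name in ("age_sd", "vdbp_sd", "albumin_sd", "total_log_sd", "vmr_sd",
                     "ipth_sd", "bmi_z_sd", "fm_z_sd", "bone_resid_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for p in ("p_male", "p_summer", "p_pubertal", "p_regular_activity"):
            if not 0 <= getattr(self, p) <= 1:
                raise ValueError(f"{p} must be in [0, 1]")


def default_params(**overrides) -> CohortParams:
    """The default calibration; any field may be overridden by keyword."""
    params = CohortParams()
    if overrides:
        params = replace(params, **overrides)
    params.validate()
    return params


def sample_diplotypes(n: int, freqs: dict[str, float] | None,
                      rng: np.random.Generator) -> list[GcDiplotype]:
    """Draw ``n`` Gc diplotypes i.i.d. from the given frequency table."""
    if freqs is None:
        freqs = default_params().diplotype_freqs
    labels = list(freqs)
    p = np.asarray([freqs[k] for k in labels], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("frequencies must form a simplex")
    idx = rng.choice(len(labels), size=n, p=p / p.sum())
    return [GcDiplotype.parse(labels[i]) for i in idx]


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (bounds are generous, so cheap)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort(params: CohortParams | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Simulate one cohort table (one row per subject).

    ``seed`` overrides ``params.seed``; one fresh generator per call, no
    global RNG state.  Identical params + seed give identical tables.
    """
    params = params or default_params()
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)

    sex = np.where(rng.random(n) < params.p_male, "M", "F")
    age = _truncnorm(rng, params.age_mean, params.age_sd, *params.age_range, n)
    season = np.where(rng.random(n) < params.p_summer, "summer", "winter")
    # puberty probability rises with age around the marginal rate
    p_pub = np.clip(params.p_pubertal + 0.12 * (age - params.age_mean), 0, 1)
    pubertal = rng.random(n) < p_pub

    bmi_z = rng.normal(params.bmi_z_mean, params.bmi_z_sd, n)
    # overweight/obese = BMI percentile >= 85 <=> bmi_z >= Phi^-1(0.85)
    owob = bmi_z >= _norm.ppf(0.85)
    weight_z = 0.7 * bmi_z + rng.normal(0, 0.9, n)
    height_z = rng.normal(-0.3, 1.0, n)

    diplos = sample_diplotypes(n, params.diplotype_freqs, rng)
    diplo_str = np.array([str(d) for d in diplos])

    # VDBP: Gc2/Gc2 shifted down; base mean raised so the cohort mean stays
    # on target given the Gc2/Gc2 frequency
    f22 = params.diplotype_freqs.get("Gc2/Gc2", 0.0)
    vdbp_base = params.vdbp_mean - f22 * params.vdbp_gc22_shift
    vdbp = rng.normal(vdbp_base, params.vdbp_sd, n)
    vdbp = vdbp + np.where(diplo_str == "Gc2/Gc2", params.vdbp_gc22_shift, 0.0)
    vdbp = np.clip(vdbp, 50.0, None)
    albumin = np.clip(rng.normal(params.albumin_mean, params.albumin_sd, n), 2.5, 6.0)

    # total 25OHD backbone: lognormal, intercept fixed by the summer target
    b_w = math.log(params.total_mean_winter / params.total_mean_summer)
    b_p = math.log(params.total_mean_pubertal / params.total_mean_prepubertal)
    b_o = math.log(params.total_mean_overweight_obese
                   / params.total_mean_normal_weight)
    e_p = (1 - params.p_pubertal) + params.p_pubertal * math.exp(b_p)
    # P(overweight/obese) implied by the BMI-Z distribution
    p_owob = 1.0 - _norm.cdf((_norm.ppf(0.85) - params.bmi_z_mean)
                             / params.bmi_z_sd)
    e_o = (1 - p_owob) + p_owob * math.exp(b_o)
    sigma = params.total_log_sd
    mu0 = (math.log(params.total_mean_summer) - sigma**2 / 2
           - math.log(e_p) - math.log(e_o))
    log_total = (mu0 + b_w * (season == "winter") + b_p * pubertal
                 + b_o * owob + rng.normal(0, sigma, n))
    total = np.exp(log_total)

    # 24,25(OH)2D3 via an independently drawn metabolite ratio
    vmr = _truncnorm(rng, params.vmr_mean, params.vmr_sd, 0.0, np.inf, n)
    d24 = total * vmr / 100.0

    # iPTH negatively coupled to vitamin D status
    r = params.ipth_total_corr
    slope = r * params.ipth_sd / params.total_sd_marginal
    resid_sd = params.ipth_sd * math.sqrt(max(1 - r**2, 0.0))
    ipth = np.clip(params.ipth_mean + slope * (total - 19.8)
                   + rng.normal(0, resid_sd, n), 1.0, None)

    # directly measured free 25OHD: attenuated, noisy transform of con-free
    binding = BindingConfig()
    con = binding.constant_scheme()
    con_free = np.array([
        free_25ohd(ConcentrationPanel(t, v, a), con).free_25ohd
        for t, v, a in zip(total, vdbp, albumin)
    ])
    a_sc = params.measured_free_scale
    sd_con = max(float(np.std(con_free)), 1e-9)
    rho = float(np.corrcoef(con_free, total)[0, 1]) if n > 2 else 0.9
    if not math.isfinite(rho):
        rho = 0.9
    rho = min(max(rho, params.measured_free_total_corr), 1.0)
    target = params.measured_free_total_corr
    # choose noise so corr(measured, total) = target (see methods note)
    sd_m = a_sc * rho * sd_con / target
    noise_var = max(sd_m**2 - (a_sc * sd_con) ** 2, 0.0)
    measured_free = np.clip(
        a_sc * con_free + rng.normal(0, math.sqrt(noise_var), n), 0.05, None)

    ca = rng.normal(params.ca_mean, params.ca_sd, n)
    phos = rng.normal(params.p_mean, params.p_sd, n)
    alp = np.clip(rng.normal(params.alp_mean, params.alp_sd, n), 20.0, None)

    vitd_intake = np.clip(rng.normal(params.vitd_intake_mean,
                                     params.vitd_intake_sd, n), 0.0, None)
    ca_intake = np.clip(rng.normal(params.ca_intake_mean,
                                   params.ca_intake_sd, n), 0.0, None)
    daylight = _truncnorm(rng, params.daylight_mean, params.daylight_sd,
                          0.0, np.inf, n)
    regular = rng.random(n) < params.p_regular_activity
    activity_days = np.where(regular, rng.integers(3, 8, n), rng.integers(0, 3, n))
    activity_min = np.where(regular, rng.uniform(60, 150, n),
                            rng.uniform(10, 59, n)).round(0)

    fm_z = params.fm_z_mean + 1.4 * (bmi_z - params.bmi_z_mean) \
        + rng.normal(0, 2.0, n)
    lm_z = np.where(
        sex == "M",
        rng.normal(params.lm_z_mean_male, params.lm_z_sd_male, n),
        rng.normal(params.lm_z_mean_female, params.lm_z_sd_female, n))

    # bone Z structural model, then raw DXA values via the reference table
    sex_ind = (sex == "M").astype(float)
    ref = ReferenceTable.load()
    bone_z: dict[str, np.ndarray] = {}
    for meas, (s_norm, s_ow) in params.bone_slopes.items():
        slope_vec = np.where(owob, s_ow, s_norm)
        mean_total = np.where(owob, params.total_mean_overweight_obese,
                              params.total_mean_normal_weight)
        bone_z[meas] = (params.bone_z_mean
                        + slope_vec * (total - mean_total)
                        + params.bone_fm_loading * (fm_z - params.fm_z_mean)
                        + params.bone_lm_loading * (lm_z + 0.6)
                        + params.bone_age_loading * (age - params.age_mean)
                        + params.bone_sex_loading * (sex_ind - 0.5)
                        + rng.normal(0, params.bone_resid_sd, n))

    def raw(meas, z):
        return np.array([ref.from_z(s, a, meas, zz)
                         for s, a, zz in zip(sex, age, z)])

    bmc_tb = raw("bmc_tb", bone_z["bmc_tb"])
    bmd_tb = raw("bmd_tb", bone_z["bmd_tb"])
    bmd_ls = raw("bmd_ls", bone_z["bmd_ls"])
    bmd_tblh_val = raw("bmd_tblh", bone_z["bmd_tblh"])
    # region split consistent with the TBLH value: BMC_r = BMD_TBLH * area_r
    area_total = 400.0 + 180.0 * (age - 5.0) / 8.5  # cm^2, smooth growth
    shares = {"trunk": 0.45, "upper_limbs": 0.15, "lower_limbs": 0.40}
    areas = {r: area_total * s for r, s in shares.items()}
    bmcs = {r: bmd_tblh_val * areas[r] for r in shares}

    df = pd.DataFrame({
        "id": [f"S{i:05d}" for i in range(1, n + 1)],
        "sex": sex, "age_years": age.round(2), "season": season,
        "pubertal": pubertal, "height_z": height_z.round(3),
        "weight_z": weight_z.round(3), "bmi_z": bmi_z.round(3),
        "diplotype": diplo_str,
        "total_25ohd_ng_ml": total.round(3),
        "d24_25ohd3_ng_ml": d24.round(3),
        "vdbp_ug_ml": vdbp.round(2), "albumin_g_dl": albumin.round(3),
        "measured_free_pg_ml": measured_free.round(3),
        "ipth_pg_ml": ipth.round(2),
        "ca_mg_dl": ca.round(2), "p_mg_dl": phos.round(2),
        "alp_iu_l": alp.round(1),
        "vitd_intake_iu_day": vitd_intake.round(1),
        "ca_intake_mg_day": ca_intake.round(1),
        "daylight_hours_week": daylight.round(2),
        "activity_days_week": activity_days.astype(float),
        "activity_min_day": activity_min,
        "fm_z": fm_z.round(3), "lm_z": lm_z.round(3),
        "bmc_tb_g": bmc_tb.round(2), "bmd_tb_g_cm2": bmd_tb.round(4),
        "bmd_ls_g_cm2": bmd_ls.round(4),
        "bmc_trunk_g": bmcs["trunk"].round(2),
        "bmc_upper_limbs_g": bmcs["upper_limbs"].round(2),
        "bmc_lower_limbs_g": bmcs["lower_limbs"].round(2),
        "area_trunk_cm2": areas["trunk"].round(2),
        "area_upper_limbs_cm2": areas["upper_limbs"].round(2),
        "area_lower_limbs_cm2": areas["lower_limbs"].round(2),
    }, columns=COHORT_COLUMNS)

    # missingness per the study's per-variable counts, applied as rates
    def knock(cols, rate):
        mask = rng.random(n) < rate
        for c in cols:
            df.loc[mask, c] = np.nan

    knock(["vitd_intake_iu_day"], params.miss_vitd_intake)
    knock(["ca_intake_mg_day"], params.miss_ca_intake)
    knock(["activity_days_week", "activity_min_day", "daylight_hours_week"],
          params.miss_activity_daylight)
    knock(["ca_mg_dl", "p_mg_dl", "alp_iu_l"], params.miss_chemistry)
    return df
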