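"""Unit and property tests for the equilibrium binding model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitdfree.binding import (
    BindingScheme,
    ConcentrationPanel,
    GcDiplotype,
    all_diplotypes,
    bioavailable_25ohd,
    bound_fractions,
    diplotype_affinity,
    free_25ohd,
    free_25ohd_exact,
    specific_scheme,
    to_molar,
)

TABLE = {"Gc1f": 1.12e9, "Gc1s": 0.60e9, "Gc2": 0.36e9}


class TestDiplotype:
    def test_six_distinct_diplotypes(self):
        dips = all_diplotypes()
        assert len(dips) == 6 == len(set(dips))

    def test_order_insensitive(self):
        assert GcDiplotype("Gc2", "Gc1f") == GcDiplotype("Gc1f", "Gc2")
        assert str(GcDiplotype("Gc2", "Gc1f")) == "Gc1f/Gc2"

    def test_unknown_allele_named_in_error(self):
        with pytest.raises(ValueError, match="Gc3"):
            GcDiplotype("Gc1f", "Gc3")

    @pytest.mark.parametrize("dip, expected", [
        ("Gc1f/Gc1f", 1.12e9),          # homozygote = allele value
        ("Gc1f/Gc2", 0.74e9),           # arithmetic mean of 1.12e9 and 0.36e9
        ("Gc1s/Gc2", 0.48e9),
    ])
    def test_mean_allele_affinity(self, dip, expected):
        assert diplotype_affinity(dip, TABLE) == pytest.approx(expected)

    def test_affinity_symmetric_in_allele_order(self):
        assert diplotype_affinity("Gc2/Gc1f", TABLE) == \
            diplotype_affinity("Gc1f/Gc2", TABLE)

    def test_missing_allele_raises(self):
        with pytest.raises(KeyError, match="Gc2"):
            diplotype_affinity("Gc1f/Gc2", {"Gc1f": 1e9, "Gc1s": 1e9})


class TestUnits:
    @pytest.mark.parametrize("value, analyte, expected", [
        (0.0, "25ohd", 0.0),
        (226.5, "vdbp", 226.5e-3 / 58_000),      # ~3.905e-6 M
        (4.3, "albumin", 43.0 / 66_500),          # ~6.47e-4 M
        (19.8, "25ohd", 19.8e-6 / 400.64),
    ])
    def test_to_molar(self, value, analyte, expected, constant_scheme):
        assert to_molar(value, analyte, constant_scheme) == pytest.approx(expected)

    def test_to_molar_linear(self, constant_scheme):
        a = to_molar(7.0, "vdbp", constant_scheme)
        b = to_molar(14.0, "vdbp", constant_scheme)
        assert b == pytest.approx(2 * a)

    def test_negative_input_rejected(self, constant_scheme):
        with pytest.raises(ValueError):
            to_molar(-1.0, "25ohd", constant_scheme)
        with pytest.raises(ValueError):
            ConcentrationPanel(-1.0, 200.0, 4.0)

    def test_pg_ng_round_trip(self):
        x = 6.34
        assert (x * 1000.0) / 1000.0 == pytest.approx(x, rel=1e-12)


class TestLinearModel:
    def test_zero_total_gives_zero(self, constant_scheme):
        r = free_25ohd(ConcentrationPanel(0.0, 226.5, 4.3), constant_scheme)
        assert r.free_25ohd == 0.0 and r.bioavailable_25ohd == 0.0

    def test_cohort_mean_inputs(self, constant_scheme):
        """Physiologic worked example: free ~6.3 pg/mL, fraction ~3.2e-4."""
        r = free_25ohd(ConcentrationPanel(19.8, 226.5, 4.3), constant_scheme)
        assert r.free_25ohd == pytest.approx(6.34, abs=0.05)
        assert r.fractions["free"] == pytest.approx(3.20e-4, rel=0.01)
        assert r.bioavailable_25ohd == pytest.approx(2.47, abs=0.02)

    def test_genotype_specific_direction(self, constant_scheme, allele_table):
        panel = ConcentrationPanel(19.8, 226.5, 4.3)
        gc22 = specific_scheme("Gc2/Gc2", allele_table, constant_scheme)
        gc11 = specific_scheme("Gc1f/Gc1f", allele_table, constant_scheme)
        f22 = free_25ohd(panel, gc22).free_25ohd
        f11 = free_25ohd(panel, gc11).free_25ohd
        assert f22 == pytest.approx(11.0, abs=0.3)
        assert f11 == pytest.approx(4.2, abs=0.3)
        assert f22 > f11

    def test_degenerate_no_binders(self, constant_scheme):
        r = free_25ohd(ConcentrationPanel(10.0, 0.0, 0.0), constant_scheme)
        assert r.free_25ohd == pytest.approx(10_000.0)  # pg/mL == total
        assert r.fractions["free"] == 1.0

    def test_fractions_match_printed_physiology(self, constant_scheme):
        fr = bound_fractions(ConcentrationPanel(19.8, 226.5, 4.3),
                             constant_scheme)
        assert fr["dbp_bound"] == pytest.approx(0.875, abs=0.005)
        assert fr["alb_bound"] == pytest.approx(0.124, abs=0.005)
        assert fr["free"] < 0.001

    def test_doubling_kdbp_monotonicity(self, constant_scheme):
        panel = ConcentrationPanel(19.8, 226.5, 4.3)
        hi = BindingScheme(2 * constant_scheme.k_dbp, constant_scheme.k_alb)
        f0, f1 = bound_fractions(panel, constant_scheme), bound_fractions(panel, hi)
        assert f1["dbp_bound"] > f0["dbp_bound"]
        assert f1["alb_bound"] < f0["alb_bound"]
        assert f1["free"] < f0["free"]

    @settings(max_examples=100, derandomize=True)
    @given(total=st.floats(0.0, 100.0), vdbp=st.floats(0.0, 500.0),
           alb=st.floats(0.0, 6.0))
    def test_fractions_sum_to_one(self, total, vdbp, alb, constant_scheme):
        fr = bound_fractions(ConcentrationPanel(total, vdbp, alb),
                             constant_scheme)
        assert math.isclose(sum(fr.values()), 1.0, abs_tol=1e-9)
        assert all(0.0 <= v <= 1.0 for v in fr.values())

    @settings(max_examples=60, derandomize=True)
    @given(total=st.floats(1.0, 60.0), vdbp=st.floats(100.0, 400.0),
           alb=st.floats(3.0, 5.5), bump=st.floats(1.01, 3.0))
    def test_monotone_in_inputs(self, total, vdbp, alb, bump, constant_scheme):
        base = free_25ohd(ConcentrationPanel(total, vdbp, alb),
                          constant_scheme).free_25ohd
        assert free_25ohd(ConcentrationPanel(total * bump, vdbp, alb),
                          constant_scheme).free_25ohd > base
        assert free_25ohd(ConcentrationPanel(total, vdbp * bump, alb),
                          constant_scheme).free_25ohd < base
        assert free_25ohd(ConcentrationPanel(total, vdbp, alb * bump),
                          constant_scheme).free_25ohd < base

    def test_free_leq_bioavailable_leq_total(self, constant_scheme):
        r = free_25ohd(ConcentrationPanel(19.8, 226.5, 4.3), constant_scheme)
        assert r.free_25ohd / 1000.0 <= r.bioavailable_25ohd <= 19.8


class TestBioavailable:
    def test_zero_free(self):
        assert bioavailable_25ohd(0.0, 6.47e-4, 6e5) == 0.0

    def test_zero_albumin_identity(self):
        assert bioavailable_25ohd(6.34, 0.0, 6e5) == pytest.approx(6.34 / 1000)

    def test_worked_example(self):
        # free 6.34 pg/mL with albumin 6.47e-4 M -> ~2.47 ng/mL bioavailable
        assert bioavailable_25ohd(6.34, 6.47e-4, 6e5) == pytest.approx(2.47, abs=0.01)


class TestExactOracle:
    def test_zero_total(self, constant_scheme):
        r = free_25ohd_exact(ConcentrationPanel(0.0, 226.5, 4.3),
                             constant_scheme)
        assert r.free_25ohd == 0.0

    def test_physiologic_agreement_with_linear(self, constant_scheme):
        panel = ConcentrationPanel(19.8, 226.5, 4.3)
        lin = free_25ohd(panel, constant_scheme).free_25ohd
        ex = free_25ohd_exact(panel, constant_scheme).free_25ohd
        assert ex == pytest.approx(6.4, abs=0.1)
        assert lin <= ex
        assert abs(lin - ex) / ex < 0.02

    def test_residual_below_tolerance(self, constant_scheme):
        panel = ConcentrationPanel(19.8, 226.5, 4.3)
        r = free_25ohd_exact(panel, constant_scheme, tol=1e-12)
        f = r.free_25ohd / (constant_scheme.mw_25ohd * 1e9)
        kd, ka = constant_scheme.k_dbp, constant_scheme.k_alb
        pd_ = to_molar(226.5, "vdbp", constant_scheme)
        pa = to_molar(4.3, "albumin", constant_scheme)
        total = to_molar(19.8, "25ohd", constant_scheme)
        resid = f * (1 + kd * pd_ / (1 + kd * f) + ka * pa / (1 + ka * f)) - total
        assert abs(resid) / total < 1e-9

    def test_saturation_limit(self, constant_scheme):
        # ligand 100x the binder: binders saturate, nearly all free
        vdbp = 1.0  # ug/mL -> 1.72e-8 M binder
        total_ng = 100 * vdbp * 400.64 / 58_000 * 1000  # 100x binder, in ng/mL
        r = free_25ohd_exact(ConcentrationPanel(total_ng, vdbp, 0.0),
                             constant_scheme)
        assert r.fractions["free"] > 0.98

    def test_exact_fractions_sum_to_one(self, constant_scheme):
        r = free_25ohd_exact(ConcentrationPanel(30.0, 150.0, 3.5),
                             constant_scheme)
        assert sum(r.fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_spe_free_strictly_ordered_by_mean_affinity(constant_scheme, allele_table):
    """Free level strictly decreases as the diplotype's mean affinity rises."""
    panel = ConcentrationPanel(19.8, 226.5, 4.3)
    by_affinity = sorted(
        all_diplotypes(), key=lambda d: diplotype_affinity(d, allele_table))
    frees = [free_25ohd(panel, specific_scheme(d, allele_table, constant_scheme)
                        ).free_25ohd for d in by_affinity]
    assert all(a > b for a, b in zip(frees, frees[1:]))


def test_scheme_validation():
    with pytest.raises(ValueError):
        BindingScheme(k_dbp=-1.0, k_alb=6e5)
    with pytest.raises(ValueError):
        BindingScheme(k_dbp=1e6, k_alb=6e5)  # ratio must exceed 100


def test_free_fraction_physiologic_band(constant_scheme):
    """Across VDBP 150-300 ug/mL and albumin 3.5-5 g/dL, free < 0.1 %."""
    for vdbp in np.linspace(150, 300, 6):
        for alb in np.linspace(3.5, 5.0, 4):
            fr = bound_fractions(ConcentrationPanel(20.0, vdbp, alb),
                                 constant_scheme)
            assert fr["free"] < 0.001


def test_linear_approximation_valid_where_depletion_negligible(constant_scheme):
    """The binder-total form tracks the depletion-corrected solution within
    2 % wherever ligand is under ~2 % of VDBP (molar) — the first-order
    depletion error is (VDBP-bound share) x (ligand/binder)."""
    for total in np.linspace(5.0, 60.0, 6):
        for vdbp in np.linspace(100.0, 400.0, 7):
            for alb in (3.0, 4.3, 5.5):
                if to_molar(total, "25ohd", constant_scheme) \
                        >= 0.02 * to_molar(vdbp, "vdbp", constant_scheme):
                    continue
                panel = ConcentrationPanel(total, vdbp, alb)
                lin = free_25ohd(panel, constant_scheme).free_25ohd
                ex = free_25ohd_exact(panel, constant_scheme).free_25ohd
                assert lin <= ex
                assert (ex - lin) / ex < 0.02
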