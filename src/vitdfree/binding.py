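"""Equilibrium free-hormone calculations for 25-hydroxyvitamin D.

Circulating 25OHD is almost entirely carried by vitamin D-binding protein
(VDBP, the Gc globulin) and, with far lower affinity, by albumin; only a
minute fraction (< 0.1 %) is free.  Under the free-hormone hypothesis the
free (and the "bioavailable" = free + albumin-bound) fraction is the
biologically available pool, and it is computed from measured total 25OHD,
VDBP and albumin by mass-action equilibrium.

Two parameterizations are supported:

* a *constant* scheme — one VDBP association constant for every subject,
  the classical Bikle-style calculation; and
* a *genotype-specific* scheme — the VDBP constant is the mean of the two
  Gc-allele affinities of the subject's diplotype (alleles Gc1f, Gc1s, Gc2
  form six diplotypes).

The default calculation is the linear (binder-total) approximation

    free = total / (1 + K_alb.[Alb] + K_dbp.[VDBP])

with all concentrations molar, which is exact in the physiologic regime
where ligand is scarce relative to binder.  A full mass-action solver with
binder depletion is provided as an independent oracle and opt-in mode.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping

from scipy.optimize import bisect

__all__ = [
    "GC_ALLELES",
    "GcDiplotype",
    "all_diplotypes",
    "BindingScheme",
    "ConcentrationPanel",
    "FreeBioAResult",
    "diplotype_affinity",
    "to_molar",
    "free_25ohd",
    "free_25ohd_exact",
    "bioavailable_25ohd",
    "bound_fractions",
    "specific_scheme",
]

#: The three common Gc (VDBP) alleles, in canonical order.
GC_ALLELES = ("Gc1f", "Gc1s", "Gc2")

# unit factors to g/L for the three analytes the panel carries
_TO_G_PER_L = {
    "25ohd": 1e-6,   # ng/mL
    "vdbp": 1e-3,    # ug/mL
    "albumin": 10.0, # g/dL
}


@dataclass(frozen=True, order=True)
class GcDiplotype:
    """Unordered pair of Gc alleles; six distinct diplotypes exist.

    Construction canonicalizes allele order, so ``GcDiplotype("Gc2","Gc1f")``
    equals ``GcDiplotype("Gc1f","Gc2")``.
    """

    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        for a in (self.allele1, self.allele2):
            if a not in GC_ALLELES:
                raise ValueError(
                    f"unknown Gc allele {a!r}; expected one of {GC_ALLELES}"
                )
        a, b = sorted((self.allele1, self.allele2), key=GC_ALLELES.index)
        object.__setattr__(self, "allele1", a)
        object.__setattr__(self, "allele2", b)

    @classmethod
    def parse(cls, text: str) -> "GcDiplotype":
        """Parse ``'Gc1f/Gc2'``-style labels (order-insensitive)."""
        parts = str(text).strip().split("/")
        if len(parts) != 2:
            raise ValueError(f"cannot parse diplotype {text!r}; expected 'A/B'")
        return cls(parts[0].strip(), parts[1].strip())

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele1, self.allele2)

    def __str__(self) -> str:
        return f"{self.allele1}/{self.allele2}"


def all_diplotypes() -> list[GcDiplotype]:
    """The six distinct Gc diplotypes in canonical order."""
    return [
        GcDiplotype(a, b)
        for a, b in itertools.combinations_with_replacement(GC_ALLELES, 2)
    ]


@dataclass(frozen=True)
class BindingScheme:
    """One free-hormone parameterization: affinities plus molar masses.

    Parameters
    ----------
    k_dbp : float
        VDBP–25OHD association constant (M^-1).
    k_alb : float
        Albumin–25OHD association constant (M^-1).
    mw_25ohd, mw_vdbp, mw_albumin : float
        Molar masses (g/mol) used for unit conversion.
    label : str
        ``"constant"`` or ``"specific:<diplotype>"``.
    """

    k_dbp: float
    k_alb: float
    mw_25ohd: float = 400.64
    mw_vdbp: float = 58_000.0
    mw_albumin: float = 66_500.0
    label: str = "constant"

    def __post_init__(self) -> None:
        for name in ("k_dbp", "k_alb", "mw_25ohd", "mw_vdbp", "mw_albumin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.k_dbp / self.k_alb <= 100:
            raise ValueError(
                "k_dbp must exceed k_alb by more than two orders of magnitude"
            )


@dataclass(frozen=True)
class ConcentrationPanel:
    """Measured concentrations in their native clinical units."""

    total_25ohd: float  # ng/mL
    vdbp: float         # ug/mL
    albumin: float      # g/dL

    def __post_init__(self) -> None:
        for name in ("total_25ohd", "vdbp", "albumin"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")


@dataclass(frozen=True)
class FreeBioAResult:
    """Free / bioavailable 25OHD and the three binding-state fractions."""

    free_25ohd: float          # pg/mL
    bioavailable_25ohd: float  # ng/mL
    fractions: Mapping[str, float] = field(default_factory=dict)


def diplotype_affinity(
    diplotype: GcDiplotype | str, allele_table: Mapping[str, float]
) -> float:
    """Mean VDBP affinity (M^-1) of a diplotype's two alleles.

    The genotype-specific calculation uses, for each subject, the average of
    the association constants of the two Gc alleles carried.
    """
    if isinstance(diplotype, str):
        diplotype = GcDiplotype.parse(diplotype)
    ks = []
    for a in diplotype.alleles:
        if a not in allele_table:
            raise KeyError(f"allele table has no affinity for allele {a!r}")
        k = float(allele_table[a])
        if k <= 0:
            raise ValueError(f"affinity for allele {a!r} must be positive, got {k}")
        ks.append(k)
    return (ks[0] + ks[1]) / 2.0


def to_molar(value: float, analyte: str, scheme: BindingScheme) -> float:
    """Convert a native-unit concentration to mol/L.

    ``analyte`` is one of ``'25ohd'`` (ng/mL), ``'vdbp'`` (ug/mL) or
    ``'albumin'`` (g/dL); the matching molar mass is taken from ``scheme``.
    """
    key = analyte.lower()
    if key not in _TO_G_PER_L:
        raise ValueError(f"unknown analyte {analyte!r}; expected one of "
                         f"{sorted(_TO_G_PER_L)}")
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"concentration must be finite and non-negative, got {value}")
    mw = {
        "25ohd": scheme.mw_25ohd,
        "vdbp": scheme.mw_vdbp,
        "albumin": scheme.mw_albumin,
    }[key]
    return value * _TO_G_PER_L[key] / mw


def _molar_panel(panel: ConcentrationPanel, scheme: BindingScheme):
    return (
        to_molar(panel.total_25ohd, "25ohd", scheme),
        to_molar(panel.vdbp, "vdbp", scheme),
        to_molar(panel.albumin, "albumin", scheme),
    )


def bound_fractions(
    panel: ConcentrationPanel, scheme: BindingScheme
) -> dict[str, float]:
    """Linear-model binding-state fractions {dbp_bound, alb_bound, free}.

    Under the binder-total approximation the fractions are independent of
    total 25OHD: with D = 1 + K_alb.[Alb] + K_dbp.[VDBP], the free fraction
    is 1/D, the albumin-bound fraction K_alb.[Alb]/D and the VDBP-bound
    fraction K_dbp.[VDBP]/D; they sum to one by construction.
    """
    _, vdbp_m, alb_m = _molar_panel(panel, scheme)
    t_dbp = scheme.k_dbp * vdbp_m
    t_alb = scheme.k_alb * alb_m
    denom = 1.0 + t_alb + t_dbp
    return {
        "dbp_bound": t_dbp / denom,
        "alb_bound": t_alb / denom,
        "free": 1.0 / denom,
    }


def free_25ohd(panel: ConcentrationPanel, scheme: BindingScheme) -> FreeBioAResult:
    """Free and bioavailable 25OHD under the linear (binder-total) model.

    Returns free 25OHD in pg/mL and bioavailable (free + albumin-bound)
    25OHD in ng/mL, mirroring the units these quantities are reported in
    clinically.  With zero VDBP and albumin the result degenerates to
    free = total.
    """
    fractions = bound_fractions(panel, scheme)
    total_pg = panel.total_25ohd * 1000.0
    free_pg = total_pg * fractions["free"]
    bioa_ng = panel.total_25ohd * (fractions["free"] + fractions["alb_bound"])
    return FreeBioAResult(free_pg, bioa_ng, fractions)


def bioavailable_25ohd(free: float, albumin_molar: float, k_alb: float) -> float:
    """Bioavailable 25OHD (ng/mL) from free 25OHD (pg/mL).

    Bioavailable = free + albumin-bound = free * (1 + K_alb.[Alb]); at zero
    albumin it equals the free level (unit-harmonized).
    """
    if free < 0 or albumin_molar < 0 or k_alb < 0:
        raise ValueError("inputs must be non-negative")
    return free * (1.0 + k_alb * albumin_molar) / 1000.0


def free_25ohd_exact(
    panel: ConcentrationPanel, scheme: BindingScheme, tol: float = 1e-10
) -> FreeBioAResult:
    """Full mass-action equilibrium with binder depletion.

    Solves, by bisection for the free molar concentration F in [0, total],

        total = F * (1 + K_dbp.P_dbp/(1 + K_dbp.F) + K_alb.P_alb/(1 + K_alb.F))

    where P_dbp, P_alb are *total* binder concentrations.  Because bound
    ligand depletes free binder, the exact free level is never below the
    linear approximation; in the physiologic regime (ligand << binder) the
    two agree to well under 2 %.

    ``tol`` is the relative tolerance on F.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    total_m, vdbp_m, alb_m = _molar_panel(panel, scheme)
    if total_m == 0.0:
        return FreeBioAResult(0.0, 0.0, bound_fractions(panel, scheme))

    kd, ka = scheme.k_dbp, scheme.k_alb

    def mass_balance(f: float) -> float:
        return f * (1.0 + kd * vdbp_m / (1.0 + kd * f)
                    + ka * alb_m / (1.0 + ka * f)) - total_m

    lo, hi = 0.0, total_m
    assert mass_balance(lo) <= 0.0 <= mass_balance(hi), "root not bracketed"
    f = bisect(mass_balance, lo, hi, rtol=max(tol, 1e-15), xtol=total_m * 1e-16)

    frac_free = f / total_m
    frac_dbp = kd * vdbp_m * f / (1.0 + kd * f) / total_m
    frac_alb = ka * alb_m * f / (1.0 + ka * f) / total_m
    free_pg = f * scheme.mw_25ohd * 1e9
    bioa_ng = panel.total_25ohd * (frac_free + frac_alb)
    return FreeBioAResult(
        free_pg, bioa_ng,
        {"dbp_bound": frac_dbp, "alb_bound": frac_alb, "free": frac_free},
    )


def specific_scheme(
    diplotype: GcDiplotype | str,
    allele_table: Mapping[str, float],
    base: BindingScheme,
) -> BindingScheme:
    """Genotype-specific scheme: ``base`` with k_dbp replaced by the mean
    allele affinity of ``diplotype``."""
    k = diplotype_affinity(diplotype, allele_table)
    label = f"specific:{diplotype}"
    return BindingScheme(
        k_dbp=k, k_alb=base.k_alb, mw_25ohd=base.mw_25ohd,
        mw_vdbp=base.mw_vdbp, mw_albumin=base.mw_albumin, label=label,
    )
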