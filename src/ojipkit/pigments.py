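"""Chlorophyll quantification from extract absorbances.

Absorbances at 663 and 646 nm are converted to chlorophyll a and b
concentrations with a named spectrophotometric coefficient set and scaled
by extract volume, dilution and fresh mass to mg g^-1 fresh weight. The
default set is the classical 80%-acetone pair

    Chl a (ug mL^-1) = 12.25 A663 - 2.55 A646
    Chl b (ug mL^-1) = 20.31 A646 - 4.91 A663

The coefficient table is user-overridable: mixed-solvent extractions
(e.g. acetone:ethanol) have no canonical published coefficients, so the set
in use is always named in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import OjipError


@dataclass(frozen=True)
class PigmentCoefficients:
    """ug mL^-1 per absorbance unit: chl = a663 * A663 + a646 * A646."""

    name: str
    chl_a_663: float
    chl_a_646: float
    chl_b_663: float
    chl_b_646: float


COEFFICIENT_SETS: dict[str, PigmentCoefficients] = {
    "porra-80-acetone": PigmentCoefficients(
        name="porra-80-acetone",
        chl_a_663=12.25, chl_a_646=-2.55,
        chl_b_663=-4.91, chl_b_646=20.31,
    ),
}

DEFAULT_COEFFICIENTS = "porra-80-acetone"


@dataclass(frozen=True)
class PigmentRecord:
    """One extract measurement: absorbances plus preparation metadata."""

    a_663: float
    a_646: float
    dilution_factor: float = 1.0
    fresh_mass_g: float = 0.1
    extract_volume_ml: float = 10.0
    sample_id: str = ""
    group: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.a_663 < 0 or self.a_646 < 0:
            raise OjipError("absorbances must be nonnegative")
        if min(self.dilution_factor, self.fresh_mass_g, self.extract_volume_ml) <= 0:
            raise OjipError("dilution, mass and volume must be positive")


@dataclass(frozen=True)
class PigmentResult:
    """Chl a, Chl b, Chl a+b in mg g^-1 fresh mass, and the Chl a/b ratio.

    ``chl_a_over_b`` is ``nan`` (flagged) when Chl b is zero.
    """

    chl_a: float
    chl_b: float
    chl_ab_sum: float
    chl_a_over_b: float
    coefficient_set: str
    qc_flags: tuple[str, ...] = ()


def pigment_concentrations(
    rec: PigmentRecord,
    coefficients: str | PigmentCoefficients = DEFAULT_COEFFICIENTS,
) -> PigmentResult:
    """Convert one absorbance record to per-fresh-mass concentrations.

    Negative computed concentrations (possible for distorted spectra) are
    floored at 0 and flagged; absorbances >= 2 are outside the usual linear
    range of a spectrophotometer and are flagged but still converted.
    """
    coef = (COEFFICIENT_SETS[coefficients]
            if isinstance(coefficients, str) else coefficients)
    flags: list[str] = []
    if max(rec.a_663, rec.a_646) >= 2.0:
        flags.append("absorbance outside linear range (>= 2)")

    a663 = rec.a_663 * rec.dilution_factor
    a646 = rec.a_646 * rec.dilution_factor
    chl_a_ug_ml = coef.chl_a_663 * a663 + coef.chl_a_646 * a646
    chl_b_ug_ml = coef.chl_b_663 * a663 + coef.chl_b_646 * a646
    if chl_a_ug_ml < 0:
        flags.append("negative Chl a floored at 0")
        chl_a_ug_ml = 0.0
    if chl_b_ug_ml < 0:
        flags.append("negative Chl b floored at 0")
        chl_b_ug_ml = 0.0

    # ug mL^-1 * mL / (1000 ug/mg) / g -> mg g^-1 fresh mass
    to_mg_per_g = rec.extract_volume_ml / (1000.0 * rec.fresh_mass_g)
    chl_a = chl_a_ug_ml * to_mg_per_g
    chl_b = chl_b_ug_ml * to_mg_per_g
    if chl_b > 0:
        ratio = chl_a / chl_b
    else:
        ratio = math.nan
        flags.append("Chl b is zero, a/b ratio unset")
    return PigmentResult(
        chl_a=chl_a, chl_b=chl_b, chl_ab_sum=chl_a + chl_b, chl_a_over_b=ratio,
        coefficient_set=coef.name, qc_flags=tuple(flags),
    )


def absorbances_for(
    chl_a_ug_ml: float,
    chl_b_ug_ml: float,
    coefficients: str | PigmentCoefficients = DEFAULT_COEFFICIENTS,
) -> tuple[float, float]:
    """Invert the coefficient set: extract concentrations -> (A663, A646).

    Used by the synthetic-data generator to fabricate absorbance records
    with known ground-truth pigment content.
    """
    coef = (COEFFICIENT_SETS[coefficients]
            if isinstance(coefficients, str) else coefficients)
    det = coef.chl_a_663 * coef.chl_b_646 - coef.chl_a_646 * coef.chl_b_663
    a663 = (coef.chl_b_646 * chl_a_ug_ml - coef.chl_a_646 * chl_b_ug_ml) / det
    a646 = (coef.chl_a_663 * chl_b_ug_ml - coef.chl_b_663 * chl_a_ug_ml) / det
    return a663, a646
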