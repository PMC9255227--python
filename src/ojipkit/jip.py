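"""The JIP-test: energy-flux parameters from OJIP cardinal points.

The cascade derives quantum yields, per-reaction-centre fluxes and the two
performance indices from five cardinal fluorescence values (F_o, F_K, F_J,
F_I, F_m). With V_J and V_I the relative variable fluorescence at J and I on
the O-P scale:

    phi_Po  = F_v/F_m = 1 - F_o/F_m         max PSII photochemical yield
    M_o     = 4 (F_K - F_o)/(F_m - F_o)     initial rise slope, ms^-1
    psi_Eo  = 1 - V_J                       electron transport past Q_A-
    phi_Eo  = phi_Po * psi_Eo
    delta_Ro= (1 - V_I)/(1 - V_J)           efficiency to PSI end acceptors
    phi_Ro  = phi_Po * psi_Eo * delta_Ro
    ABS/RC  = M_o / (V_J * phi_Po)          absorption flux per RC
    TR_o/RC = M_o / V_J                     trapping flux per RC
    ET_o/RC = (M_o/V_J) * psi_Eo            electron transport flux per RC
    DI_o/RC = ABS/RC - TR_o/RC              dissipation flux per RC
    RC/ABS  = phi_Po * V_J / M_o
    PI_ABS  = RC/ABS * phi_Po/(1-phi_Po) * psi_Eo/(1-psi_Eo)
    PI_total= PI_ABS * delta_Ro/(1-delta_Ro)

All parameters are ratios of baseline-subtracted fluorescence, hence exactly
invariant under rescaling the raw signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .errors import JipUndefinedError
from .normalization import RelativeVariableFluorescence, relative_variable_fluorescence
from .transient import CardinalPoints

logger = logging.getLogger("ojipkit")

#: Parameters reported per sample by the batch driver.
TABLE_PARAMETERS = ("V_L", "V_K", "V_J", "Fv/Fm", "PI_ABS", "PI_total")


@dataclass(frozen=True)
class JipParameters:
    """Derived JIP-test quantities for one transient.

    ``pi_total`` is ``nan`` (with a flag) when V_I <= V_J leaves delta_Ro
    undefined. Out-of-range but finite values are flagged, never clamped.
    """

    fv_over_fm: float
    m_o: float
    v_j: float
    v_i: float
    psi_eo: float
    phi_eo: float
    delta_ro: float
    phi_ro: float
    abs_per_rc: float
    tro_per_rc: float
    eto_per_rc: float
    dio_per_rc: float
    rc_per_abs: float
    pi_abs: float
    pi_total: float
    qc_flags: tuple[str, ...] = ()


def jip_parameters(
    cardinals: CardinalPoints,
    rvf: RelativeVariableFluorescence | None = None,
) -> JipParameters:
    """Run the cascade on one set of cardinal points.

    ``rvf`` supplies V_J and V_I (O-P scale); it is derived from
    ``cardinals`` when omitted.
    """
    f_o, f_k, f_m = cardinals.f_o, cardinals.f_k, cardinals.f_p
    if f_m <= f_o:
        raise JipUndefinedError("F_m <= F_o: no variable fluorescence, JIP-test undefined")
    if rvf is None:
        rvf = relative_variable_fluorescence(cardinals)
    v_j, v_i = rvf.v_j, rvf.v_i
    phi_po = 1.0 - f_o / f_m
    if not 0.0 < v_j < 1.0 or not 0.0 < phi_po < 1.0:
        raise JipUndefinedError("index undefined (division by zero): V_J or phi_Po at 0 or 1")

    flags: list[str] = []
    m_o = 4.0 * (f_k - f_o) / (f_m - f_o)
    psi_eo = 1.0 - v_j
    phi_eo = phi_po * psi_eo
    tro_per_rc = m_o / v_j
    abs_per_rc = tro_per_rc / phi_po
    eto_per_rc = tro_per_rc * psi_eo
    dio_per_rc = abs_per_rc - tro_per_rc
    rc_per_abs = phi_po * v_j / m_o
    pi_abs = rc_per_abs * (phi_po / (1.0 - phi_po)) * (psi_eo / (1.0 - psi_eo))

    if v_i <= v_j:
        flags.append("delta_Ro undefined (V_I <= V_J)")
        delta_ro = math.nan
        phi_ro = math.nan
        pi_total = math.nan
    else:
        delta_ro = (1.0 - v_i) / (1.0 - v_j)
        phi_ro = phi_eo * delta_ro
        pi_total = pi_abs * delta_ro / (1.0 - delta_ro)

    if pi_abs > 100.0:
        flags.append("PI_ABS out of plausible range")
    if m_o <= 0.0:
        flags.append("nonpositive M_o (no K-phase rise)")
    return JipParameters(
        fv_over_fm=phi_po, m_o=m_o, v_j=v_j, v_i=v_i,
        psi_eo=psi_eo, phi_eo=phi_eo, delta_ro=delta_ro, phi_ro=phi_ro,
        abs_per_rc=abs_per_rc, tro_per_rc=tro_per_rc, eto_per_rc=eto_per_rc,
        dio_per_rc=dio_per_rc, rc_per_abs=rc_per_abs,
        pi_abs=pi_abs, pi_total=pi_total, qc_flags=tuple(flags),
    )


def jip_row(cardinals: CardinalPoints, rvf: RelativeVariableFluorescence) -> dict[str, float]:
    """The six reported parameters {V_L, V_K, V_J, Fv/Fm, PI_ABS, PI_total}."""
    p = jip_parameters(cardinals, rvf)
    return {
        "V_L": rvf.v_l,
        "V_K": rvf.v_k,
        "V_J": rvf.v_j,
        "Fv/Fm": p.fv_over_fm,
        "PI_ABS": p.pi_abs,
        "PI_total": p.pi_total,
    }


def jip_table(sheet, config=None):
    """Per-replicate batch driver: sample sheet -> tidy parameter table.

    Reads each referenced transient, extracts cardinals per replicate
    (curves are never averaged before extraction), and emits one row per
    sample x parameter. Samples whose curve cannot be read or whose
    extraction is QC-flagged are excluded with a log entry; a group losing
    all its samples is an error.

    Implemented in :mod:`ojipkit.pipeline` to keep file handling in one
    place; re-exported here.
    """
    from .pipeline import jip_table as _impl

    return _impl(sheet, config)
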