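"""Independent brute-force oracles.

Everything here is coded directly from the defining formulas in plain
Python, deliberately sharing no code with the library, so tests compare two
separate derivations of each quantity.
"""

import math


def jip_oracle(f_o, f_k, f_j, f_i, f_m):
    """The JIP-test cascade evaluated step by step from five cardinals."""
    v_j = (f_j - f_o) / (f_m - f_o)
    v_i = (f_i - f_o) / (f_m - f_o)
    phi_po = 1.0 - f_o / f_m
    m_o = 4.0 * (f_k - f_o) / (f_m - f_o)
    psi_eo = 1.0 - v_j
    phi_eo = phi_po * psi_eo
    delta_ro = (1.0 - v_i) / (1.0 - v_j)
    abs_rc = m_o * (1.0 / v_j) * (1.0 / phi_po)
    tro_rc = m_o / v_j
    eto_rc = (m_o / v_j) * psi_eo
    dio_rc = abs_rc - tro_rc
    rc_abs = phi_po * (v_j / m_o)
    pi_abs = rc_abs * (phi_po / (1.0 - phi_po)) * (psi_eo / (1.0 - psi_eo))
    pi_total = pi_abs * (delta_ro / (1.0 - delta_ro))
    return {
        "fv_over_fm": phi_po, "m_o": m_o, "v_j": v_j, "v_i": v_i,
        "psi_eo": psi_eo, "phi_eo": phi_eo, "delta_ro": delta_ro,
        "phi_ro": phi_po * psi_eo * delta_ro,
        "abs_per_rc": abs_rc, "tro_per_rc": tro_rc, "eto_per_rc": eto_rc,
        "dio_per_rc": dio_rc, "rc_per_abs": rc_abs,
        "pi_abs": pi_abs, "pi_total": pi_total,
    }


# The worked cardinal set and the values the oracle produces for it,
# recomputed by hand as exact fractions before the library existed:
# phi_Po=4/5, M_o=3/5, V_J=7/20, V_I=13/20, psi_Eo=13/20, phi_Eo=13/25,
# delta_Ro=7/13, ABS/RC=15/7, TRo/RC=12/7, ETo/RC=39/35, DIo/RC=3/7,
# RC/ABS=7/15, PI_ABS=52/15, PI_total=182/45.
WORKED_CARDINALS = dict(f_o=5000.0, f_k=8000.0, f_j=12000.0,
                        f_i=18000.0, f_m=25000.0)
WORKED_EXPECTED = {
    "fv_over_fm": 4.0 / 5.0,
    "m_o": 3.0 / 5.0,
    "v_j": 7.0 / 20.0,
    "v_i": 13.0 / 20.0,
    "psi_eo": 13.0 / 20.0,
    "phi_eo": 13.0 / 25.0,
    "delta_ro": 7.0 / 13.0,
    "phi_ro": 4.0 / 5.0 * 13.0 / 20.0 * 7.0 / 13.0,
    "abs_per_rc": 15.0 / 7.0,
    "tro_per_rc": 12.0 / 7.0,
    "eto_per_rc": 39.0 / 35.0,
    "dio_per_rc": 3.0 / 7.0,
    "rc_per_abs": 7.0 / 15.0,
    "pi_abs": 52.0 / 15.0,
    "pi_total": 182.0 / 45.0,
}


def anova_oracle(groups):
    """One-way ANOVA by explicit sums of squares over a dict of lists."""
    all_values = [x for v in groups.values() for x in v]
    n = len(all_values)
    k = len(groups)
    grand = sum(all_values) / n
    ssb = sum(len(v) * (sum(v) / len(v) - grand) ** 2 for v in groups.values())
    ssw = sum(sum((x - sum(v) / len(v)) ** 2 for x in v) for v in groups.values())
    df_b, df_e = k - 1, n - k
    msb = ssb / df_b
    mse = ssw / df_e
    f = msb / mse if mse > 0 else math.inf
    return {"f": f, "msb": msb, "mse": mse, "df_b": df_b, "df_e": df_e}


def hill_curve(t, fo, fm, amplitudes, taus, h, t_o=0.01, t_p=1000.0):
    """Closed-form endpoint-pinned Hill mixture, scalar math only."""
    def s(x, tau):
        return x ** h / (x ** h + tau ** h)

    total = 0.0
    for a, tau in zip(amplitudes, taus):
        total += a * (s(t, tau) - s(t_o, tau)) / (s(t_p, tau) - s(t_o, tau))
    return fo + (fm - fo) * total
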