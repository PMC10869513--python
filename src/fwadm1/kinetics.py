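"""Compiled kinetic core: charge-balance pH, process rates, ODE right-hand side.

pH is solved algebraically at every rate evaluation (DAE-free formulation);
dissolved hydrogen stays a dynamic state.  Ion pairs (VFA anions, bicarbonate,
ammonium) are speciated algebraically from their total pools and the proton
activity.  The formulation follows the classic benchmark realisation of the
model with a fixed-headspace-pressure gas vent.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import constants as c
from .params import (
    KIN_K_DIS, KIN_KHYD_CH, KIN_KHYD_PR, KIN_KHYD_LI, KIN_KM_SU, KIN_KS_SU,
    KIN_KM_AA, KIN_KS_AA, KIN_KM_FA, KIN_KS_FA, KIN_KIH2_FA, KIN_KM_C4,
    KIN_KS_C4, KIN_KIH2_C4, KIN_KM_PRO, KIN_KS_PRO, KIN_KIH2_PRO, KIN_KM_AC,
    KIN_KS_AC, KIN_KI_NH3, KIN_KM_H2, KIN_KS_H2, KIN_KDEC, KIN_KS_IN,
    KIN_PHUL_AA, KIN_PHLL_AA, KIN_PHUL_AC, KIN_PHLL_AC, KIN_PHUL_H2,
    KIN_PHLL_H2, KIN_KA_VA, KIN_KA_BU, KIN_KA_PRO, KIN_KA_AC, KIN_KA_CO2,
    KIN_KA_IN, KIN_KW, KIN_KLA, KIN_KH_H2, KIN_KH_CH4, KIN_KH_CO2,
    KIN_P_ATM, KIN_P_H2O, KIN_T_OP,
)

SH_LO = 1e-12   # pH 12 bracket
SH_HI = 1e-2    # pH 2 bracket

# liquid COD-carrying state indices, for the effluent COD ledger
_LIQ_COD = (c.S_SU, c.S_AA, c.S_FA, c.S_VA, c.S_BU, c.S_PRO, c.S_AC,
            c.S_H2, c.S_CH4, c.S_I, c.X_C, c.X_CH, c.X_PR, c.X_LI,
            c.X_SU, c.X_AA, c.X_FA, c.X_C4, c.X_PRO, c.X_AC, c.X_H2, c.X_I)


@njit(cache=True)
def charge_balance(sh, scat, san, s_in, s_ic, s_ac, s_pro, s_bu, s_va, kin):
    """Net charge (kmol m-3) at proton concentration `sh`."""
    ka_in = kin[KIN_KA_IN]
    nh4 = s_in * sh / (sh + ka_in)
    hco3 = s_ic * kin[KIN_KA_CO2] / (sh + kin[KIN_KA_CO2])
    ac = (s_ac / c.COD_MOL_AC) * kin[KIN_KA_AC] / (sh + kin[KIN_KA_AC])
    pro = (s_pro / c.COD_MOL_PRO) * kin[KIN_KA_PRO] / (sh + kin[KIN_KA_PRO])
    bu = (s_bu / c.COD_MOL_BU) * kin[KIN_KA_BU] / (sh + kin[KIN_KA_BU])
    va = (s_va / c.COD_MOL_VA) * kin[KIN_KA_VA] / (sh + kin[KIN_KA_VA])
    oh = kin[KIN_KW] / sh
    return scat + nh4 + sh - hco3 - ac - pro - bu - va - oh - san


@njit(cache=True)
def solve_sh(y, kin):
    """Proton concentration from electroneutrality (safeguarded Newton).

    The balance is strictly increasing in S_H+, so the root in
    [SH_LO, SH_HI] is unique; Newton steps are clipped to the shrinking
    bisection bracket.
    """
    scat, san = y[c.S_CAT], y[c.S_AN]
    s_in, s_ic = y[c.S_IN], y[c.S_IC]
    s_ac, s_pro, s_bu, s_va = y[c.S_AC], y[c.S_PRO], y[c.S_BU], y[c.S_VA]

    lo, hi = SH_LO, SH_HI
    f_lo = charge_balance(lo, scat, san, s_in, s_ic, s_ac, s_pro, s_bu,
                          s_va, kin)
    if f_lo >= 0.0:
        return lo
    f_hi = charge_balance(hi, scat, san, s_in, s_ic, s_ac, s_pro, s_bu,
                          s_va, kin)
    if f_hi <= 0.0:
        return hi

    sh = 1e-7
    for _ in range(100):
        f = charge_balance(sh, scat, san, s_in, s_ic, s_ac, s_pro, s_bu,
                           s_va, kin)
        if f > 0.0:
            hi = sh
        else:
            lo = sh
        # analytic derivative
        ka = kin[KIN_KA_IN]
        d = 1.0 + kin[KIN_KW] / (sh * sh)
        d += s_in * ka / ((sh + ka) ** 2)
        ka = kin[KIN_KA_CO2]
        d += s_ic * ka / ((sh + ka) ** 2)
        ka = kin[KIN_KA_AC]
        d += (s_ac / c.COD_MOL_AC) * ka / ((sh + ka) ** 2)
        ka = kin[KIN_KA_PRO]
        d += (s_pro / c.COD_MOL_PRO) * ka / ((sh + ka) ** 2)
        ka = kin[KIN_KA_BU]
        d += (s_bu / c.COD_MOL_BU) * ka / ((sh + ka) ** 2)
        ka = kin[KIN_KA_VA]
        d += (s_va / c.COD_MOL_VA) * ka / ((sh + ka) ** 2)
        step = f / d
        sh_new = sh - step
        if not (lo < sh_new < hi):
            sh_new = 0.5 * (lo + hi)
        if abs(sh_new - sh) < 1e-16 * sh_new + 1e-30:
            sh = sh_new
            break
        sh = sh_new
    return sh


@njit(cache=True)
def inhibition_ph(ph, ph_ul, ph_ll):
    """Lower-side empirical pH inhibition switch (1 above the upper limit)."""
    if ph >= ph_ul:
        return 1.0
    x = (ph - ph_ul) / (ph_ul - ph_ll)
    return np.exp(-3.0 * x * x)


@njit(cache=True)
def rates_given_sh(y, kin, sh):
    """The 19 process rates at state `y` and proton concentration `sh`."""
    rho = np.zeros(19)
    ph = -np.log10(sh)

    s_su = max(y[c.S_SU], 0.0)
    s_aa = max(y[c.S_AA], 0.0)
    s_fa = max(y[c.S_FA], 0.0)
    s_va = max(y[c.S_VA], 0.0)
    s_bu = max(y[c.S_BU], 0.0)
    s_pro = max(y[c.S_PRO], 0.0)
    s_ac = max(y[c.S_AC], 0.0)
    s_h2 = max(y[c.S_H2], 0.0)
    s_in = max(y[c.S_IN], 0.0)

    i_ph_aa = inhibition_ph(ph, kin[KIN_PHUL_AA], kin[KIN_PHLL_AA])
    i_ph_ac = inhibition_ph(ph, kin[KIN_PHUL_AC], kin[KIN_PHLL_AC])
    i_ph_h2 = inhibition_ph(ph, kin[KIN_PHUL_H2], kin[KIN_PHLL_H2])
    i_in = s_in / (s_in + kin[KIN_KS_IN])
    i_h2_fa = 1.0 / (1.0 + s_h2 / kin[KIN_KIH2_FA])
    i_h2_c4 = 1.0 / (1.0 + s_h2 / kin[KIN_KIH2_C4])
    i_h2_pro = 1.0 / (1.0 + s_h2 / kin[KIN_KIH2_PRO])
    s_nh3 = s_in * kin[KIN_KA_IN] / (kin[KIN_KA_IN] + sh)
    i_nh3 = 1.0 / (1.0 + s_nh3 / kin[KIN_KI_NH3])

    rho[0] = kin[KIN_K_DIS] * max(y[c.X_C], 0.0)
    rho[1] = kin[KIN_KHYD_CH] * max(y[c.X_CH], 0.0)
    rho[2] = kin[KIN_KHYD_PR] * max(y[c.X_PR], 0.0)
    rho[3] = kin[KIN_KHYD_LI] * max(y[c.X_LI], 0.0)

    rho[4] = (kin[KIN_KM_SU] * s_su / (kin[KIN_KS_SU] + s_su)
              * max(y[c.X_SU], 0.0) * i_ph_aa * i_in)
    rho[5] = (kin[KIN_KM_AA] * s_aa / (kin[KIN_KS_AA] + s_aa)
              * max(y[c.X_AA], 0.0) * i_ph_aa * i_in)
    rho[6] = (kin[KIN_KM_FA] * s_fa / (kin[KIN_KS_FA] + s_fa)
              * max(y[c.X_FA], 0.0) * i_ph_aa * i_in * i_h2_fa)
    c4 = max(y[c.X_C4], 0.0)
    tot_c4 = s_va + s_bu + 1e-6
    rho[7] = (kin[KIN_KM_C4] * s_va / (kin[KIN_KS_C4] + s_va) * c4
              * (s_va / tot_c4) * i_ph_aa * i_in * i_h2_c4)
    rho[8] = (kin[KIN_KM_C4] * s_bu / (kin[KIN_KS_C4] + s_bu) * c4
              * (s_bu / tot_c4) * i_ph_aa * i_in * i_h2_c4)
    rho[9] = (kin[KIN_KM_PRO] * s_pro / (kin[KIN_KS_PRO] + s_pro)
              * max(y[c.X_PRO], 0.0) * i_ph_aa * i_in * i_h2_pro)
    rho[10] = (kin[KIN_KM_AC] * s_ac / (kin[KIN_KS_AC] + s_ac)
               * max(y[c.X_AC], 0.0) * i_ph_ac * i_in * i_nh3)
    rho[11] = (kin[KIN_KM_H2] * s_h2 / (kin[KIN_KS_H2] + s_h2)
               * max(y[c.X_H2], 0.0) * i_ph_h2 * i_in)

    for j in range(7):
        rho[12 + j] = kin[KIN_KDEC + j] * max(y[c.X_SU + j], 0.0)
    return rho


@njit(cache=True)
def rhs(t, y, nu_t, kin, y_in, q, v_liq, v_gas):
    """Mass-continuity derivative of the full state vector.

    dC/dt = Q/V (C_in - C) + sum_j nu_ij rho_j, plus liquid-gas transfer,
    headspace venting at fixed total pressure, and ledger accumulation.
    """
    dy = np.zeros(y.shape[0])
    sh = solve_sh(y, kin)
    rho = rates_given_sh(y, kin, sh)

    # biochemical terms
    for i in range(c.N_CORE):
        acc = 0.0
        for j in range(19):
            acc += nu_t[i, j] * rho[j]
        dy[i] = acc

    # liquid-gas transfer
    r_t = kin[KIN_T_OP] * c.R_BAR
    p_h2 = max(y[c.G_H2], 0.0) * r_t / c.COD_MOL_H2
    p_ch4 = max(y[c.G_CH4], 0.0) * r_t / c.COD_MOL_CH4
    p_co2 = max(y[c.G_CO2], 0.0) * r_t
    s_co2 = max(y[c.S_IC], 0.0) * sh / (sh + kin[KIN_KA_CO2])
    kla = kin[KIN_KLA]
    rt_h2 = kla * (y[c.S_H2] - c.COD_MOL_H2 * kin[KIN_KH_H2] * p_h2)
    rt_ch4 = kla * (y[c.S_CH4] - c.COD_MOL_CH4 * kin[KIN_KH_CH4] * p_ch4)
    rt_co2 = kla * (s_co2 - kin[KIN_KH_CO2] * p_co2)
    dy[c.S_H2] -= rt_h2
    dy[c.S_CH4] -= rt_ch4
    dy[c.S_IC] -= rt_co2

    # vent flow keeping headspace at atmospheric pressure (m3 d-1)
    q_gas = (r_t / (kin[KIN_P_ATM] - kin[KIN_P_H2O]) * v_liq
             * (rt_h2 / c.COD_MOL_H2 + rt_ch4 / c.COD_MOL_CH4 + rt_co2))
    if q_gas < 0.0:
        q_gas = 0.0

    dy[c.G_H2] = -y[c.G_H2] * q_gas / v_gas + rt_h2 * v_liq / v_gas
    dy[c.G_CH4] = -y[c.G_CH4] * q_gas / v_gas + rt_ch4 * v_liq / v_gas
    dy[c.G_CO2] = -y[c.G_CO2] * q_gas / v_gas + rt_co2 * v_liq / v_gas

    # hydraulic flow-through on the liquid phase
    if q > 0.0:
        d = q / v_liq
        for i in range(c.S_AN + 1):
            dy[i] += d * (y_in[i] - y[i])

    # ledgers
    dy[c.L_CH4] = q_gas * max(y[c.G_CH4], 0.0) / c.COD_MOL_CH4
    dy[c.L_H2] = q_gas * max(y[c.G_H2], 0.0) / c.COD_MOL_H2
    dy[c.L_CO2] = q_gas * max(y[c.G_CO2], 0.0)
    cod = 0.0
    for i in _LIQ_COD:
        cod += max(y[i], 0.0)
    dy[c.L_EFF_COD] = q * cod
    return dy
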