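"""Stoichiometry of the 19 biochemical processes (the Petersen matrix).

Rows are processes (disintegration, 3 hydrolyses, 7 uptakes, 7 decays),
columns the core liquid states.  Inorganic carbon and nitrogen columns are
closed algebraically so that every process conserves carbon and nitrogen to
machine precision; COD conservation is structural (yields and product
fractions sum to one).
"""

from __future__ import annotations

import numpy as np

from . import constants as c
from .params import AdmParams

N_PROC = 19

# process row indices
P_DIS = 0
P_HYD_CH = 1
P_HYD_PR = 2
P_HYD_LI = 3
P_UP_SU = 4
P_UP_AA = 5
P_UP_FA = 6
P_UP_VA = 7
P_UP_BU = 8
P_UP_PRO = 9
P_UP_AC = 10
P_UP_H2 = 11
P_DEC = 12  # 12..18 decay of X_su..X_h2

PROCESS_NAMES = [
    "disintegration", "hydrolysis_ch", "hydrolysis_pr", "hydrolysis_li",
    "uptake_su", "uptake_aa", "uptake_fa", "uptake_va", "uptake_bu",
    "uptake_pro", "uptake_ac", "uptake_h2",
    "decay_X_su", "decay_X_aa", "decay_X_fa", "decay_X_c4", "decay_X_pro",
    "decay_X_ac", "decay_X_h2",
]

BIOMASS_IDX = [c.X_SU, c.X_AA, c.X_FA, c.X_C4, c.X_PRO, c.X_AC, c.X_H2]


def composite_carbon(p: AdmParams) -> float:
    """kmol C per kgCOD of composite particulates, from its split."""
    return (p.f_si * c.C_SI + p.f_xi * c.C_XI + p.f_ch * c.C_CH
            + p.f_pr * c.C_PR + p.f_li * c.C_LI)


def composite_nitrogen(p: AdmParams) -> float:
    """kmol N per kgCOD of composite particulates, from its split."""
    return (p.f_si + p.f_xi) * c.N_I + p.f_pr * c.N_AA


def build_stoichiometry(p: AdmParams) -> np.ndarray:
    """The (19, N_CORE) stoichiometric matrix nu for the given parameters."""
    nu = np.zeros((N_PROC, c.N_CORE))

    # disintegration: X_c -> inerts + macromolecules
    nu[P_DIS, c.X_C] = -1.0
    nu[P_DIS, c.S_I] = p.f_si
    nu[P_DIS, c.X_I] = p.f_xi
    nu[P_DIS, c.X_CH] = p.f_ch
    nu[P_DIS, c.X_PR] = p.f_pr
    nu[P_DIS, c.X_LI] = p.f_li

    # hydrolyses
    nu[P_HYD_CH, c.X_CH] = -1.0
    nu[P_HYD_CH, c.S_SU] = 1.0
    nu[P_HYD_PR, c.X_PR] = -1.0
    nu[P_HYD_PR, c.S_AA] = 1.0
    nu[P_HYD_LI, c.X_LI] = -1.0
    nu[P_HYD_LI, c.S_FA] = p.f_fa_li
    nu[P_HYD_LI, c.S_SU] = 1.0 - p.f_fa_li

    # sugar uptake
    nu[P_UP_SU, c.S_SU] = -1.0
    nu[P_UP_SU, c.X_SU] = p.Y_su
    rem = 1.0 - p.Y_su
    nu[P_UP_SU, c.S_BU] = rem * p.f_bu_su
    nu[P_UP_SU, c.S_PRO] = rem * p.f_pro_su
    nu[P_UP_SU, c.S_AC] = rem * p.f_ac_su
    nu[P_UP_SU, c.S_H2] = rem * p.f_h2_su

    # amino-acid uptake
    nu[P_UP_AA, c.S_AA] = -1.0
    nu[P_UP_AA, c.X_AA] = p.Y_aa
    rem = 1.0 - p.Y_aa
    nu[P_UP_AA, c.S_VA] = rem * p.f_va_aa
    nu[P_UP_AA, c.S_BU] = rem * p.f_bu_aa
    nu[P_UP_AA, c.S_PRO] = rem * p.f_pro_aa
    nu[P_UP_AA, c.S_AC] = rem * p.f_ac_aa
    nu[P_UP_AA, c.S_H2] = rem * p.f_h2_aa

    # LCFA uptake
    nu[P_UP_FA, c.S_FA] = -1.0
    nu[P_UP_FA, c.X_FA] = p.Y_fa
    nu[P_UP_FA, c.S_AC] = (1.0 - p.Y_fa) * 0.7
    nu[P_UP_FA, c.S_H2] = (1.0 - p.Y_fa) * 0.3

    # valerate uptake
    nu[P_UP_VA, c.S_VA] = -1.0
    nu[P_UP_VA, c.X_C4] = p.Y_c4
    rem = 1.0 - p.Y_c4
    nu[P_UP_VA, c.S_PRO] = rem * 0.54
    nu[P_UP_VA, c.S_AC] = rem * 0.31
    nu[P_UP_VA, c.S_H2] = rem * 0.15

    # butyrate uptake
    nu[P_UP_BU, c.S_BU] = -1.0
    nu[P_UP_BU, c.X_C4] = p.Y_c4
    rem = 1.0 - p.Y_c4
    nu[P_UP_BU, c.S_AC] = rem * 0.8
    nu[P_UP_BU, c.S_H2] = rem * 0.2

    # propionate uptake
    nu[P_UP_PRO, c.S_PRO] = -1.0
    nu[P_UP_PRO, c.X_PRO] = p.Y_pro
    rem = 1.0 - p.Y_pro
    nu[P_UP_PRO, c.S_AC] = rem * 0.57
    nu[P_UP_PRO, c.S_H2] = rem * 0.43

    # acetoclastic methanogenesis
    nu[P_UP_AC, c.S_AC] = -1.0
    nu[P_UP_AC, c.X_AC] = p.Y_ac
    nu[P_UP_AC, c.S_CH4] = 1.0 - p.Y_ac

    # hydrogenotrophic methanogenesis
    nu[P_UP_H2, c.S_H2] = -1.0
    nu[P_UP_H2, c.X_H2] = p.Y_h2
    nu[P_UP_H2, c.S_CH4] = 1.0 - p.Y_h2

    # decays: X_i -> X_c
    for j, xi in enumerate(BIOMASS_IDX):
        nu[P_DEC + j, xi] = -1.0
        nu[P_DEC + j, c.X_C] = 1.0

    # close inorganic carbon and nitrogen per process
    cvec = c.carbon_vector()
    nvec = c.nitrogen_vector()
    cvec[c.X_C] = composite_carbon(p)
    nvec[c.X_C] = composite_nitrogen(p)
    cvec[c.S_IC] = 0.0
    nvec[c.S_IN] = 0.0
    nu[:, c.S_IC] = -nu @ cvec
    nu[:, c.S_IN] = -nu @ nvec
    return nu


def composition_vectors(p: AdmParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(COD, carbon, nitrogen) content per unit of each core state."""
    cod = c.COD_CONTENT.copy()
    cvec = c.carbon_vector()
    nvec = c.nitrogen_vector()
    cvec[c.X_C] = composite_carbon(p)
    nvec[c.X_C] = composite_nitrogen(p)
    return cod, cvec, nvec
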