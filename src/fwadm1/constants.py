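"""State-vector layout and elemental composition constants for the digester model.

The liquid phase carries 12 soluble and 12 particulate COD/nutrient variables,
two strong-ion pools and three headspace gas concentrations.  Four extra
"ledger" slots accumulate gas moles and effluent COD so that every simulation
can close its own COD mass balance.

Units: COD species kgCOD m-3 (== g/L), inorganic carbon/nitrogen and ions
kmol m-3, time in days.
"""

from __future__ import annotations

import numpy as np

# --- liquid soluble ---
S_SU = 0    # monosaccharides
S_AA = 1    # amino acids
S_FA = 2    # long-chain fatty acids
S_VA = 3    # total valerate
S_BU = 4    # total butyrate
S_PRO = 5   # total propionate
S_AC = 6    # total acetate
S_H2 = 7    # dissolved hydrogen
S_CH4 = 8   # dissolved methane
S_IC = 9    # inorganic carbon (kmol C m-3)
S_IN = 10   # inorganic nitrogen (kmol N m-3)
S_I = 11    # soluble inerts

# --- liquid particulate ---
X_C = 12    # composite particulates
X_CH = 13   # carbohydrates
X_PR = 14   # proteins
X_LI = 15   # lipids
X_SU = 16   # sugar degraders
X_AA = 17   # amino-acid degraders
X_FA = 18   # LCFA degraders
X_C4 = 19   # valerate/butyrate degraders
X_PRO = 20  # propionate degraders
X_AC = 21   # acetoclastic methanogens
X_H2 = 22   # hydrogenotrophic methanogens
X_I = 23    # particulate inerts

# --- strong ions ---
S_CAT = 24  # metallic cations (kmol m-3)
S_AN = 25   # strong anions (kmol m-3)

# --- gas phase ---
G_H2 = 26   # headspace H2 (kgCOD m-3)
G_CH4 = 27  # headspace CH4 (kgCOD m-3)
G_CO2 = 28  # headspace CO2 (kmol m-3)

N_CORE = 29

# --- cumulative ledgers (not concentrations) ---
L_CH4 = 29      # kmol CH4 vented
L_H2 = 30       # kmol H2 vented
L_CO2 = 31      # kmol CO2 vented
L_EFF_COD = 32  # kg COD withdrawn with continuous effluent

N_STATE = 33

STATE_NAMES = [
    "S_su", "S_aa", "S_fa", "S_va", "S_bu", "S_pro", "S_ac", "S_h2",
    "S_ch4", "S_IC", "S_IN", "S_I", "X_c", "X_ch", "X_pr", "X_li",
    "X_su", "X_aa", "X_fa", "X_c4", "X_pro", "X_ac", "X_h2", "X_I",
    "S_cat", "S_an", "S_gas_h2", "S_gas_ch4", "S_gas_co2",
    "cum_gas_ch4", "cum_gas_h2", "cum_gas_co2", "cum_eff_cod",
]

STATE_UNITS = (
    ["kgCOD/m3"] * 9 + ["kmol/m3"] * 2 + ["kgCOD/m3"] * 13
    + ["kmol/m3"] * 2 + ["kgCOD/m3", "kgCOD/m3", "kmol/m3"]
    + ["kmol", "kmol", "kmol", "kgCOD"]
)

SOLUBLE_COD_IDX = np.array([S_SU, S_AA, S_FA, S_VA, S_BU, S_PRO, S_AC,
                            S_H2, S_CH4, S_I])
PARTICULATE_COD_IDX = np.array([X_C, X_CH, X_PR, X_LI, X_SU, X_AA, X_FA,
                                X_C4, X_PRO, X_AC, X_H2, X_I])
VFA_COD_IDX = np.array([S_VA, S_BU, S_PRO, S_AC])

#: 1 where a liquid state carries COD, 0 for the inorganic pools.
COD_CONTENT = np.zeros(N_CORE)
COD_CONTENT[list(SOLUBLE_COD_IDX) + list(PARTICULATE_COD_IDX)] = 1.0
COD_CONTENT[[G_H2, G_CH4]] = 1.0  # headspace H2/CH4 are stored as COD

#: liquid-phase-only COD mask (headspace states excluded)
LIQ_COD_MASK = COD_CONTENT.copy()
LIQ_COD_MASK[[G_H2, G_CH4]] = 0.0

# molar COD equivalents (kgCOD per kmol) used for ion charge arithmetic
COD_MOL_VA = 208.0
COD_MOL_BU = 160.0
COD_MOL_PRO = 112.0
COD_MOL_AC = 64.0
COD_MOL_CH4 = 64.0
COD_MOL_H2 = 16.0

# carbon content, kmol C per kgCOD (per kmol for S_IC itself)
C_SU = 0.0313
C_AA = 0.03
C_FA = 0.0217
C_VA = 0.024
C_BU = 0.025
C_PRO = 0.0268
C_AC = 0.0313
C_CH4 = 0.0156
C_SI = 0.03
C_CH = 0.0313
C_PR = 0.03
C_LI = 0.022
C_XI = 0.03
C_BAC = 0.0313

# nitrogen content, kmol N per kgCOD
N_AA = 0.007      # amino acids / proteins
N_BAC = 0.08 / 14.0   # biomass
N_I = 0.06 / 14.0     # inert organics

# gas / physical constants
R_BAR = 0.083145       # bar m3 kmol-1 K-1
T_STD = 273.15         # K, gas normalisation temperature (0 degC)
P_STD = 1.013          # bar, 1 atm
V_MOLAR_STD = 22.414   # Nm3 per kmol ideal gas at 0 degC, 1 atm
NL_PER_KMOL = V_MOLAR_STD * 1000.0

#: theoretical methane yield of COD: 1 g COD == 350 NmL CH4
NL_CH4_PER_KGCOD = NL_PER_KMOL / COD_MOL_CH4  # ~350.2 NL per kg COD


def carbon_vector() -> np.ndarray:
    """kmol C per unit of each core state (per kgCOD, or per kmol for S_IC)."""
    c = np.zeros(N_CORE)
    c[[S_SU, S_AA, S_FA, S_VA, S_BU, S_PRO, S_AC, S_CH4]] = [
        C_SU, C_AA, C_FA, C_VA, C_BU, C_PRO, C_AC, C_CH4]
    c[S_IC] = 1.0
    c[S_I] = C_SI
    c[[X_CH, X_PR, X_LI, X_I]] = [C_CH, C_PR, C_LI, C_XI]
    c[[X_SU, X_AA, X_FA, X_C4, X_PRO, X_AC, X_H2]] = C_BAC
    # X_c carbon is composition dependent; petersen.build_stoichiometry fills it
    return c


def nitrogen_vector() -> np.ndarray:
    """kmol N per unit of each core state (per kmol for S_IN)."""
    n = np.zeros(N_CORE)
    n[S_AA] = N_AA
    n[S_IN] = 1.0
    n[S_I] = N_I
    n[X_PR] = N_AA
    n[X_I] = N_I
    n[[X_SU, X_AA, X_FA, X_C4, X_PRO, X_AC, X_H2]] = N_BAC
    # X_c nitrogen is composition dependent; see petersen.build_stoichiometry
    return n
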