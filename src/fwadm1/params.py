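"""ADM1 parameter set: stoichiometric fractions, kinetics, physico-chemistry.

Defaults are the standard mesophilic benchmark values of the IWA model as
used in the BSM2 reference implementation; acid-base, water and Henry
constants are re-evaluated at the operating temperature by van 't Hoff from
their 25 degC values.  The composite-split fractions (f_ch/f_pr/f_li/f_xI/f_sI)
are normally overwritten by the feed fractionation step.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

# indices into the packed kinetic/physico-chemical array handed to the
# compiled right-hand side
KIN_K_DIS = 0
KIN_KHYD_CH = 1
KIN_KHYD_PR = 2
KIN_KHYD_LI = 3
KIN_KM_SU = 4
KIN_KS_SU = 5
KIN_KM_AA = 6
KIN_KS_AA = 7
KIN_KM_FA = 8
KIN_KS_FA = 9
KIN_KIH2_FA = 10
KIN_KM_C4 = 11
KIN_KS_C4 = 12
KIN_KIH2_C4 = 13
KIN_KM_PRO = 14
KIN_KS_PRO = 15
KIN_KIH2_PRO = 16
KIN_KM_AC = 17
KIN_KS_AC = 18
KIN_KI_NH3 = 19
KIN_KM_H2 = 20
KIN_KS_H2 = 21
KIN_KDEC = 22          # 7 slots, X_su .. X_h2
KIN_KS_IN = 29
KIN_PHUL_AA = 30
KIN_PHLL_AA = 31
KIN_PHUL_AC = 32
KIN_PHLL_AC = 33
KIN_PHUL_H2 = 34
KIN_PHLL_H2 = 35
KIN_KA_VA = 36
KIN_KA_BU = 37
KIN_KA_PRO = 38
KIN_KA_AC = 39
KIN_KA_CO2 = 40
KIN_KA_IN = 41
KIN_KW = 42
KIN_KLA = 43
KIN_KH_H2 = 44
KIN_KH_CH4 = 45
KIN_KH_CO2 = 46
KIN_P_ATM = 47
KIN_P_H2O = 48
KIN_T_OP = 49
N_KIN = 50

R_J = 8.314      # J mol-1 K-1
T_BASE = 298.15  # K

T_MIN = 273.0
T_MAX = 344.0


def _vant_hoff(k_base: float, delta_h: float, temperature: float) -> float:
    """Equilibrium constant at `temperature` from its 25 degC value."""
    return k_base * math.exp((delta_h / R_J) * (1.0 / T_BASE - 1.0 / temperature))


@dataclass
class AdmParams:
    """Full parameter set of the digestion model.

    Rates in d-1, half-saturations in kgCOD m-3 (kmol m-3 for nitrogen),
    temperature in K.  Composite-split fractions must sum to one.
    """

    temperature: float = 310.15

    # composite disintegration split (dimensionless, sum to 1)
    f_si: float = 0.1
    f_xi: float = 0.2
    f_ch: float = 0.2
    f_pr: float = 0.2
    f_li: float = 0.3

    # product distribution fractions
    f_fa_li: float = 0.95
    f_h2_su: float = 0.19
    f_bu_su: float = 0.13
    f_pro_su: float = 0.27
    f_ac_su: float = 0.41
    f_h2_aa: float = 0.06
    f_va_aa: float = 0.23
    f_bu_aa: float = 0.26
    f_pro_aa: float = 0.05
    f_ac_aa: float = 0.40

    # yields (kgCOD biomass per kgCOD substrate)
    Y_su: float = 0.10
    Y_aa: float = 0.08
    Y_fa: float = 0.06
    Y_c4: float = 0.06
    Y_pro: float = 0.04
    Y_ac: float = 0.05
    Y_h2: float = 0.06

    # first-order constants (d-1)
    k_dis: float = 0.5
    k_hyd_ch: float = 10.0
    k_hyd_pr: float = 10.0
    k_hyd_li: float = 10.0

    # Monod maxima (d-1) and half-saturations (kgCOD m-3)
    k_m_su: float = 30.0
    K_S_su: float = 0.5
    k_m_aa: float = 50.0
    K_S_aa: float = 0.3
    k_m_fa: float = 6.0
    K_S_fa: float = 0.4
    k_m_c4: float = 20.0
    K_S_c4: float = 0.2
    k_m_pro: float = 13.0
    K_S_pro: float = 0.1
    k_m_ac: float = 8.0
    K_S_ac: float = 0.15
    k_m_h2: float = 35.0
    K_S_h2: float = 7e-6

    # decay constants (d-1), one per biomass group
    k_dec_su: float = 0.02
    k_dec_aa: float = 0.02
    k_dec_fa: float = 0.02
    k_dec_c4: float = 0.02
    k_dec_pro: float = 0.02
    k_dec_ac: float = 0.02
    k_dec_h2: float = 0.02

    # inhibition
    K_S_IN: float = 1e-4        # kmol N m-3, nitrogen limitation
    K_I_h2_fa: float = 5e-6     # kgCOD m-3
    K_I_h2_c4: float = 1e-5
    K_I_h2_pro: float = 3.5e-6
    K_I_nh3: float = 0.0018     # kmol N m-3, free ammonia on acetoclasts
    pH_UL_aa: float = 5.5
    pH_LL_aa: float = 4.0
    pH_UL_ac: float = 7.0
    pH_LL_ac: float = 6.0
    pH_UL_h2: float = 6.0
    pH_LL_h2: float = 5.0

    # VFA acid-base constants (temperature-independent, kmol m-3)
    K_a_va: float = 10 ** -4.86
    K_a_bu: float = 10 ** -4.82
    K_a_pro: float = 10 ** -4.88
    K_a_ac: float = 10 ** -4.76

    # gas phase
    k_La: float = 200.0    # d-1
    p_atm: float = 1.013   # bar

    # temperature-adjusted physico-chemistry (filled in __post_init__)
    K_a_co2: float = field(default=0.0)
    K_a_IN: float = field(default=0.0)
    K_w: float = field(default=0.0)
    K_H_h2: float = field(default=0.0)   # kmol m-3 bar-1
    K_H_ch4: float = field(default=0.0)
    K_H_co2: float = field(default=0.0)
    p_h2o: float = field(default=0.0)    # bar

    def __post_init__(self) -> None:
        if not (T_MIN < self.temperature < T_MAX):
            raise ValueError(
                f"temperature {self.temperature} K outside the supported "
                f"liquid-water range ({T_MIN}, {T_MAX}) K")
        self.refresh_temperature_constants()
        self.validate()

    def refresh_temperature_constants(self) -> None:
        t = self.temperature
        self.K_a_co2 = _vant_hoff(10 ** -6.35, 7646.0, t)
        self.K_a_IN = _vant_hoff(10 ** -9.25, 51965.0, t)
        self.K_w = _vant_hoff(1e-14, 55900.0, t)
        self.K_H_h2 = _vant_hoff(7.8e-4, -4180.0, t)
        self.K_H_ch4 = _vant_hoff(1.4e-3, -14240.0, t)
        self.K_H_co2 = _vant_hoff(3.5e-2, -19410.0, t)
        self.p_h2o = 0.0313 * math.exp(5290.0 * (1.0 / T_BASE - 1.0 / t))

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        s = self.f_si + self.f_xi + self.f_ch + self.f_pr + self.f_li
        if abs(s - 1.0) > 1e-12:
            raise ValueError(f"composite split fractions sum to {s!r}, not 1")
        for name in ("k_dis", "k_hyd_ch", "k_hyd_pr", "k_hyd_li", "k_m_su",
                     "k_m_aa", "k_m_fa", "k_m_c4", "k_m_pro", "k_m_ac",
                     "k_m_h2", "k_La"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0")
        for name in ("Y_su", "Y_aa", "Y_fa", "Y_c4", "Y_pro", "Y_ac", "Y_h2"):
            y = getattr(self, name)
            if not (0.0 < y < 1.0):
                raise ValueError(f"yield {name}={y} outside (0, 1)")

    def set_composite_split(self, *, f_si: float, f_xi: float, f_ch: float,
                            f_pr: float, f_li: float) -> None:
        """Overwrite the disintegration split (renormalised to sum 1)."""
        total = f_si + f_xi + f_ch + f_pr + f_li
        if total <= 0:
            raise ValueError("composite split fractions must sum to > 0")
        self.f_si, self.f_xi = f_si / total, f_xi / total
        self.f_ch, self.f_pr, self.f_li = (f_ch / total, f_pr / total,
                                           f_li / total)

    # -- packing ----------------------------------------------------------
    def kinetic_array(self) -> np.ndarray:
        """Pack the rate/physico-chemical constants for the compiled RHS."""
        k = np.zeros(N_KIN)
        k[KIN_K_DIS] = self.k_dis
        k[KIN_KHYD_CH] = self.k_hyd_ch
        k[KIN_KHYD_PR] = self.k_hyd_pr
        k[KIN_KHYD_LI] = self.k_hyd_li
        k[KIN_KM_SU] = self.k_m_su
        k[KIN_KS_SU] = self.K_S_su
        k[KIN_KM_AA] = self.k_m_aa
        k[KIN_KS_AA] = self.K_S_aa
        k[KIN_KM_FA] = self.k_m_fa
        k[KIN_KS_FA] = self.K_S_fa
        k[KIN_KIH2_FA] = self.K_I_h2_fa
        k[KIN_KM_C4] = self.k_m_c4
        k[KIN_KS_C4] = self.K_S_c4
        k[KIN_KIH2_C4] = self.K_I_h2_c4
        k[KIN_KM_PRO] = self.k_m_pro
        k[KIN_KS_PRO] = self.K_S_pro
        k[KIN_KIH2_PRO] = self.K_I_h2_pro
        k[KIN_KM_AC] = self.k_m_ac
        k[KIN_KS_AC] = self.K_S_ac
        k[KIN_KI_NH3] = self.K_I_nh3
        k[KIN_KM_H2] = self.k_m_h2
        k[KIN_KS_H2] = self.K_S_h2
        k[KIN_KDEC:KIN_KDEC + 7] = [self.k_dec_su, self.k_dec_aa,
                                    self.k_dec_fa, self.k_dec_c4,
                                    self.k_dec_pro, self.k_dec_ac,
                                    self.k_dec_h2]
        k[KIN_KS_IN] = self.K_S_IN
        k[KIN_PHUL_AA] = self.pH_UL_aa
        k[KIN_PHLL_AA] = self.pH_LL_aa
        k[KIN_PHUL_AC] = self.pH_UL_ac
        k[KIN_PHLL_AC] = self.pH_LL_ac
        k[KIN_PHUL_H2] = self.pH_UL_h2
        k[KIN_PHLL_H2] = self.pH_LL_h2
        k[KIN_KA_VA] = self.K_a_va
        k[KIN_KA_BU] = self.K_a_bu
        k[KIN_KA_PRO] = self.K_a_pro
        k[KIN_KA_AC] = self.K_a_ac
        k[KIN_KA_CO2] = self.K_a_co2
        k[KIN_KA_IN] = self.K_a_IN
        k[KIN_KW] = self.K_w
        k[KIN_KLA] = self.k_La
        k[KIN_KH_H2] = self.K_H_h2
        k[KIN_KH_CH4] = self.K_H_ch4
        k[KIN_KH_CO2] = self.K_H_co2
        k[KIN_P_ATM] = self.p_atm
        k[KIN_P_H2O] = self.p_h2o
        k[KIN_T_OP] = self.temperature
        return k

    # -- serialisation ----------------------------------------------------
    def replace(self, **changes) -> "AdmParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AdmParams":
        raw = yaml.safe_load(Path(path).read_text())
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in raw.items() if k in names})


def default_params(temperature: float = 310.15) -> AdmParams:
    """The benchmark mesophilic parameter set at the given temperature (K)."""
    return AdmParams(temperature=temperature)
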