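"""The digester state vector and its named, validated wrapper."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants as c


@dataclass
class AdmState:
    """Named view over the 29 concentration states (+4 ledger slots).

    Soluble/particulate COD species in kgCOD m-3, inorganic carbon/nitrogen
    and strong ions in kmol m-3, headspace H2/CH4 as kgCOD m-3 and CO2 as
    kmol m-3.
    """

    values: np.ndarray = field(
        default_factory=lambda: np.zeros(c.N_STATE))

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape == (c.N_CORE,):
            v = np.concatenate([v, np.zeros(c.N_STATE - c.N_CORE)])
        if v.shape != (c.N_STATE,):
            raise ValueError(
                f"state vector must have {c.N_CORE} or {c.N_STATE} entries, "
                f"got shape {v.shape}")
        self.values = v

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "AdmState":
        v = np.zeros(c.N_STATE)
        for name, val in mapping.items():
            try:
                v[c.STATE_NAMES.index(name)] = val
            except ValueError:
                raise KeyError(f"unknown state variable {name!r}") from None
        return cls(v)

    def get(self, name: str) -> float:
        return float(self.values[c.STATE_NAMES.index(name)])

    def set(self, name: str, value: float) -> None:
        self.values[c.STATE_NAMES.index(name)] = value

    def copy(self) -> "AdmState":
        return AdmState(self.values.copy())

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=c.STATE_NAMES)

    # -- aggregates -------------------------------------------------------
    @property
    def soluble_cod(self) -> float:
        """Soluble COD (g/L) excluding dissolved gases, as assayed."""
        idx = [c.S_SU, c.S_AA, c.S_FA, c.S_VA, c.S_BU, c.S_PRO, c.S_AC, c.S_I]
        return float(self.values[idx].sum())

    @property
    def vfa_cod(self) -> float:
        return float(self.values[c.VFA_COD_IDX].sum())

    @property
    def total_cod(self) -> float:
        """Liquid-phase total COD concentration (g/L)."""
        idx = list(c.SOLUBLE_COD_IDX) + list(c.PARTICULATE_COD_IDX)
        return float(self.values[idx].sum())

    # -- validation -------------------------------------------------------
    def validate(self, tol: float = 1e-10) -> None:
        v = self.values
        if not np.all(np.isfinite(v)):
            bad = [c.STATE_NAMES[i] for i in np.where(~np.isfinite(v))[0]]
            raise ValueError(f"non-finite state entries: {bad}")
        if np.any(v[:c.N_CORE] < -tol):
            bad = [c.STATE_NAMES[i]
                   for i in np.where(v[:c.N_CORE] < -tol)[0]]
            raise ValueError(f"negative concentrations: {bad}")

    # -- persistence ------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"variable": c.STATE_NAMES,
                           "value": self.values,
                           "unit": c.STATE_UNITS})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AdmState":
        df = pd.read_csv(path)
        for col in ("variable", "value"):
            if col not in df.columns:
                raise ValueError(f"state CSV missing column {col!r}")
        return cls.from_dict(dict(zip(df["variable"], df["value"])))


def default_inoculum() -> AdmState:
    """A typical mesophilic digested-sludge state used to seed simulations.

    Concentrations are in the range of a steadily operating municipal
    digester (the experimental inocula came from one); the spin-up period of
    the reactor runs acclimates it to the actual feed.
    """
    s = AdmState()
    v = s.values
    v[c.S_SU] = 0.012
    v[c.S_AA] = 0.005
    v[c.S_FA] = 0.099
    v[c.S_VA] = 0.012
    v[c.S_BU] = 0.013
    v[c.S_PRO] = 0.016
    v[c.S_AC] = 0.20
    v[c.S_H2] = 2.4e-7
    v[c.S_CH4] = 0.055
    v[c.S_IC] = 0.09
    v[c.S_IN] = 0.07
    v[c.S_I] = 0.33
    v[c.X_C] = 0.31
    v[c.X_CH] = 0.028
    v[c.X_PR] = 0.10
    v[c.X_LI] = 0.029
    v[c.X_SU] = 0.42
    v[c.X_AA] = 1.18
    v[c.X_FA] = 0.24
    v[c.X_C4] = 0.43
    v[c.X_PRO] = 0.14
    v[c.X_AC] = 0.76
    v[c.X_H2] = 0.32
    v[c.X_I] = 12.0
    v[c.S_CAT] = 0.04
    v[c.S_AN] = 0.02
    v[c.G_H2] = 1.0e-5
    v[c.G_CH4] = 1.6
    v[c.G_CO2] = 0.014
    return s
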