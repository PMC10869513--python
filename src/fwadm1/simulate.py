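"""Stiff integration of the digester ODEs with pulse-feed discontinuities.

Feeding is an instantaneous equal-volume exchange (withdraw mixed liquor,
add feed, liquid volume constant); the integrator performs a hard restart at
every event.  A COD ledger is accumulated across the run so that any
simulation can audit its own mass balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import constants as c
from .kinetics import rates_given_sh, rhs, solve_sh
from .params import AdmParams
from .petersen import PROCESS_NAMES, build_stoichiometry
from .states import AdmState

__all__ = [
    "ProcessRates", "SimulationResult", "SolverFailure", "solve_ph",
    "process_rates", "derivatives", "integrate",
]


class SolverFailure(RuntimeError):
    """Integration failed; carries the last successful time and state."""

    def __init__(self, message: str, t_last: float, y_last: np.ndarray):
        super().__init__(message)
        self.t_last = t_last
        self.y_last = y_last


@dataclass
class ProcessRates:
    """The 19 biochemical process rates (kgCOD m-3 d-1 basis)."""

    rho: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.shape != (19,):
            raise ValueError("expected 19 process rates")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(PROCESS_NAMES, self.rho))

    def __getitem__(self, name: str) -> float:
        return float(self.rho[PROCESS_NAMES.index(name)])


def solve_ph(state: AdmState, params: AdmParams) -> float:
    """pH from the electroneutrality balance (residual < 1e-12 kmol m-3)."""
    state.validate()
    sh = solve_sh(state.values, params.kinetic_array())
    return float(-np.log10(sh))


def process_rates(state: AdmState, params: AdmParams,
                  ph: float | None = None) -> ProcessRates:
    """First-order/Monod process rates with the standard inhibition terms."""
    state.validate()
    kin = params.kinetic_array()
    if ph is None:
        sh = solve_sh(state.values, kin)
    else:
        if not (0.0 < ph < 14.0):
            raise ValueError(f"pH {ph} outside (0, 14)")
        sh = 10.0 ** (-ph)
    rho = rates_given_sh(state.values, kin, sh)
    if not np.all(np.isfinite(rho)):
        raise ValueError("non-finite process rate encountered")
    return ProcessRates(rho)


def derivatives(t: float, state: AdmState, feed: np.ndarray, flow: float,
                volume: float, params: AdmParams,
                headspace: float | None = None) -> np.ndarray:
    """Right-hand side dC/dt at one instant (flow in m3/d, volume in m3)."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    if flow < 0:
        raise ValueError("flow must be >= 0 (0 encodes batch operation)")
    state.validate()
    feed = np.asarray(feed, dtype=float)
    if feed.shape[0] < c.N_CORE:
        raise ValueError(
            f"feed vector must cover the {c.N_CORE} core states")
    nu_t = np.ascontiguousarray(build_stoichiometry(params).T)
    v_gas = headspace if headspace is not None else 0.3 * volume
    return rhs(t, state.values, nu_t, params.kinetic_array(),
               feed[:c.N_CORE], flow, volume, v_gas)


@dataclass
class SimulationResult:
    """Dense trajectory plus normalized-gas and COD bookkeeping.

    `t` is in days relative to the start of the *reported* period (spin-up,
    if any, has negative times removed by the caller); ledger columns of `y`
    accumulate vented gas (kmol) and continuous-effluent COD (kg).
    """

    t: np.ndarray
    y: np.ndarray                    # (n_times, N_STATE)
    params: AdmParams
    v_liq: float                     # m3
    v_gas: float                     # m3
    cod_ledger: dict = field(default_factory=dict)
    vs_fed_daily: np.ndarray | None = None   # kg VS per calendar day
    meta: dict = field(default_factory=dict)

    # -- series -----------------------------------------------------------
    def state_at(self, i: int) -> AdmState:
        return AdmState(self.y[i].copy())

    def final_state(self) -> AdmState:
        return self.state_at(-1)

    def ph_series(self) -> np.ndarray:
        kin = self.params.kinetic_array()
        return np.array([-np.log10(solve_sh(row, kin)) for row in self.y])

    def soluble_cod_series(self) -> np.ndarray:
        idx = [c.S_SU, c.S_AA, c.S_FA, c.S_VA, c.S_BU, c.S_PRO, c.S_AC, c.S_I]
        return self.y[:, idx].sum(axis=1)

    def vfa_series(self) -> np.ndarray:
        return self.y[:, c.VFA_COD_IDX].sum(axis=1)

    def cumulative_methane_nl(self) -> np.ndarray:
        """Cumulative vented CH4 in NL (0 degC, 1 atm) on the output grid."""
        return self.y[:, c.L_CH4] * c.NL_PER_KMOL

    def _daily_cumulative(self, col: int) -> np.ndarray:
        n_days = int(round(self.t[-1] - self.t[0]))
        edges = self.t[0] + np.arange(n_days + 1)
        cum = np.interp(edges, self.t, self.y[:, col])
        return cum

    def daily_methane_nl(self) -> np.ndarray:
        """CH4 volume per calendar day, NL/d at 0 degC and 1 atm."""
        cum = self._daily_cumulative(c.L_CH4) * c.NL_PER_KMOL
        return np.diff(cum)

    def daily_gas_nl(self) -> dict[str, np.ndarray]:
        return {
            "ch4": np.diff(self._daily_cumulative(c.L_CH4)) * c.NL_PER_KMOL,
            "h2": np.diff(self._daily_cumulative(c.L_H2)) * c.NL_PER_KMOL,
            "co2": np.diff(self._daily_cumulative(c.L_CO2)) * c.NL_PER_KMOL,
        }

    # -- mass balance ------------------------------------------------------
    def cod_balance(self) -> dict[str, float]:
        """COD ledger of the run (kg); `closure` is the relative residual."""
        led = dict(self.cod_ledger)
        gas_out = (self.y[-1, c.L_CH4] - self.y[0, c.L_CH4]) * c.COD_MOL_CH4 \
            + (self.y[-1, c.L_H2] - self.y[0, c.L_H2]) * c.COD_MOL_H2
        eff_cont = self.y[-1, c.L_EFF_COD] - self.y[0, c.L_EFF_COD]
        liq1 = float(self.y[-1, :c.N_CORE] @ c.LIQ_COD_MASK) * self.v_liq
        gas1 = (self.y[-1, c.G_H2] + self.y[-1, c.G_CH4]) * self.v_gas
        if "cod_initial" in led:
            inv0 = led["cod_initial"]
        else:
            liq0 = float(self.y[0, :c.N_CORE] @ c.LIQ_COD_MASK) * self.v_liq
            gas0 = (self.y[0, c.G_H2] + self.y[0, c.G_CH4]) * self.v_gas
            inv0 = liq0 + gas0
        inv1 = liq1 + gas1
        cod_in = led.get("cod_in", 0.0)
        eff_pulse = led.get("cod_out_pulse", 0.0)
        out = gas_out + eff_cont + eff_pulse
        residual = (inv0 + cod_in) - (inv1 + out)
        basis = max(cod_in + inv0, 1e-12)
        return {"initial": inv0, "fed": cod_in, "final": inv1,
                "gas_out": gas_out, "effluent": eff_cont + eff_pulse,
                "residual": residual, "closure": abs(residual) / basis}

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd
        df = pd.DataFrame(self.y, columns=c.STATE_NAMES)
        df.insert(0, "time_d", self.t)
        return df

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        days = np.arange(len(self.daily_methane_nl()))
        ax.bar(days, self.daily_methane_nl(), width=0.9)
        ax.set_xlabel("day")
        ax.set_ylabel("CH$_4$ (NL d$^{-1}$)")
        return ax


def _liquid_exchange(y: np.ndarray, feed: np.ndarray, vol: float,
                     v_liq: float) -> np.ndarray:
    """Withdraw `vol` of mixed liquor, add `vol` of feed (liquid states)."""
    y = y.copy()
    frac = vol / v_liq
    y[:c.S_AN + 1] = (1.0 - frac) * y[:c.S_AN + 1] + frac * feed[:c.S_AN + 1]
    return y


def integrate(state0: AdmState, events, params: AdmParams, horizon: float,
              *, v_liq: float, v_gas: float, q: float = 0.0,
              feed_continuous: np.ndarray | None = None,
              output_step: float = 0.05, rtol: float = 1e-8,
              atol: float = 1e-12, method: str = "BDF",
              negative_tol: float = 1e-8) -> SimulationResult:
    """Integrate over `horizon` days with instantaneous feed exchanges.

    Parameters
    ----------
    events : sequence of (time_d, exchange_volume_m3, feed_vector)
        Pulse feedings, strictly increasing in time, all within the horizon.
    q, feed_continuous : continuous-flow mode (m3/d and input vector);
        mutually compatible with (usually exclusive of) pulse events.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    events = sorted(events, key=lambda e: e[0])
    times = [e[0] for e in events]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("event times must be strictly increasing")
    if times and (times[0] < 0 or times[-1] >= horizon):
        raise ValueError("events must lie within [0, horizon)")
    for _, vol, _ in events:
        if vol >= v_liq:
            raise ValueError(
                "exchanged volume must be smaller than the liquid volume")

    state0.validate()
    nu_t = np.ascontiguousarray(build_stoichiometry(params).T)
    kin = params.kinetic_array()
    zero_feed = np.zeros(c.N_CORE)
    if feed_continuous is None:
        y_in = zero_feed
    else:
        y_in = np.asarray(feed_continuous, dtype=float)[:c.N_CORE]
    if q < 0:
        raise ValueError("continuous flow q must be >= 0")

    cod_in = 0.0
    cod_out_pulse = 0.0
    if q > 0:
        cod_in += q * horizon * float(y_in @ c.LIQ_COD_MASK)
    cod_initial = (float(state0.values[:c.N_CORE] @ c.LIQ_COD_MASK) * v_liq
                   + (state0.values[c.G_H2] + state0.values[c.G_CH4])
                   * v_gas)

    y = state0.values.astype(float).copy()
    breakpoints = sorted({0.0, horizon, *times})
    ts_all: list[np.ndarray] = []
    ys_all: list[np.ndarray] = []
    ev_iter = {t: (vol, np.asarray(fv, dtype=float)[:c.N_CORE])
               for t, vol, fv in events}

    def rhs_wrapped(t, yy):
        return rhs(t, yy, nu_t, kin, y_in, q, v_liq, v_gas)

    for t_a, t_b in zip(breakpoints, breakpoints[1:]):
        if t_a in ev_iter:
            vol, fv = ev_iter[t_a]
            cod_in += vol * float(fv @ c.LIQ_COD_MASK[:c.N_CORE])
            cod_out_pulse += vol * float(y[:c.N_CORE] @ c.LIQ_COD_MASK)
            y = _liquid_exchange(y, fv, vol, v_liq)
        n_out = max(int(round((t_b - t_a) / output_step)), 1)
        t_eval = np.linspace(t_a, t_b, n_out + 1)
        sol = solve_ivp(rhs_wrapped, (t_a, t_b), y, method=method,
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise SolverFailure(
                f"stiff solver failed in segment [{t_a}, {t_b}]: "
                f"{sol.message}", float(sol.t[-1]) if sol.t.size else t_a, y)
        seg_min = sol.y[:c.N_CORE].min()
        if seg_min < -negative_tol:
            raise SolverFailure(
                f"negative state excursion {seg_min:.3e} in segment "
                f"[{t_a}, {t_b}]", float(sol.t[-1]), sol.y[:, -1])
        y = sol.y[:, -1].copy()
        # wash numerical dust so the next restart starts clean
        tiny = (y[:c.N_CORE] < 0)
        y[:c.N_CORE][tiny] = 0.0
        ts_all.append(sol.t[:-1] if t_b < horizon else sol.t)
        ys_all.append(sol.y[:, :-1].T if t_b < horizon else sol.y.T)

    t_arr = np.concatenate(ts_all)
    y_arr = np.vstack(ys_all)
    ledger = {"cod_in": cod_in, "cod_out_pulse": cod_out_pulse,
              "cod_initial": cod_initial}
    return SimulationResult(t=t_arr, y=y_arr, params=params, v_liq=v_liq,
                            v_gas=v_gas, cod_ledger=ledger)
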