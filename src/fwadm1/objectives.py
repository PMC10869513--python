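"""Observed methane series and the four calibration objective functions.

NE (Nash-Sutcliffe efficiency), ME (modelling efficiency, simulated-mean
denominator), IoA (Willmott's index of agreement) and LSE (mean squared
error).  All four equal their perfect-fit value (1, 1, 1, 0) when the
simulated series reproduces the observations exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ObservedSeries", "ObjectiveScores", "objectives"]


@dataclass
class ObservedSeries:
    """Daily observed methane (NL/d) with a calibration-window mask.

    `days` are integer day indices of the reported period; `mask` selects
    the stable window used for calibration.  Windows are an explicit user
    choice: final acidification phases must be excluded by hand, never
    auto-detected.
    """

    days: np.ndarray
    methane_nl: np.ndarray
    mask: np.ndarray | None = None
    effluent_cod: np.ndarray | None = None
    name: str = "observed"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.methane_nl = np.asarray(self.methane_nl, dtype=float)
        if self.days.shape != self.methane_nl.shape:
            raise ValueError("days and methane series differ in length")
        if self.days.size and np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.methane_nl < 0):
            raise ValueError("observed methane must be >= 0")
        if self.mask is None:
            self.mask = np.ones(self.days.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.days.shape:
                raise ValueError("mask length mismatch")
        if not self.mask.any():
            raise ValueError("calibration mask selects no days")

    def window(self, lo: float, hi: float) -> "ObservedSeries":
        """Copy with the mask restricted to days in [lo, hi)."""
        m = self.mask & (self.days >= lo) & (self.days < hi)
        return ObservedSeries(self.days, self.methane_nl, m,
                              self.effluent_cod, self.name, dict(self.meta))

    @property
    def masked_values(self) -> np.ndarray:
        return self.methane_nl[self.mask]

    @property
    def masked_days(self) -> np.ndarray:
        return self.days[self.mask]


@dataclass
class ObjectiveScores:
    """Goodness of fit of one simulated series against the observations."""

    ne: float
    me: float
    ioa: float
    lse: float

    def as_dict(self) -> dict[str, float]:
        return {"NE": self.ne, "ME": self.me, "IoA": self.ioa,
                "LSE": self.lse}


def objectives(obs, sim: np.ndarray) -> ObjectiveScores:
    """Score a simulated daily series against observations.

    `obs` may be an ObservedSeries (its mask is applied to both series,
    indexing `sim` by observed day) or a plain array of equal length.
    """
    if isinstance(obs, ObservedSeries):
        o = obs.masked_values
        sim = np.asarray(sim, dtype=float)
        if sim.shape == obs.days.shape:
            s = sim[obs.mask]
        else:  # a full daily series indexed by day number
            s = sim[obs.masked_days]
    else:
        o = np.asarray(obs, dtype=float)
        s = np.asarray(sim, dtype=float)
    if o.shape != s.shape:
        raise ValueError("observed and simulated series differ in length")
    n = o.size
    if n < 2:
        raise ValueError("need at least two points to score a fit")

    sse = float(np.sum((o - s) ** 2))
    obar, sbar = float(o.mean()), float(s.mean())

    denom_ne = float(np.sum((o - obar) ** 2))
    if denom_ne == 0.0:
        raise ValueError(
            "observed series is constant: NE and IoA are undefined")
    ne = 1.0 - sse / denom_ne

    denom_me = float(np.sum((o - sbar) ** 2))
    me = 1.0 - sse / denom_me if denom_me > 0 else (
        1.0 if sse == 0 else -np.inf)

    denom_ioa = float(np.sum((np.abs(s - obar) + np.abs(o - obar)) ** 2))
    ioa = 1.0 - sse / denom_ioa if denom_ioa > 0 else 1.0

    return ObjectiveScores(ne=ne, me=me, ioa=ioa, lse=sse / n)
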