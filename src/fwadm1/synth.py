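"""Synthetic inputs: variable substrate stocks and observed-looking campaigns.

Real feeding campaigns draw on successive stocks of the same heterogeneous
substrate, which differ physically and chemically; gas metering adds
flow-proportional error.  Both are emulated here: stock-to-stock
multiplicative lognormal variability around a base characterization, and
daily methane series from a known-parameter simulation corrupted by
multiplicative lognormal measurement noise.  Ground truth travels with every
generated campaign, enabling calibration-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .feed import FeedSpec, SubstrateCharacterization, fractionate
from .objectives import ObservedSeries
from .params import AdmParams, default_params
from .reactor import ReactorConfig, daily_series, run_cstr
from .states import AdmState

__all__ = ["SynthCampaign", "gen_substrate_stocks", "gen_observed_campaign"]


def _lognormal_factors(rng: np.random.Generator, cv: float,
                       size) -> np.ndarray:
    """Unit-mean multiplicative lognormal factors with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def gen_substrate_stocks(base: SubstrateCharacterization, n: int, cv: float,
                         seed: int) -> list[SubstrateCharacterization]:
    """`n` jittered stocks around `base` with per-analyte lognormal CV.

    After jittering, ordering invariants are repaired (soluble <= total,
    VS <= TS) so every stock is a valid characterization.  Deterministic for
    a given seed.
    """
    if n < 1:
        raise ValueError("need n >= 1 stocks")
    if not (0.0 <= cv < 0.5):
        raise ValueError(f"cv {cv} outside [0, 0.5)")
    base.validate()
    rng = np.random.default_rng(seed)
    fields = SubstrateCharacterization._NUMERIC
    stocks = []
    for i in range(n):
        fac = _lognormal_factors(rng, cv, len(fields))
        vals = {f: getattr(base, f) * fac[j]
                for j, f in enumerate(fields)}
        if cv > 0:
            # invariant repair: ordering, then COD-equivalent consistency
            # of the soluble pool (so every stock fractionates cleanly)
            vals["vs"] = min(vals["vs"], vals["ts"])
            vals["cod_sol"] = min(vals["cod_sol"], vals["cod_tot"])
            vals["carb_sol"] = min(vals["carb_sol"], vals["carb_tot"])
            vals["prot_sol"] = min(vals["prot_sol"], vals["prot_tot"])
            eq_sol = 1.1 * vals["carb_sol"] + 1.5 * vals["prot_sol"]
            if eq_sol > vals["cod_tot"]:
                shrink = vals["cod_tot"] / eq_sol
                vals["carb_sol"] *= shrink
                vals["prot_sol"] *= shrink
                eq_sol = vals["cod_tot"]
            vals["cod_sol"] = min(max(vals["cod_sol"], eq_sol),
                                  vals["cod_tot"])
        stocks.append(SubstrateCharacterization(
            name=f"{base.name}#stock{i}", **vals))
    return stocks


@dataclass
class SynthCampaign:
    """One generated feeding campaign with its ground truth."""

    truth: dict[str, float]
    observed: ObservedSeries
    noise_cv: float
    stock_cv: float
    seed: int
    stocks: list[SubstrateCharacterization] = field(repr=False,
                                                    default_factory=list)
    config: ReactorConfig | None = None
    noiseless: np.ndarray | None = None

    def spec(self) -> dict:
        """JSON-able sidecar describing how the campaign was generated."""
        return {"truth": self.truth, "noise_cv": self.noise_cv,
                "stock_cv": self.stock_cv, "seed": self.seed,
                "n_days": int(self.observed.days.size)}


def gen_observed_campaign(truth: tuple[float, float], config: ReactorConfig,
                          base_char: SubstrateCharacterization,
                          ratio: float | None = None, *,
                          noise_cv: float = 0.05, stock_cv: float = 0.05,
                          seed: int = 0, params: AdmParams | None = None,
                          inoculum: AdmState | None = None) -> SynthCampaign:
    """Simulate a campaign at known (k_dis, f_xI) and add measurement noise.

    Each feeding week draws a fresh substrate stock (lognormal variability
    `stock_cv` around the base characterization, with its own realized
    COD/VS ratio); the resulting daily methane is multiplied by unit-mean
    lognormal noise with CV `noise_cv`.  The full reported horizon is
    annotated as the stable window.
    """
    k_dis, f_xi = truth
    if not (0 < k_dis < 10 and 0 <= f_xi < 1):
        raise ValueError(f"ground truth ({k_dis}, {f_xi}) not physical")
    if params is None:
        params = default_params(config.temperature)
    if ratio is None:
        ratio = base_char.cod_tot / base_char.vs

    rng = np.random.default_rng(seed)
    n_weeks = int(np.ceil((config.spinup + config.horizon) / 7.0)) + 1
    stocks = gen_substrate_stocks(base_char, n_weeks, stock_cv,
                                  int(rng.integers(2 ** 31)))
    feeds = []
    for st in stocks:
        # each stock realizes its own COD/VS ratio, jittered with the assays
        r = st.cod_tot / st.vs if stock_cv > 0 else ratio
        feeds.append(fractionate(st, r, f_xi))
    nominal = fractionate(base_char, ratio, f_xi)

    res = run_cstr(config, nominal, params.replace(k_dis=k_dis),
                   inoculum=inoculum, feed_per_week=feeds)
    clean = daily_series(res)
    noisy = clean * _lognormal_factors(rng, noise_cv, clean.size)
    obs = ObservedSeries(np.arange(clean.size), noisy,
                         meta={"window": (0, clean.size)})
    return SynthCampaign(
        truth={"k_dis": k_dis, "f_xi": f_xi, "cod_vs_ratio": ratio},
        observed=obs, noise_cv=noise_cv, stock_cv=stock_cv, seed=seed,
        stocks=stocks, config=config, noiseless=clean)
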