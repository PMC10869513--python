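"""Grid calibration mechanics and the sensitivity scan."""

import numpy as np
import pandas as pd
import pytest

import fwadm1 as fw
from fwadm1.calibration import (MethaneCalibration, _pick_optima,
                                calibrate_grid, respec_inert,
                                sensitivity_scan)
from fwadm1.objectives import ObservedSeries


def test_respec_inert_rescales_split(pretreated_char):
    feed = fw.fractionate(pretreated_char, 1.3, 0.12)
    feed2 = respec_inert(feed, 0.3)
    p = feed2.provenance
    assert p["f_xi"] == 0.3
    assert p["f_ch"] + p["f_pr"] + p["f_li"] == pytest.approx(0.7)
    # mutual proportions preserved
    p0 = feed.provenance
    assert p["f_ch"] / p["f_pr"] == pytest.approx(p0["f_ch"] / p0["f_pr"])
    # concentrations untouched
    assert np.array_equal(feed2.concentrations, feed.concentrations)


def test_tie_breaking_prefers_small_f_xi_then_small_k_dis():
    rows = []
    for kd in (0.5, 1.0):
        for fx in (0.1, 0.2):
            rows.append({"k_dis": kd, "f_xi": fx, "NE": 0.9, "ME": 0.9,
                         "IoA": 0.9, "LSE": 0.01})
    best = _pick_optima(pd.DataFrame(rows))
    assert best["LSE"] == (0.5, 0.1)
    assert best["NE"] == (0.5, 0.1)


def test_noise_free_self_recovery_on_grid(raw_char):
    """Observations generated by the model itself are recovered exactly."""
    ratio = raw_char.cod_tot / raw_char.vs
    cfg = fw.ReactorConfig(hrt=20.0, olr=1.6, horizon=21.0, spinup=7.0,
                           rtol=1e-6, atol=1e-10)
    p = fw.default_params()
    kgrid, fgrid = np.array([0.8, 1.0, 1.2]), np.array([0.1, 0.2, 0.3])
    feed = fw.fractionate(raw_char, ratio, 0.2)

    sims = {}
    for kd in kgrid:
        for fx in fgrid:
            res = fw.run_cstr(cfg, respec_inert(feed, fx),
                              p.replace(k_dis=kd))
            sims[(round(float(kd), 6), round(float(fx), 6))] = \
                fw.daily_series(res)

    truth = sims[(1.0, 0.2)]
    obs = ObservedSeries(np.arange(truth.size), truth)
    model = MethaneCalibration(obs, cfg, feed, params=p, k_dis_grid=kgrid,
                               f_xi_grid=fgrid)
    fit = model.fit(simulations=sims)
    assert (fit.k_dis, fit.f_xi) == (1.0, 0.2)
    # all four objectives agree on the optimum for noise-free data
    for name in ("NE", "ME", "IoA", "LSE"):
        assert fit.best[name] == (1.0, 0.2)
    sc = fit.best_scores()
    assert sc.ne == pytest.approx(1.0)
    assert sc.lse == pytest.approx(0.0, abs=1e-12)
    # and the summary table carries the estimates
    text = fit.summary()
    assert "k_dis" in text and "1.000" in text


def test_failed_cells_are_flagged_not_fatal(raw_char):
    cfg = fw.ReactorConfig(hrt=20.0, olr=1.6, horizon=7.0, spinup=0.0,
                           rtol=1e-6, atol=1e-10)
    feed = fw.fractionate(raw_char, 1.19, 0.2)
    obs = ObservedSeries(np.arange(7), np.linspace(1, 2, 7))
    sims = {(0.5, 0.2): np.linspace(1, 2, 7)}
    # second cell simulates for real; make it fail via an absurd inert
    fit = calibrate_grid(obs, cfg, feed, grid=([0.5], [0.2, 2.0]),
                         simulations=sims)
    assert fit.scores.failed.sum() == 1
    assert (fit.k_dis, fit.f_xi) == (0.5, 0.2)


def test_empty_grid_rejected(raw_char):
    feed = fw.fractionate(raw_char, 1.19, 0.2)
    obs = ObservedSeries(np.arange(3), np.ones(3) + np.arange(3))
    cfg = fw.ReactorConfig(horizon=3.0, spinup=0.0)
    with pytest.raises(ValueError, match="non-empty"):
        calibrate_grid(obs, cfg, feed, grid=([], []))


def test_sensitivity_scan_ranks_inert_and_disintegration(raw_char):
    ratio = raw_char.cod_tot / raw_char.vs
    feed = fw.fractionate(raw_char, ratio, 0.15)
    cfg = fw.ReactorConfig(hrt=20.0, olr=1.6, horizon=21.0, spinup=14.0,
                           rtol=1e-6, atol=1e-10)
    p = fw.default_params().replace(k_dis=1.0)
    df = sensitivity_scan(
        p, {"f_xi": (0.0, 0.3), "k_dis": (0.5, 1.5),
            "K_S_ac": (0.075, 0.3), "K_S_su": (0.5, 0.5)},
        cfg, feed, window=(7, 21))
    ranked = list(df.parameter)
    assert set(ranked[:2]) == {"f_xi", "k_dis"}
    # zero-width interval has exactly zero effect
    zero_row = df[(df.low == df.high)].iloc[0]
    assert zero_row.effect == 0.0
    # the inert-fraction effect follows the analytic methane ceiling:
    # 0.35 NL/gCOD x COD/VS x particulate share x delta f_xi
    part = 1.0 - feed.provenance["soluble_share"]
    predicted = 0.35 * ratio * part * 0.3
    f_xi_effect = float(df[df.parameter == "f_xi"].effect.iloc[0])
    assert f_xi_effect == pytest.approx(predicted, rel=0.15)


def test_sensitivity_requires_ranges(raw_char):
    feed = fw.fractionate(raw_char, 1.19, 0.2)
    with pytest.raises(ValueError, match="interval"):
        sensitivity_scan(fw.default_params(), {}, fw.ReactorConfig(), feed)
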