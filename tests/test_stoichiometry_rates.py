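"""Conservation of the process stoichiometry and the kinetic rate laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fwadm1 as fw
import fwadm1.constants as c
from fwadm1.petersen import build_stoichiometry, composition_vectors


def _conservation_residuals(p):
    nu = build_stoichiometry(p)
    cod, cvec, nvec = composition_vectors(p)
    cod = cod.copy()
    cod[[c.G_H2, c.G_CH4]] = 0.0  # biochemical terms act on the liquid only
    return nu @ cod, nu @ cvec, nu @ nvec


def test_every_process_conserves_cod_carbon_nitrogen(params):
    r_cod, r_c, r_n = _conservation_residuals(params)
    assert np.abs(r_cod).max() < 1e-9
    assert np.abs(r_c).max() < 1e-9
    assert np.abs(r_n).max() < 1e-9


@settings(max_examples=30, derandomize=True, deadline=None)
@given(fr=st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5),
       y_ac=st.floats(0.02, 0.2))
def test_conservation_holds_for_any_composite_split(fr, y_ac):
    """COD/C/N closure is structural, not tied to the default split."""
    p = fw.default_params()
    p.set_composite_split(f_si=fr[0], f_xi=fr[1], f_ch=fr[2], f_pr=fr[3],
                          f_li=fr[4])
    p = p.replace(Y_ac=y_ac, f_si=p.f_si, f_xi=p.f_xi, f_ch=p.f_ch,
                  f_pr=p.f_pr, f_li=p.f_li)
    r_cod, r_c, r_n = _conservation_residuals(p)
    assert np.abs(r_cod).max() < 1e-9
    assert np.abs(r_c).max() < 1e-9
    assert np.abs(r_n).max() < 1e-9


def test_disintegration_first_order_and_idle_uptakes(params):
    """With no biomass, only disintegration (and hydrolysis) can proceed."""
    s = fw.AdmState()
    s.set("X_c", 2.0)
    p = params.replace(k_dis=1.0)
    rho = fw.process_rates(s, p, ph=7.0)
    assert rho["disintegration"] == pytest.approx(2.0)
    for name in ("uptake_su", "uptake_aa", "uptake_fa", "uptake_va",
                 "uptake_bu", "uptake_pro", "uptake_ac", "uptake_h2"):
        assert rho[name] == 0.0


def test_hydrogen_inhibition_shuts_down_acetogens(params):
    s = fw.AdmState()
    for name, val in [("S_fa", 1.0), ("S_pro", 1.0), ("S_bu", 1.0),
                      ("X_fa", 1.0), ("X_pro", 1.0), ("X_c4", 1.0),
                      ("S_h2", 10.0), ("S_IN", 0.05)]:
        s.set(name, val)
    rho = fw.process_rates(s, params, ph=7.0)
    # S_h2 = 10 kgCOD/m3 >> K_I (1e-5 scale): inhibition factor ~ 1e-6
    assert rho["uptake_fa"] < 1e-4
    assert rho["uptake_pro"] < 1e-4
    assert rho["uptake_bu"] < 1e-4


def test_monod_uptake_matches_hand_computed_product(params):
    """One nonzero substrate+biomass pair against a spreadsheet oracle."""
    s = fw.AdmState()
    s.set("S_su", 0.8)
    s.set("X_su", 1.5)
    s.set("S_IN", 0.02)
    ph = 6.5
    rho = fw.process_rates(s, params, ph=ph)
    # independent arithmetic: k_m * S/(KS+S) * X * I_pH * I_IN
    i_ph = 1.0  # 6.5 > pH_UL_aa = 5.5
    i_in = 0.02 / (0.02 + params.K_S_IN)
    expected = 30.0 * 0.8 / (0.5 + 0.8) * 1.5 * i_ph * i_in
    assert rho["uptake_su"] == pytest.approx(expected, rel=1e-12)

    # below the upper pH limit the empirical switch engages
    rho_acid = fw.process_rates(s, params, ph=4.75)
    i_ph_acid = math.exp(-3.0 * ((4.75 - 5.5) / 1.5) ** 2)
    assert rho_acid["uptake_su"] == pytest.approx(
        expected * i_ph_acid, rel=1e-12)


def test_acetoclastic_ammonia_inhibition(params):
    s = fw.AdmState()
    s.set("S_ac", 2.0)
    s.set("X_ac", 1.0)
    s.set("S_IN", 0.5)   # high total ammonia
    s.set("S_cat", 0.05)
    rho_hi = fw.process_rates(s, params, ph=7.8)
    s.set("S_IN", 0.02)
    rho_lo = fw.process_rates(s, params, ph=7.8)
    assert rho_hi["uptake_ac"] < rho_lo["uptake_ac"]


@settings(max_examples=50, derandomize=True, deadline=None)
@given(data=st.data())
def test_rates_nonnegative_and_zero_without_substrate(params, data):
    v = np.zeros(c.N_STATE)
    for i in range(c.N_CORE):
        v[i] = data.draw(st.floats(0.0, 5.0), label=c.STATE_NAMES[i])
    s = fw.AdmState(v)
    rho = fw.process_rates(s, params)
    assert np.all(rho.rho >= 0.0)
    # uptakes vanish when their substrate or biomass pool is empty
    pairs = [("S_su", "X_su", "uptake_su"), ("S_aa", "X_aa", "uptake_aa"),
             ("S_ac", "X_ac", "uptake_ac"), ("S_h2", "X_h2", "uptake_h2")]
    for sub, bio, proc in pairs:
        if s.get(sub) == 0.0 or s.get(bio) == 0.0:
            assert rho[proc] == 0.0


def test_invalid_state_rejected(params):
    s = fw.AdmState()
    s.set("S_ac", -1.0)
    with pytest.raises(ValueError, match="negative"):
        fw.process_rates(s, params)
    s2 = fw.AdmState()
    s2.set("S_su", float("nan"))
    with pytest.raises(ValueError, match="finite"):
        fw.process_rates(s2, params)
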