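"""COD fractionation of substrate characterizations into model inputs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fwadm1 as fw
import fwadm1.constants as c
from fwadm1.feed import SubstrateCharacterization, composite_split


def test_cod_vs_ratio_single_stock_exp1_feed():
    # Exp1 feed assay: COD 37.3 g/L over VS 31.1 g/L
    assert fw.cod_vs_ratio([(37.3, 31.1)]) == pytest.approx(1.199, abs=5e-4)


def test_cod_vs_ratio_identity_and_hand_sum():
    assert fw.cod_vs_ratio([(5.0, 5.0), (2.0, 2.0)]) == 1.0
    # three unequal stocks, hand-summed
    stocks = [(10.0, 8.0), (20.0, 15.0), (5.0, 6.0)]
    assert fw.cod_vs_ratio(stocks) == pytest.approx(35.0 / 29.0)


def test_cod_vs_ratio_validates():
    with pytest.raises(ValueError):
        fw.cod_vs_ratio([])
    with pytest.raises(ValueError):
        fw.cod_vs_ratio([(1.0, 0.0)])


def test_pretreated_residue_soluble_share(pretreated_char):
    # soluble / total COD = 40 / 151 ~= 26 %
    feed = fw.fractionate(pretreated_char, 1.3, 0.12)
    share = feed.soluble_cod / feed.total_cod
    assert share == pytest.approx(40.0 / 151.0, rel=1e-9)
    assert round(100 * share) == 26


def test_total_cod_equals_vs_times_ratio(pretreated_char):
    feed = fw.fractionate(pretreated_char, 1.3, 0.12)
    assert feed.total_cod == pytest.approx(pretreated_char.vs * 1.3,
                                           abs=1e-9)


def test_full_inert_fraction_removes_degradable_split(pretreated_char):
    feed = fw.fractionate(pretreated_char, 1.3, 1.0)
    split = composite_split(feed)
    assert split["f_xi"] == 1.0
    assert split["f_ch"] == split["f_pr"] == split["f_li"] == 0.0
    # all particulate COD still enters as composite, to be routed to X_I
    assert feed.concentrations[c.X_C] == pytest.approx(
        feed.total_cod - feed.soluble_cod)


def test_raw_residue_split_matches_equivalent_arithmetic(raw_char):
    """f_ch : f_pr : f_li follow the particulate COD-equivalents."""
    feed = fw.fractionate(raw_char, 1.19, 0.2)
    s = composite_split(feed)
    eq = np.array([(93 - 19) * 1.1, (27 - 8) * 1.5, 8 * 2.9])
    expected = (1 - 0.2) * eq / eq.sum()
    assert np.allclose([s["f_ch"], s["f_pr"], s["f_li"]], expected)
    assert abs(sum(s.values()) - 1.0) < 1e-12


def test_soluble_allocation_overshoot_rejected():
    char = SubstrateCharacterization(
        name="inconsistent", ts=100, vs=90, cod_tot=100, cod_sol=20,
        carb_tot=50, carb_sol=25, prot_tot=20, prot_sol=10, lipids=5)
    # 1.1*25 + 1.5*10 = 42.5 >> 20 measured soluble COD
    with pytest.raises(ValueError, match="exceed measured soluble COD"):
        fw.fractionate(char, 1.1, 0.1)


def test_inert_fraction_bounds(pretreated_char):
    with pytest.raises(ValueError):
        fw.fractionate(pretreated_char, 1.3, -0.1)
    with pytest.raises(ValueError):
        fw.fractionate(pretreated_char, 1.3, 1.2)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(vs=st.floats(20, 300), ratio=st.floats(0.8, 2.0),
       f_xi=st.floats(0, 0.95), sol=st.floats(0.05, 0.95))
def test_round_trip_cod_for_random_characterizations(vs, ratio, f_xi, sol):
    cod_tot = vs * 1.2
    char = SubstrateCharacterization(
        name="rand", ts=vs * 1.1, vs=vs, cod_tot=cod_tot,
        cod_sol=sol * cod_tot, carb_tot=0.4 * vs, carb_sol=0.0,
        prot_tot=0.15 * vs, prot_sol=0.0, lipids=0.03 * vs)
    feed = fw.fractionate(char, ratio, f_xi)
    assert feed.total_cod == pytest.approx(vs * ratio, abs=1e-9)


def test_raising_inert_fraction_never_raises_biodegradable_cod(
        pretreated_char):
    prev = np.inf
    for f_xi in (0.0, 0.1, 0.2, 0.3, 0.5):
        feed = fw.fractionate(pretreated_char, 1.3, f_xi)
        s = composite_split(feed)
        biodeg = (feed.soluble_cod + feed.concentrations[c.X_C]
                  * (s["f_ch"] + s["f_pr"] + s["f_li"]))
        assert biodeg <= prev + 1e-12
        prev = biodeg


def test_feed_concentration_realizes_olr():
    char = SubstrateCharacterization(
        name="stock", ts=116, vs=112, cod_tot=151, cod_sol=40, carb_tot=63,
        carb_sol=20, prot_tot=19, prot_sol=11, lipids=8)
    vs_feed, dil = fw.feed_concentration(char, olr=1.6, hrt=20)
    assert vs_feed == pytest.approx(32.0)
    assert dil == pytest.approx(112 / 32.0)
    vs_feed40, _ = fw.feed_concentration(char, olr=1.6, hrt=40)
    assert vs_feed40 == pytest.approx(64.0)
    assert fw.feed_concentration(char, olr=0.0, hrt=20)[0] == 0.0
    with pytest.raises(ValueError, match="cannot concentrate"):
        fw.feed_concentration(char, olr=4.0, hrt=40)  # needs 160 > 112 gVS/L


def test_characterization_invariants():
    with pytest.raises(ValueError, match="cod_sol"):
        SubstrateCharacterization(name="bad", ts=10, vs=9, cod_tot=5,
                                  cod_sol=6, carb_tot=1, carb_sol=0,
                                  prot_tot=1, prot_sol=0, lipids=0)
    with pytest.raises(ValueError, match=">= 0"):
        SubstrateCharacterization(name="bad", ts=10, vs=9, cod_tot=5,
                                  cod_sol=1, carb_tot=-1, carb_sol=0,
                                  prot_tot=1, prot_sol=0, lipids=0)
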