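import numpy as np
import pytest

import fwadm1 as fw
from fwadm1 import datasets


@pytest.fixture(scope="session")
def chars():
    return datasets.characterizations()


@pytest.fixture(scope="session")
def pretreated_char(chars):
    return chars["pretreated_solid_residue"]


@pytest.fixture(scope="session")
def raw_char(chars):
    return chars["raw_solid_residue"]


@pytest.fixture(scope="session")
def params():
    return fw.default_params(310.15)


@pytest.fixture()
def fast_cfg():
    """Short semi-continuous configuration for quick dynamic tests."""
    return fw.ReactorConfig(hrt=20.0, olr=1.6, horizon=21.0, spinup=7.0,
                            rtol=1e-6, atol=1e-10)


@pytest.fixture(scope="session")
def exp4_run(pretreated_char):
    """The HRT-40 emulation of the pretreated solid residue.

    Table-characterized feed at the Exp4 COD/VS ratio (80.1/61.6),
    disintegration constant 1.2 1/d and inert fraction 0.12, 5 L working
    volume, weekday pulse feeding, 30 d spin-up + 160 d reported.
    Session-scoped: several tests read different quantities off this run.
    """
    feed = fw.fractionate(pretreated_char, 80.1 / 61.6, 0.12)
    cfg = fw.ReactorConfig(v_liq=5.0, v_gas=5.0, hrt=40.0, olr=1.6,
                           horizon=160.0, spinup=30.0)
    p = fw.default_params(310.15).replace(k_dis=1.2)
    return fw.run_cstr(cfg, feed, p)


@pytest.fixture(scope="session")
def acetate_substrate():
    """A pure-acetate 'substrate' spec (10 gCOD/L at nominal 10 gVS/L)."""
    import fwadm1.constants as c
    conc = np.zeros(c.N_CORE)
    conc[c.S_AC] = 10.0
    conc[c.S_IN] = 0.01
    conc[c.S_CAT] = 0.04
    prov = {"f_si": 0.0, "f_xi": 0.0, "f_ch": 0.0, "f_pr": 0.0, "f_li": 0.0,
            "phi_su": 0.0, "phi_aa": 0.0, "phi_fa": 0.0, "soluble_share": 1.0}
    return fw.FeedSpec(conc, 1.0, 10.0, prov)
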