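# fwadm1 — anaerobic digestion modelling of food-waste solid residues

`fwadm1` is a mechanistic modelling toolkit for bench-scale anaerobic
digestion of the solid residues that remain after solid–liquid separation of
food waste in a biorefinery setting.  It is aimed at bioprocess engineers
and modellers who need to (i) turn proximate substrate assays into digester
model inputs on a closed COD basis, (ii) simulate semi-continuous CSTR and
batch methane-potential experiments, (iii) calibrate the substrate-specific
parameters against measured daily methane, and (iv) close the COD mass
balance of the surrounding valorization platform.

## The model

The core is the IWA Anaerobic Digestion Model No. 1 (ADM1): 19 biochemical
processes (disintegration, three hydrolyses, seven Monod uptakes with pH /
hydrogen / free-ammonia inhibition, seven first-order biomass decays) acting
on 24 liquid-phase states and 3 headspace gases.  Every state obeys the
mass-continuity equation of a completely mixed reactor,

    dC_i/dt = Q/V · (C_in,i − C_i) + Σ_j ν_ij ρ_j ,

with the Petersen stoichiometry ν built so that each process conserves COD,
carbon and nitrogen to machine precision.  pH is solved algebraically from
electroneutrality at every evaluation (DAE-free), dissolved H₂ stays
dynamic, and biogas leaves through a fixed-pressure vent with `k_La`
transfer.  Feeding is an instantaneous equal-volume exchange — the bench
reactors are fed by manual pulses Monday–Friday and run as batches over the
weekend, while methane is metered continuously and normalized to 0 °C,
1 atm (1 g COD ≡ 350 NmL CH₄).

Substrate enters through a COD fractionation: total feed COD is VS × the
experiment-wide COD/VS ratio; soluble COD is allocated to sugar / amino-acid
/ LCFA pools proportionally to the COD equivalents of the measured soluble
carbohydrates (×1.1) and proteins (×1.5); particulate COD enters as
composite with `f_ch/f_pr/f_li` recomputed from the particulate assays and a
(calibrated) inert fraction `f_xI`.

Calibration follows the experimental practice for hydrolysis-limited
digesters: the two most sensitive parameters — the disintegration constant
`k_dis` (d⁻¹) and `f_xI` — are estimated by simulating a parameter grid and
scoring each cell against observed daily methane with four objectives
(Nash–Sutcliffe NE, modelling efficiency ME, Willmott's index of agreement
IoA, and the mean squared error LSE).

## Worked example

```python
import numpy as np
import fwadm1 as fw
from fwadm1 import datasets

char = datasets.characterization("pretreated_solid_residue")
feed = fw.fractionate(char, ratio=80.1 / 61.6, inert_fraction=0.12)

cfg = fw.ReactorConfig(v_liq=5.0, hrt=40.0, olr=1.6,
                       horizon=160.0, spinup=30.0)
params = fw.default_params(310.15).replace(k_dis=1.2)
res = fw.run_cstr(cfg, feed, params)

daily = fw.daily_series(res)
print(f"mean daily methane (stable window): {daily[120:].mean():.2f} NL/d")
print(f"SMP over days 120-160: {fw.smp(res, (120, 160)):.3f} Nm3 CH4/kgVS")
print(f"effluent soluble COD: {res.soluble_cod_series()[-1]:.2f} g/L, "
      f"pH {res.ph_series()[-1]:.2f}")
print(f"COD ledger closure: {res.cod_balance()['closure']:.2e}")
```

prints

```
mean daily methane (stable window): 2.91 NL/d
SMP over days 120-160: 0.372 Nm3 CH4/kgVS
effluent soluble COD: 0.08 g/L, pH 7.15
COD ledger closure: 6.22e-15
```

i.e. a 5 L digester fed the thermally pretreated solid residue at 40 d
retention produces ~2.9 NL CH₄ per day with a specific methane production of
0.372 Nm³ per kg of VS fed, a clean effluent (soluble COD far below 1 g/L)
at circum-neutral pH, and a COD balance that closes to round-off.

Calibrating against a synthetic campaign with known ground truth
(k_dis = 1.0 d⁻¹, f_xI = 0.20, 5 % gas-meter noise, 5 % stock variability):

```python
camp = fw.gen_observed_campaign((1.0, 0.20), fw.ReactorConfig(
    hrt=20.0, olr=1.6, horizon=35.0, spinup=10.0, rtol=1e-6, atol=1e-10),
    datasets.characterization("raw_solid_residue"), seed=42)
model = fw.MethaneCalibration(
    camp.observed, camp.config,
    fw.fractionate(datasets.characterization("raw_solid_residue"),
                   camp.truth["cod_vs_ratio"], 0.20),
    k_dis_grid=np.array([0.8, 0.9, 1.0, 1.1, 1.2]),
    f_xi_grid=np.array([0.10, 0.15, 0.20, 0.25, 0.30]))
print(model.fit().summary())
```

```
Methane grid calibration
==========================================================
grid: k_dis 0.8..1.2 (5 values), f_xI 0.1..0.3 (5 values)
observations: 35 daily methane values, window (0, 35)
----------------------------------------------------------
estimate                   value
k_dis (1/d)                1.100
f_xI (-)                   0.250
----------------------------------------------------------
objective   at optimum  argmax k_dis argmax f_xI
NE              0.9847         1.100       0.250
ME              0.9847         1.100       0.250
IoA             0.9962         1.100       0.250
LSE             0.0138         1.100       0.250
==========================================================
```

The estimate lands one grid step from the truth for this noise realization;
across many campaigns the recovery is unbiased (see the test suite).

A command line wraps the same stages:

```bash
fwadm1 simulate --config run.yaml --outdir out/
fwadm1 calibrate --config run.yaml --observed methane.csv
fwadm1 balance --outdir out/      # two-scenario platform COD balance
fwadm1 synth --seed 42            # synthetic campaign + JSON sidecar
```

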