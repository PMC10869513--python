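# Methods

This note documents the model, the numerical choices and the deliberate
design decisions behind `fwadm1`, in the spirit of a model-description
appendix.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The digestion model

The core is the standard Anaerobic Digestion Model No. 1 (ADM1) for a
completely mixed reactor: 24 liquid-phase states (12 soluble, 12
particulate), two strong-ion pools and 3 headspace gases, driven by 19
biochemical processes.  All COD species are carried in kgCOD m⁻³ (≡ g/L),
inorganic carbon/nitrogen and ions in kmol m⁻³, time in days.  Every
parameter not specific to the substrate is taken from the published
mesophilic benchmark parameter set of the model's reference implementation,
re-evaluated at the operating temperature: acid–base constants, the water
product and Henry constants follow van 't Hoff from their 25 °C values
(e.g. K_w(35 °C) = 2.079·10⁻¹⁴, K_a,CO₂(35 °C) = 4.94·10⁻⁷ — both
reproduced by the test suite).  The full set is exposed as a dataclass and
can be exported/imported as YAML.

**Stoichiometric closure.**  The Petersen matrix is assembled from the
yields and product fractions; the inorganic-carbon and -nitrogen columns
are then closed per process (ν_IC,j = −Σᵢ Cᵢ ν_ij, likewise for N), so COD,
C and N conservation hold to machine precision for *any* composite split —
including splits produced by the feed fractionation.  The composite
particulate pool inherits its C and N content from its split
(N_xc = (f_sI+f_xI)·N_I + f_pr·N_aa), which with the benchmark defaults
reproduces the published N_xc = 0.0376/14 kmol N·kgCOD⁻¹.

**pH.**  Solved algebraically at every right-hand-side evaluation from
electroneutrality — cations + NH₄⁺ + H⁺ − HCO₃⁻ − ionized VFAs − OH⁻ −
anions = 0 — with ion pairs speciated from their total pools and H⁺.  The
balance is strictly monotone in H⁺, so a safeguarded Newton iteration
(clipped into a shrinking bisection bracket on pH 2–12) converges to a
residual below 10⁻¹² kmol m⁻³.  A brute-force Brent bisection oracle,
implemented independently in the tests, agrees to 10⁻⁶ pH units across
1 000 random ionic states.

**Gas phase.**  Dissolved H₂, CH₄ and CO₂ transfer to the headspace through
k_La·(S − K_H·p).  The vent flow is computed so the headspace stays at
atmospheric pressure (water vapour included); this "ideal vent" variant is
chosen over the overpressure-valve law because the bench reactors meter gas
at ambient pressure after a CO₂ trap.  Methane volumes are normalized to
0 °C and 1 atm (22.414 NL/mol); the CO₂ trap is treated as ideal, so the
reported series is pure CH₄.  Cumulative vented moles are carried as extra
integrated states, which makes daily aggregation exact (interpolation of a
cumulative ledger at day boundaries) and lets every run audit its own COD
balance: fed + initial inventory = final inventory + effluent + gas, closed
to <10⁻⁶ relative in the long emulations (the test suite asserts 0.5 %).

**Integration.**  `scipy.integrate.solve_ivp` (BDF) between feeding events
with a hard restart at each event; the right-hand side and the pH Newton
solve are numba-compiled.  Feeding is an instantaneous equal-volume
exchange (withdraw mixed liquor, add feed) — manual once-daily feeding is
fast relative to retention times of 20–40 d.  Reference tolerances are
rtol 10⁻⁸ / atol 10⁻¹²; short screening and calibration runs use
rtol 10⁻⁶ / atol 10⁻¹⁰ (configurable per run).  With non-negative initial
state and feed, trajectories stay above −10⁻¹⁰; sub-tolerance negative dust
is zeroed at event restarts.

## 2. Feed fractionation

A substrate stream is described by its proximate assay (TS, VS, total and
soluble COD, total/soluble carbohydrates and proteins, lipids, starch,
lignocellulosics; g per kg of material).  The model input is built per unit
of COD:

* total feed COD = VS × the experiment-wide COD/VS ratio (Σ COD / Σ VS over
  the stocks, the single constant that closes the campaign's COD balance);
* the measured soluble/total COD split fixes the soluble share; soluble COD
  goes to monosaccharides and amino acids proportionally to the COD
  equivalents of the soluble carbohydrate (×1.1) and protein (×1.5) assays,
  remainder to LCFA.  If the equivalents overshoot the measured soluble COD
  by ≤10 % (assay inconsistency — the shipped raw-residue table overshoots
  by 2.8 %), the allocation is renormalised with no LCFA pool; beyond 10 %
  it is an error;
* particulate COD enters as composite X_c whose split f_ch : f_pr : f_li
  follows the particulate COD equivalents (carbohydrates ×1.1, proteins
  ×1.5, lipids ×2.9), scaled to 1 − f_xI − f_sI.  The inert fraction f_xI
  is the calibration target; f_sI defaults to 0 so the entire
  non-biodegradable fraction is routed to particulate inerts (the two are
  not separately identifiable from methane data).

The feed is water-diluted to VS = OLR × HRT, the concentration at which the
daily exchanged volume V/HRT delivers the configured organic loading rate.
With 5 weekday feedings the per-event exchange is V·(7/5)/HRT, so the
*weekly* hydraulic and organic loads match the nominal continuous values.

Default feed ions (S_IN 0.01, S_cat 0.01, S_an 0.02 kmol m⁻³) were chosen
once so that protein mineralization reproduces digestate ammonium around
1 g N/L and a circum-neutral reactor pH, as observed in stable operation;
they are explicit `fractionate` arguments.

## 3. Reactor drivers and derived quantities

`run_cstr` simulates spin-up (default 30 d, discarded from all reported
series — the experimental inocula were acclimated by daily feeding) plus
the reported horizon, with the weekday/weekend calendar.  The default
working volume is 5 L in a 10 L vessel (only the total size is known;
specific yields are volume-invariant).  Derived quantities:

* daily methane (NL/d) by calendar-day differencing of the cumulative
  normalized volume;
* SMP = cumulative CH₄ / cumulative VS fed over a stated window
  (Nm³ kgVS⁻¹); its theoretical ceiling is
  0.35·(COD/VS)·(1 − f_xI·particulate share);
* VS reduction = 100·(feed − digestate)/feed;
* weekend share of weekly methane, the qualitative fingerprint of slow
  disintegration.

`run_bmp` runs substrate + inoculum and a paired inoculum-only blank as
batches (flow = 0) and reports net SMP = (CH₄_test − CH₄_blank)/VS_substrate
at a substrate/inoculum VS ratio of 0.5.  The inoculum's VS, unknown for a
state vector, is estimated from its particulate COD at 1.42 gCOD/gVS unless
given.  Absolute BMP values therefore depend on an uncharacterized
inoculum; only ledger closure and qualitative batch behaviour are asserted.

## 4. Sensitivity and calibration

One-at-a-time sensitivity runs the model at the endpoints (optionally
midpoint) of each parameter interval and ranks parameters by the range of
stable-window SMP.  The inert fraction and the disintegration constant top
the ranking in hydrolysis-limited configurations.  The analytic check used
in the tests is the methane-ceiling difference
0.35·(COD/VS)·(particulate share)·Δf_xI; the particulate-share factor is
essential because the inert split applies to particulate COD only.

Calibration is a grid search, as in the experimental procedure: simulate
every (k_dis, f_xI) cell, score the four objectives against observed daily
methane over an explicit stable window (never auto-detected; the
experiments' final acidification phases are excluded by hand), report
per-objective optima and the LSE optimum as the headline estimate, ties
broken toward smaller f_xI then smaller k_dis.  Default grid:
k_dis 0.3–2.0 step 0.05 d⁻¹, f_xI 0–0.5 step 0.025.

Typeset versions of these objective functions in the application
literature are frequently corrupted (missing exponents and overbars); the
implemented forms are the standard ones: NE = 1 − SSE/Σ(obs−ō)², IoA = 1 − SSE/Σ(|sim−ō|+|obs−ō|)²,
LSE = SSE/n, and ME = 1 − SSE/Σ(obs−s̄)² with the *simulated* mean in the
denominator, as the typeset fragment indicates.  All four equal their
perfect-fit value on identical series, which the tests assert.

## 5. Synthetic campaigns

The generator emulates the two dominant noise sources of the bench
campaigns: stock-to-stock substrate variability (each feeding week draws a
fresh characterization with unit-mean multiplicative lognormal jitter,
default CV 5 %, including its own realized COD/VS ratio) and
flow-proportional gas-meter error (unit-mean lognormal on daily volumes,
default CV 5 % — meter error scales with flow, hence multiplicative).
Jittered stocks get an invariant repair (soluble ≤ total, VS ≤ TS, soluble
COD consistent with its constituents' COD equivalents).  Ground truth
travels with the campaign; seeds are explicit everywhere and no global
random state is used.

What the generator does *not* emulate: drift of the inoculum community,
acidification collapse, within-week stock ageing, or correlated assay
errors.  Passing recovery tests therefore demonstrate identifiability of
(k_dis, f_xI) under the stated noise model, not under every failure mode of
a real campaign.

Calibration-recovery experiments score each synthetic campaign against grid
simulations of the *nominal* averaged feed — the calibrator never sees the
per-week stocks, mirroring how the averaged-input model is used against
real data.  The recovery experiments in the test suite use a scaled-down
design (HRT 20 d, 10 d spin-up + 35 observed days, 5×5 grid with steps
0.1 d⁻¹ and 0.05) chosen to keep the full suite fast while spanning the
plausible parameter region; recovery there is unbiased with maximum error
of one grid step.

## 6. Platform COD balance

Measured product amounts convert to COD equivalents with fixed
stoichiometric factors (gCOD/g: carbohydrates 1.1, proteins 1.5, lignin
1.56, lipids 2.9, ethanol 2.09, lactate 1.07, acetic 1.07, propionic 1.51,
butyric/isobutyric 1.82, valeric/isovaleric 2.04, caproic 2.21; gCOD/L:
H₂ 0.71, CH₄ 2.86).  The gas factors are used exactly as conventionally
printed even though recomputing from the stated densities (0.09 and
0.72 g/L) gives 0.72/2.88 — the table is overridable if the recomputed
values are preferred.  The two-scenario balance (with/without thermal
pretreatment) expresses every stream in gCOD per kg of raw feedstock;
per-node residuals are reported, never absorbed, and splits that exceed
their input by more than 10 % are rejected as measurement inconsistencies.
Fermentation yields are user inputs: the shipped example configuration is
illustrative, chosen to land at the ~31 vs ~69 gCOD VFA split of the two
scenarios given the shipped liquid-extract characterizations.

## 7. Known limitations

* The benchmark parameter set converts ~86–88 % of degradable COD to
  methane at 20–40 d retention (the remainder is biomass washout and
  residual particulates).  Substrate-specific deviations beyond that are
  absorbed by f_xI during calibration; f_xI is therefore an *effective*
  inert fraction, not a pure substrate property.
* Acidification/collapse dynamics beyond the native inhibition terms are
  out of scope; calibration windows must end before collapse.
* The fixed-pressure vent slightly lowers headspace CH₄ partial pressure
  relative to an overpressure-valve formulation (order 5 % in benchmark
  comparisons); vented volumes are unaffected at closure level.
* Ion-pair states are algebraic; very fast acid–base transients (seconds)
  are outside the model's resolution, which is irrelevant at daily feeding.
* The BMP driver inherits every uncertainty of the inoculum state; its
  absolute yields are illustrative.
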