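"""From proximate substrate characterization to a digester input vector.

A substrate stream is assayed per kg of material (solids, COD, carbohydrates,
proteins, lipids, starch, lignocellulosics).  The model input is built on a
COD basis: the experiment-wide COD/VS ratio converts VS fed to COD fed, the
soluble share is allocated to sugar/amino-acid/LCFA pools proportionally to
the COD-equivalents of the measured soluble fractions, and the particulate
share enters as composite particulates whose disintegration split
(f_ch/f_pr/f_li with an inert fraction f_xI) is recomputed from the measured
particulate composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as c

# COD equivalents used for composition arithmetic (gCOD per g compound)
COD_EQ_CARB = 1.1
COD_EQ_PROT = 1.5
COD_EQ_LIPID = 2.9
COD_EQ_LIGNIN = 1.56

#: tolerated overshoot of soluble COD-equivalents over measured soluble COD
SOLUBLE_OVERSHOOT_TOL = 0.10


@dataclass
class SubstrateCharacterization:
    """Proximate analysis of one substrate stream, g per kg of material."""

    name: str
    ts: float
    vs: float
    cod_tot: float
    cod_sol: float
    carb_tot: float
    carb_sol: float
    prot_tot: float
    prot_sol: float
    lipids: float
    starch: float = 0.0
    lignocellulosics: float = 0.0
    uncertainties: dict[str, float] = field(default_factory=dict)

    _NUMERIC = ("ts", "vs", "cod_tot", "cod_sol", "carb_tot", "carb_sol",
                "prot_tot", "prot_sol", "lipids", "starch",
                "lignocellulosics")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in self._NUMERIC:
            v = getattr(self, f)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{self.name}: {f}={v!r} must be >= 0")
        pairs = [("cod_sol", "cod_tot"), ("vs", "ts"),
                 ("carb_sol", "carb_tot"), ("prot_sol", "prot_tot")]
        for lo, hi in pairs:
            if getattr(self, lo) > getattr(self, hi) * (1 + 1e-9):
                raise ValueError(
                    f"{self.name}: {lo} ({getattr(self, lo)}) exceeds "
                    f"{hi} ({getattr(self, hi)})")

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in self._NUMERIC}

    @property
    def soluble_cod_fraction(self) -> float:
        return self.cod_sol / self.cod_tot


@dataclass
class FeedSpec:
    """Digester input concentrations plus the allocation that built them."""

    concentrations: np.ndarray         # (N_CORE,) feed vector, kgCOD m-3 basis
    cod_vs_ratio: float                # gCOD per gVS
    vs: float                          # gVS per L of feed as built
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.shape != (c.N_CORE,):
            raise ValueError("feed vector must cover the core states")

    @property
    def total_cod(self) -> float:
        """Total COD concentration of the feed (g/L)."""
        return float(self.concentrations @ c.COD_CONTENT[:c.N_CORE])

    @property
    def soluble_cod(self) -> float:
        idx = [c.S_SU, c.S_AA, c.S_FA, c.S_VA, c.S_BU, c.S_PRO, c.S_AC, c.S_I]
        return float(self.concentrations[idx].sum())

    @property
    def particulate_cod(self) -> float:
        return float(self.concentrations[list(c.PARTICULATE_COD_IDX)].sum())

    def diluted(self, vs_target: float) -> "FeedSpec":
        """Water-diluted copy at the target VS concentration (gVS/L)."""
        if vs_target > self.vs * (1 + 1e-9):
            raise ValueError(
                f"cannot concentrate feed from {self.vs} to {vs_target} gVS/L")
        f = vs_target / self.vs
        return FeedSpec(self.concentrations * f, self.cod_vs_ratio,
                        vs_target, dict(self.provenance,
                                        dilution_factor=1.0 / f))


def cod_vs_ratio(stocks: list[tuple[float, float]]) -> float:
    """Experiment-wide COD/VS ratio closing the COD balance: sum COD / sum VS."""
    if not stocks:
        raise ValueError("at least one (COD, VS) stock pair is required")
    cods, vss = zip(*stocks)
    if any(v <= 0 for v in vss):
        raise ValueError("every stock VS must be > 0")
    return float(sum(cods) / sum(vss))


def fractionate(char: SubstrateCharacterization, ratio: float,
                inert_fraction: float, *, f_si: float = 0.0,
                s_IN: float = 0.01, s_cat: float = 0.01,
                s_an: float = 0.02) -> FeedSpec:
    """Allocate one unit of substrate COD over the model input pools.

    Total COD is VS x ratio; the measured soluble/total COD split decides the
    soluble share; soluble COD goes to monosaccharide and amino-acid pools in
    proportion to the COD-equivalents of the soluble carbohydrate and protein
    assays, remainder to LCFA; particulate COD enters as composite with
    f_ch/f_pr/f_li from the particulate COD-equivalents, f_xI = the
    (calibrated) inert fraction, and f_sI = `f_si` (0 by default).
    """
    char.validate()
    if not (0.0 <= inert_fraction <= 1.0):
        raise ValueError(f"inert_fraction {inert_fraction} outside [0, 1]")
    if not (0.0 <= f_si <= 1.0 - inert_fraction):
        raise ValueError("f_si must lie in [0, 1 - inert_fraction]")

    cod_total = char.vs * ratio
    sol_share = char.soluble_cod_fraction
    sol_cod = sol_share * cod_total
    part_cod = cod_total - sol_cod

    # soluble allocation
    eq_su = COD_EQ_CARB * char.carb_sol
    eq_aa = COD_EQ_PROT * char.prot_sol
    if char.cod_sol > 0:
        phi_su = eq_su / char.cod_sol
        phi_aa = eq_aa / char.cod_sol
    else:
        phi_su = phi_aa = 0.0
    overshoot = phi_su + phi_aa - 1.0
    if overshoot > SOLUBLE_OVERSHOOT_TOL:
        raise ValueError(
            f"{char.name}: soluble carbohydrate+protein COD-equivalents "
            f"exceed measured soluble COD by {overshoot:.1%} "
            "(negative LCFA remainder)")
    if overshoot > 0:  # small assay inconsistency: renormalise, no LCFA pool
        phi_su, phi_aa = (phi_su / (phi_su + phi_aa),
                          phi_aa / (phi_su + phi_aa))
    phi_fa = max(1.0 - phi_su - phi_aa, 0.0)

    # particulate split from COD-equivalents
    p_ch = COD_EQ_CARB * max(char.carb_tot - char.carb_sol, 0.0)
    p_pr = COD_EQ_PROT * max(char.prot_tot - char.prot_sol, 0.0)
    p_li = COD_EQ_LIPID * char.lipids
    p_sum = p_ch + p_pr + p_li
    if p_sum <= 0 and part_cod > 0:
        raise ValueError(
            f"{char.name}: no particulate composition to split {part_cod} "
            "gCOD of particulate matter")
    degr = 1.0 - inert_fraction - f_si
    if p_sum > 0:
        f_ch = degr * p_ch / p_sum
        f_pr = degr * p_pr / p_sum
        f_li = degr * p_li / p_sum
    else:
        f_ch = f_pr = f_li = 0.0

    conc = np.zeros(c.N_CORE)
    conc[c.S_SU] = phi_su * sol_cod
    conc[c.S_AA] = phi_aa * sol_cod
    conc[c.S_FA] = phi_fa * sol_cod
    conc[c.X_C] = part_cod
    conc[c.S_IN] = s_IN
    conc[c.S_CAT] = s_cat
    conc[c.S_AN] = s_an

    prov = {
        "substrate": char.name,
        "phi_su": phi_su, "phi_aa": phi_aa, "phi_fa": phi_fa,
        "f_ch": f_ch, "f_pr": f_pr, "f_li": f_li,
        "f_xi": inert_fraction, "f_si": f_si,
        "soluble_share": sol_share,
    }
    return FeedSpec(conc, ratio, char.vs, prov)


def composite_split(spec: FeedSpec) -> dict[str, float]:
    """The disintegration split the feed implies, for AdmParams."""
    p = spec.provenance
    return {k: p[k] for k in ("f_si", "f_xi", "f_ch", "f_pr", "f_li")}


def feed_concentration(char: SubstrateCharacterization, olr: float,
                       hrt: float) -> tuple[float, float]:
    """Feed VS concentration realizing an OLR at a given HRT.

    Returns (VS_feed gVS/L, dilution factor from the stock VS).  The daily
    exchanged volume V/HRT at concentration OLR x HRT delivers OLR gVS per
    litre of reactor per day.
    """
    if olr < 0 or hrt <= 0:
        raise ValueError("OLR must be >= 0 and HRT > 0")
    vs_feed = olr * hrt
    if vs_feed > char.vs * (1 + 1e-9):
        raise ValueError(
            f"required feed VS {vs_feed} g/L exceeds stock VS {char.vs}; "
            "cannot concentrate by dilution")
    dilution = char.vs / vs_feed if vs_feed > 0 else np.inf
    return vs_feed, dilution
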