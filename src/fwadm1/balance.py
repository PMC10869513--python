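"""Biorefinery COD bookkeeping: equivalents table and platform balance.

Every measured product (sugars, VFAs, alcohols, gases) is converted to
gCOD with stoichiometric factors, and the two platform scenarios
(centrifugation only vs thermal pretreatment + centrifugation) are expressed
as per-node balances in gCOD per kg of raw feedstock.  Node residuals are
reported, never silently absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType

import numpy as np
import pandas as pd

from .feed import SubstrateCharacterization

# gCOD per g of compound
_MASS_FACTORS = {
    "carbohydrates": 1.1,
    "proteins": 1.5,
    "lignin": 1.56,
    "lipids": 2.9,
    "ethanol": 2.09,
    "lactate": 1.07,
    "acetic": 1.07,
    "propionic": 1.51,
    "butyric": 1.82,
    "isobutyric": 1.82,
    "valeric": 2.04,
    "isovaleric": 2.04,
    "caproic": 2.21,
}
# gCOD per normalized litre of gas (used exactly as conventionally assumed)
_GAS_FACTORS = {
    "hydrogen": 0.71,
    "methane": 2.86,
}


@dataclass(frozen=True)
class CodEquivalentTable:
    """Immutable-by-default factor table; override via `with_factors`."""

    mass_factors: MappingProxyType = field(
        default_factory=lambda: MappingProxyType(dict(_MASS_FACTORS)))
    gas_factors: MappingProxyType = field(
        default_factory=lambda: MappingProxyType(dict(_GAS_FACTORS)))

    def factor(self, compound: str) -> float:
        key = compound.lower()
        if key in self.mass_factors:
            return self.mass_factors[key]
        if key in self.gas_factors:
            return self.gas_factors[key]
        known = sorted([*self.mass_factors, *self.gas_factors])
        raise KeyError(
            f"unknown compound {compound!r}; accepted names: {known}")

    def with_factors(self, **overrides: float) -> "CodEquivalentTable":
        mf, gf = dict(self.mass_factors), dict(self.gas_factors)
        for k, v in overrides.items():
            if v <= 0:
                raise ValueError(f"factor for {k} must be > 0")
            (gf if k.lower() in gf else mf)[k.lower()] = v
        return CodEquivalentTable(MappingProxyType(mf), MappingProxyType(gf))


DEFAULT_TABLE = CodEquivalentTable()


def cod_equivalents(amounts: dict[str, float],
                    table: CodEquivalentTable = DEFAULT_TABLE
                    ) -> dict[str, float]:
    """gCOD per compound from masses (g) or normalized gas volumes (L)."""
    out = {}
    for compound, amount in amounts.items():
        if amount < 0:
            raise ValueError(f"negative amount for {compound!r}")
        out[compound] = amount * table.factor(compound)
    return out


@dataclass
class BalanceSheet:
    """Per-node COD balance of one platform scenario (gCOD per kg raw FW)."""

    scenario: str
    edges: pd.DataFrame           # columns: source, target, gcod
    residuals: dict[str, float]   # per-node closure residual

    def node_input(self, node: str) -> float:
        return float(self.edges.loc[self.edges.target == node, "gcod"].sum())

    def node_output(self, node: str) -> float:
        return float(self.edges.loc[self.edges.source == node, "gcod"].sum())

    def total_products(self) -> dict[str, float]:
        prod = self.edges[self.edges.target.str.startswith("product:")]
        return {t.split(":", 1)[1]: float(g)
                for t, g in zip(prod.target, prod.gcod)}

    def to_csv(self, path) -> None:
        self.edges.to_csv(path, index=False)


def _ferment_node(liquid_cod: float, yields: dict[str, float],
                  table: CodEquivalentTable,
                  edges: list, node: str) -> float:
    """Products of the fermentation node; returns unconverted COD."""
    converted = 0.0
    for compound, y in yields.items():
        if y < 0:
            raise ValueError(f"negative yield for {compound!r}")
        cod = y * liquid_cod * table.factor(compound)
        if cod > 0:
            edges.append((node, f"product:{compound}", cod))
            converted += cod
    if converted > liquid_cod * (1 + 1e-9):
        raise ValueError(
            f"fermentation products ({converted:.1f} gCOD) exceed the "
            f"liquid stream COD ({liquid_cod:.1f} gCOD)")
    return liquid_cod - converted


def _split_node(cod_in: float, solid: float, liquid: float,
                node: str, edges: list, residuals: dict) -> None:
    if solid + liquid > cod_in * 1.10:
        raise ValueError(
            f"{node}: split streams ({solid + liquid:.0f} gCOD) exceed the "
            f"input ({cod_in:.0f} gCOD) by more than 10%")
    edges.append((node, "solid residue", solid))
    edges.append((node, "liquid extract", liquid))
    residuals[node] = cod_in - solid - liquid


def platform_balance(raw: SubstrateCharacterization,
                     split_raw: tuple[SubstrateCharacterization,
                                      SubstrateCharacterization],
                     split_pre: tuple[SubstrateCharacterization,
                                      SubstrateCharacterization],
                     fermentation_yields: dict[str, dict[str, float]],
                     ad_smp: dict[str, float],
                     table: CodEquivalentTable = DEFAULT_TABLE
                     ) -> dict[str, BalanceSheet]:
    """Two-scenario COD balance of the platform, per kg of raw feedstock.

    Parameters
    ----------
    split_raw, split_pre : (solid residue, liquid extract) characterizations
        after centrifugation, without and with thermal pretreatment.
    fermentation_yields : per scenario, product amounts per gCOD of liquid
        extract fed to the fermenter (g/gCOD, or L/gCOD for gases).
    ad_smp : per scenario, digestion yield of the solid residue in
        Nm3 CH4 per kg VS fed.
    """
    sheets = {}
    for scenario, (solid, liquid) in (("raw", split_raw),
                                      ("pretreated", split_pre)):
        edges: list[tuple[str, str, float]] = []
        residuals: dict[str, float] = {}
        cod_in = raw.cod_tot
        edges.append(("raw FW", "separation", cod_in))
        _split_node(cod_in, solid.cod_tot, liquid.cod_tot, "separation",
                    edges, residuals)

        # liquid extract -> fermentation products
        yields = fermentation_yields.get(scenario, {})
        edges.append(("liquid extract", "fermentation", liquid.cod_tot))
        unconv = _ferment_node(liquid.cod_tot, yields, table, edges,
                               "fermentation")
        edges.append(("fermentation", "fermentation residue", unconv))

        # solid residue -> anaerobic digestion
        smp = ad_smp.get(scenario, 0.0)
        ch4_l = smp * solid.vs            # Nm3/kgVS * gVS/kg = NL per kg FW
        ch4_cod = ch4_l * table.factor("methane")
        if ch4_cod > solid.cod_tot * (1 + 1e-9):
            raise ValueError(
                f"{scenario}: methane COD {ch4_cod:.0f} exceeds the solid "
                f"residue COD {solid.cod_tot:.0f}")
        edges.append(("solid residue", "anaerobic digestion",
                      solid.cod_tot))
        if ch4_cod > 0:
            edges.append(("anaerobic digestion", "product:methane",
                          ch4_cod))
        edges.append(("anaerobic digestion", "digestate",
                      solid.cod_tot - ch4_cod))

        df = pd.DataFrame(edges, columns=["source", "target", "gcod"])
        sheets[scenario] = BalanceSheet(scenario, df, residuals)
    return sheets
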