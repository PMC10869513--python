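"""Shipped reference tables: substrate characterizations and steady states.

The characterization table covers the five streams of the bench platform
(raw feedstock, solid residues and liquid extracts with and without thermal
pretreatment); the steady-state table holds the feed/digestate assays of
the four semi-continuous experiments.  All values in g per kg of material
(COD columns g/L for the diluted feeds) with 1-sigma uncertainties in the
`*_sd` columns.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .feed import SubstrateCharacterization
from .io import load_characterization

STREAMS = ("raw_fw", "raw_solid_residue", "raw_liquid_extract",
           "pretreated_solid_residue", "pretreated_liquid_extract")


def _data_path(name: str):
    return resources.files("fwadm1.data") / name


def characterizations() -> dict[str, SubstrateCharacterization]:
    """All five substrate streams keyed by name."""
    with resources.as_file(_data_path("characterizations.csv")) as p:
        return load_characterization(p)


def characterization(stream: str) -> SubstrateCharacterization:
    chars = characterizations()
    if stream not in chars:
        raise KeyError(f"unknown stream {stream!r}; have {sorted(chars)}")
    return chars[stream]


def example_fermentation_yields() -> dict:
    """Illustrative per-scenario fermentation yields (g per gCOD fed)."""
    import yaml
    with resources.as_file(
            _data_path("example_fermentation_yields.yaml")) as p:
        return yaml.safe_load(p.read_text())


def steady_states() -> pd.DataFrame:
    """Feed and digestate assays of the four experiments (long format)."""
    with resources.as_file(_data_path("steady_states.csv")) as p:
        return pd.read_csv(p)


def experiment_feed(exp: str) -> pd.Series:
    df = steady_states()
    row = df[(df.experiment == exp) & (df.role == "feed")]
    if row.empty:
        raise KeyError(f"no feed row for experiment {exp!r}")
    return row.iloc[0]


def experiment_digestate(exp: str) -> pd.Series:
    df = steady_states()
    row = df[(df.experiment == exp) & (df.role == "digestate")]
    if row.empty:
        raise KeyError(f"no digestate row for experiment {exp!r}")
    return row.iloc[0]
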