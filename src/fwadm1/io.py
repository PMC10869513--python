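"""Reading and writing the package's delimited-text dialects.

Characterization tables: one row per substrate stream, g per kg of material,
columns `stream, ts, vs, cod_tot, cod_sol, carb_tot, carb_sol, prot_tot,
prot_sol, lipids, starch, lignocellulosics` (optional `<col>_sd`
uncertainty columns).  Observed series: two numeric columns (day, NL CH4).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .feed import SubstrateCharacterization
from .objectives import ObservedSeries

CHAR_COLUMNS = ("ts", "vs", "cod_tot", "cod_sol", "carb_tot", "carb_sol",
                "prot_tot", "prot_sol", "lipids", "starch",
                "lignocellulosics")


class SchemaError(ValueError):
    """A file does not match the documented header or its invariants."""


def load_characterization(path: str | Path, stream: str | None = None):
    """Load substrate characterizations from CSV.

    Returns a dict keyed by stream name, or a single object if `stream` is
    given.  Row order is irrelevant; missing columns, negative values and
    soluble>total violations raise `SchemaError` naming the offender.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty characterization file") from None
    if "stream" not in df.columns:
        raise SchemaError(f"{path}: missing column 'stream'")
    missing = [c for c in CHAR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    out: dict[str, SubstrateCharacterization] = {}
    for i, row in df.iterrows():
        sds = {c: float(row[f"{c}_sd"]) for c in CHAR_COLUMNS
               if f"{c}_sd" in df.columns and pd.notna(row[f"{c}_sd"])}
        try:
            out[str(row["stream"])] = SubstrateCharacterization(
                name=str(row["stream"]),
                **{c: float(row[c]) for c in CHAR_COLUMNS},
                uncertainties=sds)
        except (ValueError, TypeError) as err:
            raise SchemaError(f"{path}, row {i} "
                              f"({row['stream']!r}): {err}") from None
    if stream is not None:
        if stream not in out:
            raise KeyError(
                f"stream {stream!r} not in {path} (have {sorted(out)})")
        return out[stream]
    return out


def save_characterization(chars, path: str | Path) -> None:
    if isinstance(chars, SubstrateCharacterization):
        chars = [chars]
    elif isinstance(chars, dict):
        chars = list(chars.values())
    rows = []
    for ch in chars:
        row = {"stream": ch.name, **ch.as_dict()}
        for k, v in ch.uncertainties.items():
            row[f"{k}_sd"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_timeseries(path: str | Path) -> ObservedSeries:
    """Two-column CSV (day, NL CH4) -> validated, day-sorted series."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty series file") from None
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: need two columns (day, value)")
    day = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    val = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if day.isna().any() or val.isna().any():
        raise SchemaError(f"{path}: non-numeric entries in series")
    order = np.argsort(day.to_numpy(), kind="stable")
    d = day.to_numpy()[order]
    if np.any(np.diff(d) == 0):
        dup = int(d[np.where(np.diff(d) == 0)[0][0]])
        raise SchemaError(f"{path}: duplicated day {dup}")
    return ObservedSeries(d.astype(int), val.to_numpy()[order],
                          name=path.stem)


def save_timeseries(obs: ObservedSeries, path: str | Path) -> None:
    pd.DataFrame({"day": obs.days, "methane_nl": obs.methane_nl}
                 ).to_csv(path, index=False)


def file_sha256(path: str | Path) -> str:
    import hashlib
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
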