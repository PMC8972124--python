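"""Reading and writing the delimited-text table dialects.

All tables are plain CSV with ISO-8601 timestamps.  Output files carry a
provenance header of ``#``-prefixed comment lines (tool version, config
hash, seed) which the readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .exceptions import ConfigurationError, SchemaError

MET_REQUIRED = ["timestamp", "t_canopy_C", "rh_pct", "sw_global_Wm2"]
SAPFLOW_REQUIRED = ["timestamp", "vine_id", "sensor_flow_g_s"]
CANOPY_REQUIRED = ["date", "vine_id", "lai_m2m2", "porosity_frac"]


def _check_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing required columns: {missing}")


def read_met_csv(path) -> pd.DataFrame:
    """Read met.csv into a timestamp-indexed frame."""
    df = pd.read_csv(path, comment="#")
    _check_columns(df, MET_REQUIRED, "met table")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df.set_index("timestamp").sort_index()


def read_sapflow_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _check_columns(df, SAPFLOW_REQUIRED, "sap-flow table")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def read_canopy_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _check_columns(df, CANOPY_REQUIRED, "canopy survey table")
    df["date"] = pd.to_datetime(df["date"])
    return df


def read_config(path) -> dict:
    """Parse a ``key = value`` plain-text config file.

    Blank lines and ``#`` comments are ignored; values are parsed as JSON
    scalars where possible (numbers, booleans), else kept as strings.
    """
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        try:
            out[key] = json.loads(value)
        except json.JSONDecodeError:
            out[key] = value
    return out


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, *, provenance: dict | None = None,
                index: bool = False) -> None:
    """Write a table with a ``#``-prefixed provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            for key, value in provenance.items():
                fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=index)
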