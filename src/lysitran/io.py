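"""CSV schemas, validated readers/writers, configuration and run logs.

Standard schemas (all plain CSV, dates either ISO-8601 or integer days):

* ``microclimate``  — date, dar, ta, vpd, w
* ``weighing``      — date, w_morning, irrigation, return_flow
* ``growth``        — day, plant_height, stem_diameter, leaf_length,
  leaf_width[, lai]
* ``transpiration`` — date, td_mass, tm_depth, flag
* ``lai_daily``     — day, lai
* ``indicators``    — alternative, criterion, value, direction

If a microclimate file lacks ``vpd`` but has ``ta`` and ``rh``, VPD is
derived from the Tetens formula and the substitution is logged.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import __version__
from .exceptions import SchemaError
from .microclimate import vpd_from_ta_rh

logger = logging.getLogger("lysitran")

SCHEMAS: Dict[str, dict] = {
    "microclimate": {"required": ["date", "dar", "ta", "vpd", "w"], "key": "date"},
    "weighing": {
        "required": ["date", "w_morning", "irrigation", "return_flow"],
        "key": "date",
    },
    "growth": {
        "required": ["day", "plant_height", "stem_diameter", "leaf_length", "leaf_width"],
        "optional": ["lai"],
        "key": "day",
    },
    "transpiration": {"required": ["date", "td_mass", "tm_depth", "flag"], "key": "date"},
    "lai_daily": {"required": ["day", "lai"], "key": "day"},
    "indicators": {
        "required": ["alternative", "criterion", "value", "direction"],
        "key": None,
    },
}


def read_csv_schema(path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV against one of the documented schemas.

    Raises :class:`SchemaError` naming any missing column, on an empty
    file, or on duplicated key values (dates/days), listing offenders.
    """
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}")
    schema = SCHEMAS[schema_name]
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path} is empty") from None
    if df.empty:
        raise SchemaError(f"{path} contains no data rows")

    missing = [c for c in schema["required"] if c not in df.columns]
    if schema_name == "microclimate" and "vpd" in missing:
        if {"ta", "rh"}.issubset(df.columns):
            df["vpd"] = vpd_from_ta_rh(df["ta"].to_numpy(), df["rh"].to_numpy())
            missing.remove("vpd")
            logger.info("%s: derived vpd from ta and rh (Tetens)", path.name)
    if missing:
        raise SchemaError(f"{path} missing required column(s): {missing}")

    key = schema.get("key")
    if key and df[key].duplicated().any():
        dups = sorted(df.loc[df[key].duplicated(), key].unique().tolist())
        raise SchemaError(f"{path} has duplicated {key} values: {dups}")
    logger.info("%s: %d rows validated against %r schema", path.name, len(df), schema_name)
    return df


def write_csv(df: pd.DataFrame, path) -> Path:
    """Write a table losslessly (shortest round-tripping floats, ISO dates)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_config(path) -> dict:
    """Load a YAML pipeline configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash identifying a configuration."""
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_run_log(out_dir, subcommand: str, cfg: dict, seed: Optional[int]) -> Path:
    """Record package version, config hash and seed for reproducibility."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"run_{subcommand}.log"
    path.write_text(
        f"lysitran {__version__}\nsubcommand: {subcommand}\n"
        f"config_hash: {config_hash(cfg)}\nseed: {seed}\n"
    )
    return path
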