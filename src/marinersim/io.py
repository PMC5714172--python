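"""CSV/config readers and writers tying the stages into a pipeline.

All tabular data are small CSV files (gel quantifications are tables of
a few dozen lanes); configuration is JSON or YAML.  Every file written
through :func:`stamp_and_write` starts with a comment line carrying the
package version and a hash of the run configuration, and the readers
skip such comment lines, so outputs round-trip.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .mechanism_core import PRODUCT_LABELS
from .model_fit import QuantTable

__all__ = ["read_quant_table", "write_quant_table", "load_config",
           "config_hash", "stamp_and_write", "get_logger"]

logger = logging.getLogger("marinersim")


def get_logger(verbose: bool = False) -> logging.Logger:
    """Package logger writing to stderr (results never mix with logs)."""
    if not logger.handlers:
        handler = logging.StreamHandler()  # stderr
        handler.setFormatter(
            logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
    return logger


def read_quant_table(path) -> QuantTable:
    """Read a lane-fraction CSV (columns lane, f or time_h, SC, N, L, EX).

    ``BB`` (plasmid backbone) is accepted as an alias of ``EX``.
    Validation (fractions in range, row sums within 0.02 of 1) happens
    in the QuantTable constructor, which names the offending lane.
    """
    df = pd.read_csv(path, comment="#")
    if "BB" in df.columns and "EX" not in df.columns:
        df = df.rename(columns={"BB": "EX"})
    if "lane" not in df.columns:
        df.insert(0, "lane", range(1, len(df) + 1))
    if "f" in df.columns:
        series_type = "mixing"
    elif "time_h" in df.columns:
        series_type = "timecourse"
    else:
        raise ValueError(f"{path}: need an 'f' or 'time_h' column")
    missing = [c for c in PRODUCT_LABELS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing product columns {missing}")
    return QuantTable(df[["lane", "f" if series_type == "mixing" else "time_h",
                          *PRODUCT_LABELS]], series_type=series_type)


def write_quant_table(table: QuantTable, path,
                      config: Optional[dict] = None) -> None:
    stamp_and_write(table.table, path, config)


def config_hash(config: Optional[dict]) -> str:
    """Short stable hash of a run configuration."""
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def stamp_and_write(df: pd.DataFrame, path,
                    config: Optional[dict] = None) -> None:
    """Write a CSV prefixed with a version/config-hash comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# marinersim {__version__} config_sha256={config_hash(config)}\n")
        df.to_csv(fh, index=False)


def load_config(path) -> dict:
    """Load a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
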