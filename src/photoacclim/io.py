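"""Readers, writers, and configuration for the pipeline.

Gas-exchange tables are long-format CSV, one row per A/Ci step.  The reader
normalises instrument-export dialects onto canonical column names, validates
mandatory columns, and quarantines (rather than silently dropping or
crashing on) rows with unparseable numerics.  Output CSVs carry a comment
header recording the package version and a hash of the generating
configuration so results are traceable to their run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "ValidationReport",
    "CANONICAL_COLUMNS",
    "read_gas_exchange",
    "write_output_csv",
    "read_output_csv",
    "load_config",
    "config_hash",
]


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


# canonical name -> accepted aliases (case-insensitive)
CANONICAL_COLUMNS: dict[str, tuple[str, ...]] = {
    "tree_id": ("tree_id", "tree", "plant_id"),
    "species": ("species",),
    "year": ("year",),
    "t_growth": ("t_growth", "tgrow", "growth_temperature"),
    "co2_growth": ("co2_growth", "cgrow", "growth_co2"),
    "t_leaf": ("t_leaf", "tleaf", "tleafcnd"),
    "ca": ("ca",),
    "ci": ("ci",),
    "anet": ("anet", "a", "photo"),
    "gs": ("gs", "gsw", "cond"),
    "q": ("q", "qin", "ppfd", "pari"),
}
_NUMERIC = ("t_leaf", "ca", "ci", "anet", "gs", "q")
_MANDATORY = tuple(CANONICAL_COLUMNS)


@dataclass(frozen=True)
class ValidationReport:
    n_rows: int
    n_accepted: int
    n_quarantined: int
    messages: tuple[str, ...]


def read_gas_exchange(
    path: str | Path,
    column_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a long-format gas-exchange CSV.

    ``column_map`` maps source column names to canonical names and takes
    precedence over the built-in alias table.  Unknown columns are preserved
    as passthrough.  Rows with unparseable numerics are quarantined and
    reported, never silently kept.
    """
    raw = pd.read_csv(path, comment="#")
    rename: dict[str, str] = {}
    lower = {c.lower(): c for c in raw.columns}
    for canonical, aliases in CANONICAL_COLUMNS.items():
        for alias in aliases:
            if alias in lower:
                rename[lower[alias]] = canonical
                break
    if column_map:
        for src, canonical in column_map.items():
            if src in raw.columns:
                rename[src] = canonical
    table = raw.rename(columns=rename)
    for col in _MANDATORY:
        if col not in table.columns:
            raise SchemaError(f"missing mandatory column: {col}")

    messages: list[str] = []
    bad = np.zeros(len(table), dtype=bool)
    for col in _NUMERIC:
        coerced = pd.to_numeric(table[col], errors="coerce")
        newly_bad = coerced.isna() & table[col].notna()
        if newly_bad.any():
            messages.append(
                f"{int(newly_bad.sum())} row(s) quarantined: unparseable {col}"
            )
        bad |= newly_bad.to_numpy()
        table[col] = coerced
    accepted = table[~bad].reset_index(drop=True)
    report = ValidationReport(
        n_rows=len(table),
        n_accepted=len(accepted),
        n_quarantined=int(bad.sum()),
        messages=tuple(messages),
    )
    return accepted, report


# ---------------------------------------------------------------------------
# traceable output CSVs
# ---------------------------------------------------------------------------


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_output_csv(
    df: pd.DataFrame, path: str | Path, version: str, cfg_hash: str
) -> None:
    """Write a CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# photoacclim {version} config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def read_output_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON pipeline configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
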