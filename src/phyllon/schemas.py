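"""CSV schemas, input validation, and run configuration.

Validation never coerces silently: a malformed table produces a
:class:`phyllon.errors.SchemaError` carrying line-numbered messages (row
numbers refer to the data rows of the CSV, first data row = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .budget import MeadowParams
from .errors import ConfigError, SchemaError

#: records CSV: column -> (required, kind)
RECORD_SCHEMA = {
    "experiment": (True, "category"),
    "site": (True, "category"),
    "light": (True, "category"),
    "epiphytes": (True, "category"),
    "tracer": (True, "category"),
    "role": (True, "category"),
    "timepoint_h": (True, "number"),
    "replicate_id": (True, "label"),
    "vial_volume_mL": (True, "number"),
    "atom_pct_15n_tissue": (False, "number"),
    "pn_tissue_ug": (False, "number"),
    "c_pct": (False, "number"),
    "n_pct": (False, "number"),
    "leaf_area_cm2": (False, "number"),
    "conc_29n2_nM": (False, "number"),
    "conc_30n2_nM": (False, "number"),
    "delta15n_no3_permil": (False, "number"),
    "nh4_uM": (False, "number"),
    "no2_uM": (False, "number"),
    "nox_uM": (False, "number"),
    "po4_uM": (False, "number"),
}

_CATEGORIES = {
    "experiment": {"n2_fixation", "nitrification", "n2_production", "nutrient_flux"},
    "site": {"ambient", "vent"},
    "light": {"light", "dark"},
    "epiphytes": {"present", "removed", "none"},
    "tracer": {"15N2", "15NH4", "15NO3"},
    "role": {"sample", "baseline", "control"},
}

_NON_NEGATIVE = ["timepoint_h", "conc_29n2_nM", "conc_30n2_nM",
                 "nh4_uM", "no2_uM", "nox_uM", "po4_uM"]
_POSITIVE = ["vial_volume_mL", "leaf_area_cm2", "pn_tissue_ug"]


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a records table against the schema; return it unchanged.

    Raises :class:`SchemaError` listing every problem with its row number.
    """
    errors: list[str] = []
    for col, (required, _) in RECORD_SCHEMA.items():
        if required and col not in df.columns:
            errors.append(f"missing required column {col!r}")
    unknown = [c for c in df.columns if c not in RECORD_SCHEMA]
    for c in unknown:
        errors.append(f"unknown column {c!r}")
    if errors:
        raise SchemaError(errors)

    for col, allowed in _CATEGORIES.items():
        bad = ~df[col].isin(allowed)
        for idx in df.index[bad]:
            errors.append(f"row {idx + 1}: {col}={df.loc[idx, col]!r} not in {sorted(allowed)}")
    for col in _NON_NEGATIVE:
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.notna() & (vals < 0)
            for idx in df.index[bad]:
                errors.append(f"row {idx + 1}: {col} must be >= 0, got {df.loc[idx, col]}")
    for col in _POSITIVE:
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.notna() & (vals <= 0)
            for idx in df.index[bad]:
                errors.append(f"row {idx + 1}: {col} must be > 0, got {df.loc[idx, col]}")
    if "nox_uM" in df.columns and "no2_uM" in df.columns:
        nox = pd.to_numeric(df["nox_uM"], errors="coerce")
        no2 = pd.to_numeric(df["no2_uM"], errors="coerce")
        bad = nox.notna() & no2.notna() & (nox < no2)
        for idx in df.index[bad]:
            errors.append(f"row {idx + 1}: nox_uM ({nox[idx]}) < no2_uM ({no2[idx]})")
    if errors:
        raise SchemaError(errors)
    return df


def read_records(path) -> pd.DataFrame:
    """Read and validate a records CSV."""
    return validate_records(pd.read_csv(path))


@dataclass
class RunConfig:
    """Parsed run configuration (see ``phyllon.cli`` for the YAML layout)."""

    meadow: dict[str, MeadowParams]
    medium_atom_pct: dict = field(default_factory=dict)
    r_air_15n: float = 0.0036765
    molar_mass_n: float = 14.0067
    pseudocount: float = 0.5
    gate_k: float = 2.5
    n2_as_molecules: bool = False
    emit_umol: bool = False
    seed: int = 0
    exclude_replicates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.r_air_15n > 0:
            raise ConfigError("r_air_15n must be > 0")
        if not 13.9 < self.molar_mass_n < 14.1:
            raise ConfigError("molar_mass_n must lie in (13.9, 14.1)")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be > 0")
        if self.gate_k <= 0:
            raise ConfigError("gate_k must be > 0")


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; raises :class:`ConfigError` on bad values."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    meadow_raw = raw.pop("meadow", None)
    if not meadow_raw:
        raise ConfigError("config needs a 'meadow' section with per-site parameters")
    try:
        meadow = {site: MeadowParams(**params) for site, params in meadow_raw.items()}
    except TypeError as exc:
        raise ConfigError(f"bad meadow parameters: {exc}") from exc
    known = {f for f in RunConfig.__dataclass_fields__ if f != "meadow"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(meadow=meadow, **raw)


def apply_exclusions(df: pd.DataFrame, exclude_replicates) -> pd.DataFrame:
    """Drop explicitly excluded (experiment, site, light, epiphytes, replicate_id) rows.

    Exclusion entries are mappings; omitted keys match anything. This is the
    only outlier-removal mechanism — nothing is dropped automatically.
    """
    if not exclude_replicates:
        return df
    keep = np.ones(len(df), dtype=bool)
    for entry in exclude_replicates:
        mask = np.ones(len(df), dtype=bool)
        for key, val in entry.items():
            if key not in df.columns:
                raise ConfigError(f"exclusion key {key!r} is not a records column")
            mask &= (df[key] == val).to_numpy()
        keep &= ~mask
    return df[keep].reset_index(drop=True)
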