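"""Cohort table I/O and run configuration.

The canonical cohort CSV schema is a UTF-8, comma-delimited file with a
header row and columns ``id, sex, age, hb_g_l, mcv_fl, gi_cancer``.  Sex
accepts 0/1 or the strings M/F, male/female (case-insensitive, 1 = male).
A ``column_map`` lets differently named files be read without editing them.
An optional boolean ``exclude`` column marks rows to drop (clinical
exclusions such as non-GI malignancies are upstream data preparation, not
computable from the five modelling variables).  Exact duplicate rows are
dropped with a logged count; rows missing any required field are rejected
with a logged count.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import validate_covariates

logger = logging.getLogger(__name__)

__all__ = ["read_cohort_csv", "write_cohort_csv", "load_run_config"]

#: canonical column names, keyed by the internal field name
CANONICAL_COLUMNS = {
    "sex": "sex",
    "age": "age",
    "hb": "hb_g_l",
    "mcv": "mcv_fl",
    "outcome": "gi_cancer",
}

_SEX_CODES = {
    "m": 1, "male": 1, "1": 1,
    "f": 0, "female": 0, "0": 0,
}


def _map_sex(values: pd.Series) -> pd.Series:
    def one(v):
        key = str(v).strip().lower()
        if key in _SEX_CODES:
            return _SEX_CODES[key]
        try:
            num = float(key)
        except ValueError:
            raise ValueError(f"unparseable sex value {v!r} (expected M/F or 0/1)")
        if num in (0.0, 1.0):
            return int(num)
        raise ValueError(f"unparseable sex value {v!r} (expected M/F or 0/1)")

    return values.map(one)


def read_cohort_csv(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    *,
    require_outcome: bool = True,
    strict_ranges: bool = False,
) -> pd.DataFrame:
    """Read a cohort table into the internal schema (sex, age, hb, mcv[, outcome]).

    ``column_map`` maps internal field names to the file's column names for
    files that deviate from the canonical schema.  Set
    ``require_outcome=False`` for scoring-only inputs without an outcome
    column.
    """
    path = Path(path)
    raw = pd.read_csv(path, float_precision="round_trip")
    if raw.empty:
        raise ValueError(f"{path} contains no data rows")

    colmap = dict(CANONICAL_COLUMNS)
    if column_map:
        colmap.update(column_map)
    required = ["sex", "age", "hb", "mcv"] + (["outcome"] if require_outcome else [])
    missing = [f for f in required if colmap[f] not in raw.columns]
    if missing:
        raise ValueError(
            f"{path} is missing required column(s): "
            + ", ".join(colmap[f] for f in missing)
        )

    n0 = len(raw)
    raw = raw.drop_duplicates()
    n_dup = n0 - len(raw)
    if n_dup:
        logger.info("%s: removed %d exact duplicate row(s)", path.name, n_dup)

    if "exclude" in raw.columns:
        flag = raw["exclude"].astype(bool)
        if flag.any():
            logger.info("%s: dropped %d row(s) flagged for exclusion", path.name, int(flag.sum()))
        raw = raw.loc[~flag]

    fields = {f: raw[colmap[f]] for f in required}
    cohort = pd.DataFrame(index=raw.index)
    cohort["sex"] = _map_sex(fields["sex"])
    for f in ("age", "hb", "mcv"):
        cohort[f] = pd.to_numeric(fields[f], errors="coerce")
    if require_outcome:
        cohort["outcome"] = pd.to_numeric(fields["outcome"], errors="coerce")
        bad = ~cohort["outcome"].isin([0, 1]) & cohort["outcome"].notna()
        if bad.any():
            raise ValueError(f"{path}: outcome column contains non-binary values")

    incomplete = cohort.isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "%s: rejected %d row(s) with missing required field(s)",
            path.name,
            int(incomplete.sum()),
        )
        cohort = cohort.loc[~incomplete]
    if cohort.empty:
        raise ValueError(f"{path}: no valid rows remain after cleaning")

    if "id" in raw.columns:
        cohort.insert(0, "id", raw.loc[cohort.index, "id"])
    cohort = cohort.reset_index(drop=True)
    if require_outcome:
        cohort["outcome"] = cohort["outcome"].astype(int)
    validate_covariates(cohort, strict=strict_ranges)
    return cohort


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort in the canonical CSV schema (inverse of ``read_cohort_csv``)."""
    out = pd.DataFrame()
    if "id" in cohort.columns:
        out["id"] = cohort["id"]
    else:
        out["id"] = np.arange(1, len(cohort) + 1)
    for field, column in CANONICAL_COLUMNS.items():
        if field in cohort.columns:
            out[column] = np.asarray(cohort[field])
    out.to_csv(path, index=False)


def load_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration mirroring the CLI flags."""
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError(f"{path}: run configuration must be a mapping")
    return config
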