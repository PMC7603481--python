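"""Reading and validating resighting tables and writing result files."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from cobreed.association import validate_resightings
from cobreed.errors import DataError
from cobreed.simulate import RESIGHTING_COLUMNS

logger = logging.getLogger(__name__)


def read_resightings(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a resighting CSV.

    The file must carry the header ``individual_id,year,colony,patch_id``.
    Years must parse as integers and ids must be non-empty; violations are
    reported with their line number. Duplicate (individual, year) rows are
    rejected (strict, default) or collapsed to the first with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != list(RESIGHTING_COLUMNS):
        raise DataError(
            f"{path}: expected header {','.join(RESIGHTING_COLUMNS)}, "
            f"got {','.join(df.columns)}"
        )
    if len(df) == 0:
        logger.warning("%s: empty resighting table", path)
        df["year"] = df["year"].astype(int)
        return df
    years = pd.to_numeric(df["year"], errors="coerce")
    bad = years.isna() | (years != years.round())
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise DataError(
            f"{path}: malformed year {df.loc[bad.idxmax(), 'year']!r} at line {line}"
        )
    df["year"] = years.astype(int)
    empty = (df["individual_id"].str.len() == 0) | (df["patch_id"].str.len() == 0)
    if empty.any():
        line = int(np.flatnonzero(empty.to_numpy())[0]) + 2
        raise DataError(f"{path}: empty individual or patch id at line {line}")
    df = validate_resightings(df, strict=strict)
    logger.info(
        "%s: %d rows, %d individuals, years %d-%d",
        path, len(df), df["individual_id"].nunique(),
        df["year"].min(), df["year"].max(),
    )
    return df


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _to_jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj: dict, path: str | Path) -> None:
    """Deterministic JSON dump (sorted keys, stable float repr)."""
    Path(path).write_text(
        json.dumps(_to_jsonable(obj), indent=2, sort_keys=True) + "\n"
    )
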