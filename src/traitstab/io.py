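"""CSV readers/writers for the pipeline's tabular interchange formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .constants import (
    SURVEY_COLUMNS,
    TRAIT_MEASUREMENT_COLUMNS,
    TRAIT_NAMES,
    DataError,
)


def read_survey_csv(path) -> pd.DataFrame:
    """Long-format survey: one row per measured individual plus count-only
    rows (empty ``fork_length_mm``) carrying the unmeasured remainder."""
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"survey CSV missing columns: {missing}")
    df = df[list(SURVEY_COLUMNS)]
    df["count"] = df["count"].astype(int)
    if (df["count"] < 0).any():
        raise DataError("negative counts in survey")
    df["fork_length_mm"] = pd.to_numeric(df["fork_length_mm"], errors="coerce")
    return df


def read_trait_measurements_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRAIT_MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"trait CSV missing columns: {missing}")
    unknown = sorted(set(df["trait"]) - set(TRAIT_NAMES))
    if unknown:
        raise DataError(f"unknown trait names: {unknown}")
    return df[list(TRAIT_MEASUREMENT_COLUMNS)]


def read_feeding_mode_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "species" not in df.columns or "feeding_mode" not in df.columns:
        raise DataError("lookup CSV needs 'species' and 'feeding_mode' columns")
    return df


def write_matrix_csv(matrix: pd.DataFrame, path) -> None:
    """Pond x year matrix with a two-column (pond, year) row index."""
    out = matrix.copy()
    out.index = pd.MultiIndex.from_tuples(list(out.index), names=["pond", "year"])
    out.reset_index().to_csv(path, index=False)


def read_matrix_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.columns[0] != "pond" or df.columns[1] != "year":
        raise DataError("matrix CSV must start with pond,year columns")
    return df.set_index(["pond", "year"])


def write_distance_csv(D, path) -> None:
    D.to_dataframe().to_csv(path)


def ensure_exists(path, kind: str) -> Path:
    p = Path(path)
    if not p.is_file():
        raise DataError(f"{kind} file not found: {p}")
    return p
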