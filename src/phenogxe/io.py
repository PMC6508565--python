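"""Table and image I/O for the long-format experiment schema.

Everything is plain comma-separated text (plus PNG for images): trait
tables (plant_id, genotype, treatment, day, area, ...), hue-histogram
tables (identifier columns followed by hue_000..hue_359), and long ionome
tables (sample_id, genotype, treatment, rep, element, ppm).  Schema
problems are reported with the offending row numbers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

TRAIT_KEY_COLS = ["plant_id", "genotype", "treatment", "day"]
IONOME_COLS = ["sample_id", "genotype", "treatment", "rep", "element", "ppm"]


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _check_numeric(df: pd.DataFrame, col: str, path, integer: bool = False):
    raw = df[col]
    coerced = pd.to_numeric(raw, errors="coerce")
    bad = coerced.isna() & raw.notna()
    if bad.any():
        rows = list(np.nonzero(bad.to_numpy())[0][:5])
        raise SchemaError(f"{path}: non-numeric {col!r} at row(s) {rows}")
    if integer:
        frac = coerced.dropna() % 1
        if (frac != 0).any():
            rows = list(frac.index[frac != 0][:5])
            raise SchemaError(f"{path}: non-integer {col!r} at row(s) {rows}")
        return coerced.astype("Int64").astype(int)
    return coerced


def read_trait_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, TRAIT_KEY_COLS + ["area"], path)
    df["day"] = _check_numeric(df, "day", path, integer=True)
    df["area"] = _check_numeric(df, "area", path)
    df["treatment"] = df["treatment"].astype(str)
    return df


def write_trait_table(table: pd.DataFrame, path) -> None:
    _check_columns(table, TRAIT_KEY_COLS + ["area"], path)
    table.to_csv(path, index=False)


def read_hue_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    hue_cols = [c for c in df.columns if c.startswith("hue_")]
    if len(hue_cols) != 360:
        raise SchemaError(f"{path}: expected 360 hue_* columns, found {len(hue_cols)}")
    return df


def write_hue_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_ionome_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, IONOME_COLS, path)
    df["ppm"] = _check_numeric(df, "ppm", path)
    return df


def write_ionome_table(table: pd.DataFrame, path) -> None:
    _check_columns(table, IONOME_COLS, path)
    table.to_csv(path, index=False)


def write_image(path, image: np.ndarray) -> None:
    import imageio.v3 as iio
    iio.imwrite(Path(path), image)


def read_image(path) -> np.ndarray:
    import imageio.v3 as iio
    return np.asarray(iio.imread(Path(path)))


def write_mask(path, mask: np.ndarray) -> None:
    import imageio.v3 as iio
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def read_mask(path) -> np.ndarray:
    import imageio.v3 as iio
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127
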