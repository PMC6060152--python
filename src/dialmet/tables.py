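"""Readers and writers for the pipeline's tidy TSV tables.

All tables are long/tidy TSV with a one-line header; missing values are
encoded as an empty field.  Four dialects are used:

* long sample table  — mouse, group, region, analyte, bin, intensity
* wake fractions     — mouse, bin, wake_fraction
* EEG band power     — mouse, hour, band, power
* spectral features  — mass, rt, mouse, region, bin, intensity
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .config import BANDS, IntegrityError, SchemaError, StudyDesign, log

LONG_COLUMNS = ["mouse", "group", "region", "analyte", "bin", "intensity"]
WAKE_COLUMNS = ["mouse", "bin", "wake_fraction"]
BAND_COLUMNS = ["mouse", "hour", "band", "power"]
FEATURE_COLUMNS = ["mass", "rt", "mouse", "region", "bin", "intensity"]

_KEY = ["mouse", "region", "analyte", "bin"]


def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, sep="\t", dtype={"mouse": str}, float_precision="round_trip"
    )
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df[columns]


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def validate_long_table(df: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Check schema/integrity of a long sample table and normalize dtypes."""
    df = df.copy()
    df["bin"] = df["bin"].astype(int)
    df["intensity"] = pd.to_numeric(df["intensity"], errors="coerce")

    bad_groups = set(df["group"]) - set(design.group_names)
    if bad_groups:
        raise SchemaError(f"unknown group labels: {sorted(bad_groups)}")
    bad_regions = set(df["region"]) - set(design.regions)
    if bad_regions:
        raise SchemaError(f"unknown region labels: {sorted(bad_regions)}")
    if df.duplicated(_KEY).any():
        dupes = df.loc[df.duplicated(_KEY), _KEY].head()
        raise IntegrityError(f"duplicate (mouse,region,analyte,bin) keys:\n{dupes}")
    mg = df.groupby("mouse")["group"].nunique()
    if (mg > 1).any():
        raise IntegrityError(
            f"mice assigned to multiple groups: {list(mg[mg > 1].index)}"
        )
    if (df["intensity"].dropna() < 0).any():
        raise SchemaError("negative intensities present")
    if (df["bin"] < 0).any() or (df["bin"] >= design.bins_per_mouse).any():
        raise SchemaError("bin index out of range for design")
    return df


def read_long_table(path: str | Path, design: StudyDesign) -> pd.DataFrame:
    df = validate_long_table(_read_tsv(path, LONG_COLUMNS), design)
    log.info("read %d sample rows from %s", len(df), path)
    return df


def write_long_table(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df[LONG_COLUMNS], path)


def read_wake_fractions(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, WAKE_COLUMNS)
    df["bin"] = df["bin"].astype(int)
    df["wake_fraction"] = df["wake_fraction"].astype(float)
    if df.duplicated(["mouse", "bin"]).any():
        raise IntegrityError("duplicate (mouse, bin) in wake fractions")
    frac = df["wake_fraction"]
    if ((frac < 0) | (frac > 1)).any():
        raise SchemaError("wake_fraction outside [0, 1]")
    return df


def write_wake_fractions(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df[WAKE_COLUMNS], path)


def read_band_power(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, BAND_COLUMNS)
    df["hour"] = df["hour"].astype(int)
    df["power"] = df["power"].astype(float)
    bad = set(df["band"]) - set(BANDS)
    if bad:
        raise SchemaError(f"unknown EEG bands: {sorted(bad)}")
    if (df["power"] <= 0).any():
        raise SchemaError("band power must be positive")
    return df


def write_band_power(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df[BAND_COLUMNS], path)


def read_features(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, FEATURE_COLUMNS)
    df["bin"] = df["bin"].astype(int)
    for col in ("mass", "rt", "intensity"):
        df[col] = df[col].astype(float)
    if (df["mass"] <= 0).any() or (df["rt"] < 0).any():
        raise SchemaError("features require mass > 0 and rt >= 0")
    return df


def write_features(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df[FEATURE_COLUMNS], path)


def empty_long_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mouse": pd.Series(dtype=str),
            "group": pd.Series(dtype=str),
            "region": pd.Series(dtype=str),
            "analyte": pd.Series(dtype=str),
            "bin": pd.Series(dtype=int),
            "intensity": pd.Series(dtype=float),
        }
    )
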