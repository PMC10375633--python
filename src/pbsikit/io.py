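"""Validated CSV/TSV readers and writers for the pipeline's tables.

Sex is stored as M/F and diagnosis as ASD/NC in files; both are mapped to
internal encodings (sex 0/1) on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pbsi import ProfileMatrix

__all__ = [
    "read_table",
    "write_table",
    "read_profiles",
    "write_profiles",
    "read_phenotypes",
    "write_phenotypes",
    "read_expression",
    "write_expression",
]

_SEX_TO_INT = {"M": 0, "F": 1}
_INT_TO_SEX = {0: "M", 1: "F"}


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() == ".tsv" else ","


def read_table(
    path: str | Path,
    required: tuple[str, ...] = (),
    numeric: tuple[str, ...] = (),
    unique: str | None = None,
) -> pd.DataFrame:
    """Read a delimited table with schema checks.

    ``required`` columns must be present, ``numeric`` ones fully numeric, and
    values in the ``unique`` column must not repeat.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(path), float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            raise ValueError(
                f"{path}: non-numeric value(s) in column {col!r}: "
                f"{df.loc[bad, col].head(3).tolist()}"
            )
        df[col] = coerced
    if unique is not None and df[unique].duplicated().any():
        dupes = df.loc[df[unique].duplicated(), unique].tolist()
        raise ValueError(f"{path}: duplicate {unique} value(s): {dupes[:5]}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips float64 exactly
    df.to_csv(path, sep=_sep(path), index=index, float_format="%.17g")
    return path


def write_profiles(profiles: ProfileMatrix, path: str | Path) -> Path:
    df = profiles.to_dataframe().reset_index()
    return write_table(df, path)


def read_profiles(path: str | Path) -> ProfileMatrix:
    df = read_table(path, required=("subject_id",), unique="subject_id")
    df = df.set_index("subject_id")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: profile table contains missing values")
    return ProfileMatrix(values=values, subject_ids=[str(s) for s in df.index],
                         region_labels=[str(c) for c in df.columns])


PHENOTYPE_NUMERIC = ("age", "tiv", "fiq", "adi_rrb", "adi_soc", "adi_ver")


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> Path:
    out = phenotypes.copy()
    if out["sex"].dtype != object:
        out["sex"] = out["sex"].map(_INT_TO_SEX)
    return write_table(out, path)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = read_table(
        path,
        required=("subject_id", "age", "sex", "site", "dx"),
        numeric=tuple(c for c in PHENOTYPE_NUMERIC),
        unique="subject_id",
    )
    if df["sex"].dtype == object:
        unknown = set(df["sex"].dropna()) - set(_SEX_TO_INT)
        if unknown:
            raise ValueError(f"{path}: unknown sex code(s) {sorted(unknown)}")
        df["sex"] = df["sex"].map(_SEX_TO_INT)
    bad_dx = set(df["dx"].dropna()) - {"ASD", "NC"}
    if bad_dx:
        raise ValueError(f"{path}: unknown diagnosis label(s) {sorted(bad_dx)}")
    return df


def write_expression(expression: pd.DataFrame, path: str | Path) -> Path:
    return write_table(expression.reset_index(), path)


def read_expression(path: str | Path) -> pd.DataFrame:
    df = read_table(path, required=("gene_id",), unique="gene_id")
    return df.set_index("gene_id")
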