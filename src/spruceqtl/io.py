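"""Readers and writers for the pipeline's tabular formats.

All tables are TSV with header rows and "NA" for missing values.  Readers
validate schemas up front (missing columns, duplicate markers, non-numeric
or unsorted cM) and raise with file context so malformed inputs fail loudly
rather than propagating.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_READ_KW = dict(sep="\t", na_values=["NA"], keep_default_na=False)
_WRITE_KW = dict(sep="\t", na_rep="NA")

MAP_COLUMNS = ["marker", "lg", "cm"]
QTL_WRITE_COLUMNS = {
    "cm": "cM",
}


class TableError(ValueError):
    """Schema or content problem in an input table."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing column(s) {missing}")


def read_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, **_READ_KW)
    _require_columns(df, MAP_COLUMNS, path)
    dup = df["marker"][df["marker"].duplicated()]
    if not dup.empty:
        raise TableError(f"{path}: duplicate marker id(s) {sorted(set(dup))}")
    try:
        df["cm"] = pd.to_numeric(df["cm"])
    except (ValueError, TypeError) as exc:
        raise TableError(f"{path}: non-numeric cM position ({exc})") from exc
    if df["cm"].isna().any():
        rows = df.index[df["cm"].isna()].tolist()
        raise TableError(f"{path}: non-numeric cM position at row(s) {rows}")
    for lg, sub in df.groupby("lg"):
        if np.any(np.diff(sub["cm"].to_numpy()) < 0):
            raise TableError(f"{path}: cM positions not sorted within linkage group {lg}")
    logger.info("read map %s: %d markers on %d linkage groups",
                path, len(df), df["lg"].nunique())
    return df[MAP_COLUMNS + [c for c in df.columns if c not in MAP_COLUMNS]]


def write_map(map_df: pd.DataFrame, path) -> None:
    map_df.to_csv(path, index=False, **_WRITE_KW)


def read_transmissions(directory) -> dict[str, pd.DataFrame]:
    """Read ``transmissions_<parent>.tsv`` files from a directory."""
    directory = Path(directory)
    paths = sorted(directory.glob("transmissions_*.tsv"))
    if not paths:
        raise TableError(f"{directory}: no transmissions_<parent>.tsv files found")
    out = {}
    for p in paths:
        parent = p.stem.removeprefix("transmissions_")
        df = pd.read_csv(p, index_col=0, **_READ_KW)
        bad = df.stack().pipe(lambda s: s[~s.isin([1.0, 2.0])])
        if not bad.empty:
            raise TableError(f"{p}: transmission codes must be 1, 2 or NA")
        df.index.name = "progeny"
        out[parent] = df
    return out


def write_transmissions(transmissions: dict[str, pd.DataFrame], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for parent, tm in transmissions.items():
        tm.to_csv(directory / f"transmissions_{parent}.tsv", **_WRITE_KW)


def read_matrix(path, index_name: str = "individual") -> pd.DataFrame:
    """Numeric matrix (expression, intensities) with a leading id column."""
    df = pd.read_csv(path, index_col=0, **_READ_KW)
    df.index.name = index_name
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise TableError(f"{path}: non-numeric column(s) {non_numeric}")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, **_WRITE_KW)


def read_phenotypes(path, known_traits: list[str] | None = None) -> pd.DataFrame:
    df = read_matrix(path, index_name="individual")
    if known_traits:
        unknown = [c for c in df.columns if c not in known_traits]
        if unknown:
            logger.warning("%s: unknown trait column(s) %s carried through", path, unknown)
    return df


def read_samplesheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, **_READ_KW)
    _require_columns(df, ["channel", "individual", "dye"], path)
    return df.set_index("channel")


def write_samplesheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, **_WRITE_KW)


def read_qtl_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, **_READ_KW)
    df = df.rename(columns={"cM": "cm"})
    _require_columns(df, ["trait", "marker", "lg", "cm", "parent", "lod"], path)
    return df


def write_qtl_table(qtl: pd.DataFrame, path) -> None:
    out = qtl.rename(columns=QTL_WRITE_COLUMNS)
    out.to_csv(path, index=False, **_WRITE_KW)


def read_crosses(path) -> pd.Series:
    """progeny -> cross membership table."""
    df = pd.read_csv(path, **_READ_KW)
    _require_columns(df, ["progeny", "cross"], path)
    return df.set_index("progeny")["cross"]


def write_crosses(cross_df: pd.DataFrame, path) -> None:
    cross_df.to_csv(path, **_WRITE_KW)
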