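"""TSV readers/writers for the pipeline's tables.

All artifacts are tab-separated text with a header row; matrices carry
probe ids in the first column and sample ids in the header.  "NA" cells
parse to missing values and "Inf"/"-Inf" to infinities, so the NA/Inf
probe filter sees exactly what was written.  Round-trips are lossless to
full float precision.
"""

from __future__ import annotations

import pandas as pd

from .errors import ParseError

__all__ = [
    "read_expression", "write_expression", "read_metadata", "write_metadata",
    "read_annotation", "write_table", "read_table",
]

_FLOAT_FMT = "%.10g"


def _check_unique(index: pd.Index, what: str, path) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()[:5]
        raise ParseError(f"{path}: duplicate {what} ids: {dupes}")


def read_expression(path) -> pd.DataFrame:
    """Probe x sample matrix from TSV (probe ids in the first column)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0,
                         keep_default_na=False,
                         na_values=["NA", "NaN", "nan", ""])
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    _check_unique(df.index, "probe", path)
    _check_unique(df.columns, "sample", path)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: non-numeric cell in column "
                             f"'{col}': {exc}") from exc
    df.index.name = "probe_id"
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT)


read_detection = read_expression
write_detection = write_expression


def read_metadata(path) -> pd.DataFrame:
    """Per-sample table: diagnosis, age, sex, ethnicity, rin, batch."""
    df = pd.read_csv(path, sep="\t", index_col=0,
                     keep_default_na=False,
                     na_values=["NA", "NaN", "nan", ""])
    _check_unique(df.index, "sample", path)
    df.index.name = "sample_id"
    df.index = df.index.astype(str)
    for col in ("age", "rin"):
        if col in df:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "batch" in df:
        df["batch"] = df["batch"].astype(str)
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT)


def read_annotation(path) -> pd.DataFrame:
    """Per-probe table: gene_symbol and snp_in_probe flag."""
    df = pd.read_csv(path, sep="\t", index_col=0,
                     keep_default_na=False,
                     na_values=["NA", ""])
    _check_unique(df.index, "probe", path)
    df.index.name = "probe_id"
    if "snp_in_probe" in df:
        df["snp_in_probe"] = df["snp_in_probe"].astype(str).str.lower().isin(
            ["true", "1", "yes"])
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index=index,
              float_format=_FLOAT_FMT)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col,
                       keep_default_na=False,
                       na_values=["NA", "NaN", "nan", ""])
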