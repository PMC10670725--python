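"""Tab-separated table I/O with light schema validation.

Dialect: tab-separated, UTF-8, ``#`` starts a comment line, ``.`` encodes
a missing value.  ``read_table``/``write_table`` round-trip any results
table; named readers validate the fixed schemas and build the in-memory
containers the analysis modules expect.
"""

from __future__ import annotations

import pathlib

import pandas as pd

from .diffexpr import CountMatrix

SCHEMAS = {
    "samples": ["sample", "condition"],
    "proteins": ["gene", "direction"],
    "interactions": ["mirna", "gene", "support_type", "database"],
    "clinical": ["sample", "t_stage", "os_time", "os_event"],
    "de_result": ["feature", "base_mean", "log2fc", "se", "wald_stat",
                  "p_value", "p_adj", "call"],
}


class SchemaError(ValueError):
    """A table's header does not match the expected schema."""


def read_table(path, schema: list | None = None) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", na_values=["."], keep_default_na=False
    )
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        extra = [c for c in df.columns if c not in schema]
        if missing or extra:
            raise SchemaError(
                f"{path}: missing columns {missing}, unexpected columns {extra}"
            )
        df = df[schema]
    return df


def write_table(df: pd.DataFrame, path) -> pathlib.Path:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=".")
    return path


def read_counts(counts_path, samples_path, kind: str) -> CountMatrix:
    """Counts TSV (first column ``feature``) plus a sample sheet."""
    df = read_table(counts_path)
    if df.columns[0] != "feature":
        raise SchemaError(f"{counts_path}: first column must be 'feature'")
    counts = df.set_index("feature")
    sheet = read_table(samples_path, SCHEMAS["samples"])
    condition = pd.Series(
        sheet["condition"].values, index=sheet["sample"].values, name="condition"
    )
    return CountMatrix(counts=counts, condition=condition, kind=kind)


def read_proteins(path) -> pd.DataFrame:
    return read_table(path, SCHEMAS["proteins"])


def read_interactions(path) -> pd.DataFrame:
    return read_table(path, SCHEMAS["interactions"])


def read_clinical(path) -> pd.DataFrame:
    df = read_table(path, SCHEMAS["clinical"])
    if df["sample"].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample IDs")
    has_event = df["os_event"].notna()
    if (has_event & df["os_time"].isna()).any():
        raise SchemaError(f"{path}: os_event present without os_time")
    return df


def read_id_list(path) -> list:
    """One-ID-per-line plain text (``#`` comments and blanks skipped)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_de_result(result: pd.DataFrame, path) -> pathlib.Path:
    df = result.copy()
    df.insert(0, "feature", df.index)
    return write_table(df, path)


def read_de_result(path) -> pd.DataFrame:
    return read_table(path, SCHEMAS["de_result"]).set_index("feature")
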