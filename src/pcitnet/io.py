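"""TSV dialects and table writing with provenance headers.

Counts: TSV, first column ``gene_id``, remaining columns sample ids,
integer cells. Sample metadata: TSV with columns ``sample_id`` and
``group`` (values exactly "FH"/"SFH"). Ct tables: long TSV with columns
sample_id, group, gene, ct. Result tables are written with a leading
comment line declaring the generating stage and the configuration hash so
every output is traceable to the run that produced it; readers skip
``#`` comment lines.
"""

from __future__ import annotations

import pandas as pd

from .errors import ValidationError
from .preprocess import CountMatrix
from .qpcr import CT_COLUMNS


def read_counts(counts_path, metadata_path) -> CountMatrix:
    """Read a counts TSV plus its sample metadata into a CountMatrix."""
    counts = pd.read_csv(counts_path, sep="\t", comment="#")
    if counts.columns[0] != "gene_id":
        raise ValidationError(
            f"{counts_path}: first column must be 'gene_id', got "
            f"{counts.columns[0]!r}"
        )
    counts = counts.set_index("gene_id")
    for j, col in enumerate(counts.columns):
        series = pd.to_numeric(counts[col], errors="coerce")
        bad = series.isna() | (series != series.round())
        if bad.any():
            row = counts.index[bad.to_numpy().argmax()]
            raise ValidationError(
                f"{counts_path}: non-integer count at row {row!r}, "
                f"column {col!r}"
            )
        counts[col] = series.astype("int64")
    groups = read_metadata(metadata_path)
    return CountMatrix(counts=counts, groups=groups)


def read_metadata(path) -> pd.Series:
    """Read the sample metadata TSV (sample_id, group)."""
    meta = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise ValidationError(f"{path}: metadata missing column {col!r}")
    return meta.set_index("sample_id")["group"]


def write_counts(cm: CountMatrix, counts_path, metadata_path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    meta = cm.groups.rename("group").to_frame()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t")


def read_ct(path) -> pd.DataFrame:
    """Read a long-format Ct table (sample_id, group, gene, ct)."""
    ct = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValidationError(f"{path}: Ct table missing column(s) {missing}")
    ct["ct"] = ct["ct"].astype(float)
    return ct


def write_table(df: pd.DataFrame, path, stage: str, config_hash: str,
                index: bool = True) -> None:
    """Write a result TSV with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    """Read a result TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
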