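"""Readers, writers and validation for the pipeline's tabular formats.

The pipeline's entry point is a gene-level read-count matrix (TSV, genes in
rows, samples in columns), accompanied by a sample sheet (CSV with columns
``sample_id``, ``region``, ``animal_id`` and optional ``sex``) and a table of
gene lengths in base pairs (TSV with columns ``gene_id``, ``length``).

All objects are plain pandas containers:

* count matrix — ``DataFrame`` of non-negative integers, index ``gene_id``,
  columns ``sample_id``;
* sample sheet — ``DataFrame`` indexed by ``sample_id``;
* gene lengths — ``Series`` of positive integers indexed by ``gene_id``.

Validation happens on read; errors always name the offending record. Gene and
sample order is preserved exactly as read, and every reader/writer pair
round-trips byte-identically on its own output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DataFormatError",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_lengths",
    "write_gene_lengths",
    "read_matrix",
    "write_matrix",
    "read_gene_list",
    "write_gene_list",
    "validate_counts",
    "validate_sample_sheet",
    "validate_gene_lengths",
    "region_order",
]

DEFAULT_REGIONS = ("LD", "IM", "T", "BB", "GM", "QF")


class DataFormatError(ValueError):
    """An input table violates the format contract; the message names the record."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise DataFormatError(f"duplicate {what} {dup!r}")


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a count matrix in place and return it with integer dtype."""
    _check_unique(counts.index, "gene id")
    _check_unique(counts.columns, "sample id")
    for sample in counts.columns:
        col = pd.to_numeric(counts[sample], errors="coerce")
        bad = col.index[col.isna()]
        if len(bad):
            raise DataFormatError(
                f"non-numeric count for gene {bad[0]!r} in sample {sample!r}"
            )
        if (col < 0).any():
            gene = col.index[col < 0][0]
            raise DataFormatError(
                f"negative count for gene {gene!r} in sample {sample!r}"
            )
        if (col % 1 != 0).any():
            gene = col.index[col % 1 != 0][0]
            raise DataFormatError(
                f"non-integer count for gene {gene!r} in sample {sample!r}"
            )
    return counts.astype(np.int64)


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples TSV of read counts.

    First column holds gene ids, the header row sample ids. Cells must be
    non-negative integers; duplicate gene or sample ids are rejected.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.index.name = "gene_id"
    return validate_counts(raw)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def validate_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet indexed by sample_id."""
    _check_unique(samples.index, "sample_id")
    for col in ("region", "animal_id"):
        if col not in samples.columns:
            raise DataFormatError(f"sample sheet is missing column {col!r}")
    empty = samples.index[
        samples["region"].isna() | (samples["region"].astype(str).str.strip() == "")
    ]
    if len(empty):
        raise DataFormatError(f"empty region for sample {empty[0]!r}")
    pair = samples[["animal_id", "region"]]
    if pair.duplicated().any():
        sid = samples.index[pair.duplicated()][0]
        raise DataFormatError(
            f"duplicate (animal_id, region) pair at sample {sid!r}"
        )
    if "sex" in samples.columns:
        bad = samples.index[~samples["sex"].isin(["M", "F"]) & samples["sex"].notna()]
        if len(bad):
            raise DataFormatError(
                f"sex must be 'M' or 'F'; offending sample {bad[0]!r}"
            )
    return samples


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a CSV sample sheet with columns sample_id, region, animal_id[, sex]."""
    samples = pd.read_csv(path, dtype=str)
    if "sample_id" not in samples.columns:
        raise DataFormatError("sample sheet is missing column 'sample_id'")
    samples = samples.set_index("sample_id")
    return validate_sample_sheet(samples)


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index_label="sample_id")


def validate_gene_lengths(lengths: pd.Series) -> pd.Series:
    _check_unique(lengths.index, "gene id")
    num = pd.to_numeric(lengths, errors="coerce")
    bad = num.index[num.isna()]
    if len(bad):
        raise DataFormatError(f"non-numeric length for gene {bad[0]!r}")
    if (num <= 0).any():
        gene = num.index[num <= 0][0]
        raise DataFormatError(f"non-positive length for gene {gene!r}")
    out = num.astype(np.int64)
    out.name = "length"
    return out


def read_gene_lengths(path) -> pd.Series:
    """Read a TSV of gene_id, length (bp, positive integers)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if list(table.columns[:2]) != ["gene_id", "length"]:
        raise DataFormatError(
            "gene length table must have columns 'gene_id' and 'length'"
        )
    lengths = table.set_index("gene_id")["length"]
    return validate_gene_lengths(lengths)


def write_gene_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("length").to_csv(path, sep="\t", index_label="gene_id")


def read_matrix(path) -> pd.DataFrame:
    """Read a real-valued TSV matrix (e.g. FPKM or region means)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    mat.index.name = "gene_id"
    return mat


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_list(path) -> list[str]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return table["gene_id"].tolist()


def write_gene_list(genes, path) -> None:
    pd.Series(list(genes), name="gene_id").to_csv(path, sep="\t", index=False)


def region_order(samples: pd.DataFrame) -> list[str]:
    """Region labels in order of first appearance in the sample sheet."""
    return list(dict.fromkeys(samples["region"]))


def check_samples_match(matrix: pd.DataFrame, samples: pd.DataFrame) -> None:
    """Require every matrix column to be described in the sample sheet."""
    missing = matrix.columns.difference(samples.index)
    if len(missing):
        raise DataFormatError(
            f"sample {missing[0]!r} in matrix is absent from the sample sheet"
        )
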