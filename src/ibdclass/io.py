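"""Readers and writers for count matrices, metadata and matrix sidecars.

Counts travel either as a TSV (first column gene id, header row of sample
ids) or as a MatrixMarket .mtx file with plain-text sidecar files listing
the row (gene) and column (sample) identifiers; both readers produce an
identical genes x samples integer DataFrame for equivalent content.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .preprocess import validate_counts

__all__ = ["read_counts", "write_counts", "read_metadata", "write_metadata"]

DISEASES = ("CD", "UC")
STATUSES = ("inflamed", "normal")


def _sidecar_paths(path: Path, genes_path, samples_path) -> tuple[Path, Path]:
    base = path.with_suffix("")
    return (
        Path(genes_path) if genes_path else base.with_suffix(".genes.txt"),
        Path(samples_path) if samples_path else base.with_suffix(".samples.txt"),
    )


def read_counts(path, fmt: str | None = None, genes_path=None, samples_path=None) -> pd.DataFrame:
    """Read a genes x samples count matrix from TSV or MatrixMarket MTX.

    ``fmt`` defaults to the file suffix (``.mtx`` -> mtx, otherwise tsv).
    For MTX the gene and sample identifiers come from sidecar text files
    (one id per line), by default ``<stem>.genes.txt`` / ``<stem>.samples.txt``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
    elif fmt == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        gpath, spath = _sidecar_paths(path, genes_path, samples_path)
        genes = gpath.read_text().split()
        samples = spath.read_text().split()
        if len(genes) != mat.shape[0] or len(samples) != mat.shape[1]:
            raise ValueError(
                f"sidecar identifier counts ({len(genes)} genes, {len(samples)} samples) "
                f"do not match matrix shape {mat.shape}"
            )
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown count format {fmt!r} (expected 'tsv' or 'mtx')")
    validate_counts(df)
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path, fmt: str | None = None) -> None:
    """Write a count matrix as TSV or as MTX plus identifier sidecars."""
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        counts.to_csv(path, sep="\t", index_label="gene_id")
    elif fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.csr_matrix(counts.to_numpy()))
        gpath, spath = _sidecar_paths(path, None, None)
        gpath.write_text("\n".join(map(str, counts.index)) + "\n")
        spath.write_text("\n".join(map(str, counts.columns)) + "\n")
    else:
        raise ValueError(f"unknown count format {fmt!r} (expected 'tsv' or 'mtx')")


def read_metadata(path) -> pd.DataFrame:
    """Read and validate the sample metadata table.

    Expects a TSV with columns ``sample_id``, ``disease`` (CD or UC) and
    ``status`` (inflamed or normal). Unknown labels raise with the row and
    the allowed vocabulary named.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "disease", "status"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required column(s) {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in metadata: {dup!r}")
    for col, vocab in (("disease", DISEASES), ("status", STATUSES)):
        bad = ~meta[col].isin(vocab)
        if bad.any():
            row = meta.index[bad][0]
            raise ValueError(
                f"metadata row {row} (sample_id={meta.loc[row, 'sample_id']!r}) has "
                f"{col}={meta.loc[row, col]!r}; allowed values are {list(vocab)}"
            )
    return meta[required]


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)
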