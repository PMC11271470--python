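"""Tabular input/output and table normalisation.

Genus-level count tables are plain tab-separated files with taxa as rows
and samples as columns; the first column holds taxon identifiers and the
header row holds sample identifiers.  In memory they are
:class:`pandas.DataFrame` objects (index = taxa, columns = samples).
Sample metadata is one row per sample (index = sample ID) with at least a
``subject`` and an ``age`` column for longitudinal analyses.
"""

from __future__ import annotations

import logging
import sys

import numpy as np
import pandas as pd

logger = logging.getLogger("enterodyn")


class TableFormatError(ValueError):
    """Raised when a table violates the expected format or invariants."""


def setup_logging(verbose: bool = False) -> None:
    """Configure package logging to stderr."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


def validate_count_table(table: pd.DataFrame) -> None:
    """Check count-table invariants: unique IDs, non-negative numeric cells.

    Raises
    ------
    TableFormatError
        naming the offending taxon/sample on the first violation found.
    """
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise TableFormatError(f"duplicate taxon ID {dup!r}")
    if table.columns.duplicated().any():
        dup = table.columns[table.columns.duplicated()][0]
        raise TableFormatError(f"duplicate sample ID {dup!r}")
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = np.zeros(table.shape, dtype=bool)
        for j in range(table.shape[1]):
            bad[:, j] = ~pd.to_numeric(table.iloc[:, j], errors="coerce").notna()
        i, j = np.argwhere(bad)[0]
        raise TableFormatError(
            f"non-numeric count for taxon {table.index[i]!r} "
            f"in sample {table.columns[j]!r}"
        )
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise TableFormatError(
            f"negative count {values[i, j]} for taxon {table.index[i]!r} "
            f"in sample {table.columns[j]!r}"
        )


def read_count_table(path) -> pd.DataFrame:
    """Read a taxa x samples count table from TSV.

    The first column is taxon IDs, the header row sample IDs.  Row and
    column order of the file is preserved.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = next(h for h in header if header.count(h) > 1)
        raise TableFormatError(f"duplicate sample ID {dup!r}")
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    table.index.name = None
    table.columns.name = None
    validate_count_table(table)
    return table


def write_count_table(table: pd.DataFrame, path) -> None:
    """Write a taxa x samples table to TSV (round-trips with the reader)."""
    validate_count_table(table)
    table.to_csv(path, sep="\t", index_label="taxon")


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata (one row per sample, indexed by sample ID)."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()][0]
        raise TableFormatError(f"duplicate sample ID {dup!r} in metadata")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def check_metadata_covers(table: pd.DataFrame, meta: pd.DataFrame) -> None:
    """Every sample column of *table* must have a metadata row."""
    missing = set(table.columns) - set(meta.index)
    if missing:
        raise TableFormatError(
            f"metadata missing for {len(missing)} samples, "
            f"e.g. {sorted(missing)[:3]}"
        )


def to_relative(
    table: pd.DataFrame,
    min_prevalence: float = 0.0,
    min_mean_abund: float = 0.0,
) -> pd.DataFrame:
    """Convert counts to relative abundances, optionally filtering rare taxa.

    Columns are first normalised to proportions; taxa are then dropped if
    their prevalence (fraction of samples with non-zero abundance) is below
    ``min_prevalence`` or their mean relative abundance is below
    ``min_mean_abund``; finally the retained compositions are re-closed so
    every column again sums to 1 (a requirement for divergence-based
    distances, which are defined on probability vectors).

    With the default thresholds of 0 no taxon is dropped.

    Raises
    ------
    TableFormatError
        if any sample has zero total count (no composition is defined).
    """
    validate_count_table(table)
    totals = table.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise TableFormatError(
            f"sample(s) with zero total count: {list(zero.index[:5])}"
        )
    rel = table.astype(float) / totals

    if min_prevalence > 0 or min_mean_abund > 0:
        prevalence = (rel > 0).mean(axis=1)
        mean_abund = rel.mean(axis=1)
        keep = (prevalence >= min_prevalence) & (mean_abund >= min_mean_abund)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("to_relative: dropped %d/%d taxa below thresholds",
                        dropped, len(keep))
        rel = rel.loc[keep]
        if rel.empty:
            raise TableFormatError("all taxa removed by filtering thresholds")
        rel = rel / rel.sum(axis=0)
    return rel


def validate_relative(table: pd.DataFrame, atol: float = 1e-9) -> None:
    """Check relative-abundance invariants: entries in [0, 1], columns sum to 1."""
    values = table.to_numpy(dtype=float)
    if (values < 0).any() or (values > 1 + atol).any():
        raise TableFormatError("relative abundances must lie in [0, 1]")
    sums = values.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=atol):
        j = int(np.argmax(np.abs(sums - 1.0)))
        raise TableFormatError(
            f"sample {table.columns[j]!r} composition sums to {sums[j]!r}, not 1"
        )


def write_distance_matrix(d: np.ndarray, labels, path) -> None:
    """Serialise a square labelled distance matrix as TSV."""
    pd.DataFrame(np.asarray(d), index=labels, columns=labels).to_csv(
        path, sep="\t", index_label="sample"
    )


def read_distance_matrix(path):
    """Read a square labelled distance matrix written by :func:`write_distance_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise TableFormatError("distance matrix rows and columns disagree")
    return df.to_numpy(dtype=float), list(df.index)
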