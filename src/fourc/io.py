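"""Readers and writers for the plain-text formats the pipeline touches.

BED and bedGraph intervals are 0-based half-open on disk, matching the
internal convention, so no coordinate shifting happens here. Parse errors
report 1-based line numbers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .fragments import RestrictionFragmentMap


class ParseError(ValueError):
    """Malformed line in an interval file; the message names the line."""


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def _read_tabular(path, n_required: int, colnames: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            dtype=str,
            skip_blank_lines=False,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=colnames)
    # drop blank lines but remember original 1-based line numbers
    df.index = df.index + 1
    df = df[~df[0].isna() | (df.shape[1] == 1)]
    df = df[df[0].astype(str).str.len() > 0]
    if df.shape[1] < n_required:
        raise ParseError(
            f"{path.name}: expected at least {n_required} tab-separated columns"
        )
    for col in (1, 2):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            line = int(df.index[bad][0])
            raise ParseError(f"{path.name}, line {line}: non-integer coordinate")
        df[col] = converted.astype(np.int64)
    if (df[2] <= df[1]).any():
        line = int(df.index[df[2] <= df[1]][0])
        raise ParseError(f"{path.name}, line {line}: end must exceed start")
    out = df.iloc[:, : len(colnames)].copy()
    out.columns = colnames[: out.shape[1]]
    return out.reset_index(drop=True)


def read_bed(path) -> pd.DataFrame:
    """Read BED (3+ columns) into a DataFrame: chrom, start, end[, name, score]."""
    return _read_tabular(path, 3, ["chrom", "start", "end", "name", "score"])


def read_bedgraph(path, on_unsorted: str = "raise") -> pd.DataFrame:
    """Read a 4-column bedGraph into chrom/start/end/value.

    ``on_unsorted`` is either ``"raise"`` or ``"sort"``.
    """
    df = _read_tabular(path, 4, ["chrom", "start", "end", "value"])
    if df.empty:
        df["value"] = df.get("value", pd.Series(dtype=float))
        return df
    value = pd.to_numeric(df["value"], errors="coerce")
    if value.isna().any():
        line = int(np.nonzero(value.isna().to_numpy())[0][0]) + 1
        raise ParseError(f"{Path(path).name}, line {line}: non-numeric value")
    df["value"] = value.astype(float)
    sorted_ok = all(
        grp["start"].is_monotonic_increasing for _, grp in df.groupby("chrom", sort=False)
    )
    if not sorted_ok:
        if on_unsorted == "sort":
            df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        else:
            raise ParseError(f"{Path(path).name}: bedGraph is not sorted by start")
    return df


def write_bedgraph(path, chrom, starts, ends, values, precision: int = 6) -> None:
    """Write a per-interval track as bedGraph with fixed decimal formatting."""
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        for s, e, v in zip(starts, ends, values):
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.{precision}f}\n")


def write_bed(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def fragment_track_to_bedgraph(
    path, fragment_map: RestrictionFragmentMap, values, precision: int = 6
) -> None:
    """Write one value per fragment of a map as bedGraph."""
    write_bedgraph(
        path,
        fragment_map.chrom,
        fragment_map.starts,
        fragment_map.ends,
        values,
        precision=precision,
    )


def read_sparse_matrix(matrix_path, bins_path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a (bin_i, bin_j, count) triple list plus its bin-table BED.

    Returns the bin table and a dense symmetric matrix.
    """
    bins = read_bed(bins_path)[["chrom", "start", "end"]]
    n = len(bins)
    triples = pd.read_csv(
        matrix_path, sep="\t", header=None, names=["i", "j", "count"], comment="#"
    )
    mat = np.zeros((n, n))
    i = triples["i"].to_numpy(dtype=int)
    j = triples["j"].to_numpy(dtype=int)
    if len(i) and (i.min() < 0 or j.min() < 0 or i.max() >= n or j.max() >= n):
        raise ParseError("sparse matrix refers to bins outside the bin table")
    mat[i, j] = triples["count"].to_numpy(dtype=float)
    mat[j, i] = mat[i, j]
    return bins, mat


def write_sparse_matrix(matrix_path, bins_path, bins: pd.DataFrame, matrix) -> None:
    """Write the upper triangle of a symmetric matrix as (i, j, count) triples."""
    matrix = np.asarray(matrix)
    iu, ju = np.nonzero(np.triu(matrix))
    with open(matrix_path, "w") as fh:
        for i, j in zip(iu, ju):
            v = matrix[i, j]
            text = f"{v:.6g}" if v != int(v) else str(int(v))
            fh.write(f"{i}\t{j}\t{text}\n")
    write_bed(bins_path, bins[["chrom", "start", "end"]])
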