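"""Readers and writers for the plain-text formats the pipeline speaks.

Matrices travel as a HiC-Pro-style two-file dialect: a triplet TSV
(bin_id_1, bin_id_2, count) plus a BED-like bins table
(chrom, start, end, bin_id).  Tracks are bedGraph, intervals are BED,
anchor pairs are BEDPE, tabular results are TSV.  All writers round-trip
bit-exactly for integer raw counts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import MatrixFormatError
from .matrix import ContactMatrix, DecayCurve, ExpectedProfile

__all__ = [
    "read_bins",
    "read_matrix",
    "write_matrix",
    "write_dense",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedgraph",
    "write_tsv",
    "read_de_table",
    "write_json",
]


def read_bins(bins_path) -> pd.DataFrame:
    """Load a bins table (chrom, start, end, bin_id), sorted genomically."""
    bins = pd.read_csv(
        bins_path, sep="\t", header=None,
        names=["chrom", "start", "end", "bin_id"], comment="#",
    )
    return bins.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def read_matrix(triplet_path, bins_path, chrom: str) -> ContactMatrix:
    """Read one chromosome's raw contact matrix from triplet + bins files.

    Bin ids are mapped to 0-based row indices by genomic order.  Duplicate
    records for the same oriented pair are summed; when both orientations of
    a pair are present their totals must agree.  Bins with zero marginal are
    marked invalid.
    """
    bins = read_bins(bins_path)
    sel = bins[bins["chrom"] == chrom]
    if sel.empty:
        raise MatrixFormatError(f"chromosome {chrom!r} not in bins table")
    widths = (sel["end"] - sel["start"]).to_numpy()
    if widths.size > 1 and np.unique(widths[:-1]).size != 1:
        raise MatrixFormatError("non-uniform bin widths")
    bin_size = int(widths[0])
    ids = sel["bin_id"].to_numpy()
    id_to_row = {int(b): r for r, b in enumerate(ids)}
    n = len(ids)

    trip = pd.read_csv(
        triplet_path, sep="\t", header=None,
        names=["bin1", "bin2", "count"], comment="#",
    )
    counts = np.zeros((n, n), dtype=float)
    if not trip.empty:
        if (trip["count"] < 0).any():
            raise ValueError("negative counts in triplet file")
        known = set(int(b) for b in bins["bin_id"])
        for col in ("bin1", "bin2"):
            bad = set(int(b) for b in trip[col]) - known
            if bad:
                raise IndexError(f"bin ids not in bins table: {sorted(bad)[:5]}")
        on_chrom = trip["bin1"].isin(id_to_row) & trip["bin2"].isin(id_to_row)
        trip = trip[on_chrom]
        # sum duplicates of the same orientation first
        agg = trip.groupby(["bin1", "bin2"], as_index=False)["count"].sum()
        i = agg["bin1"].map(id_to_row).to_numpy()
        j = agg["bin2"].map(id_to_row).to_numpy()
        c = agg["count"].to_numpy(dtype=float)
        mirrored = {}
        for a, b, v in zip(i, j, c):
            key = (min(a, b), max(a, b))
            if key in mirrored and (a, b) != mirrored[key][0]:
                if mirrored[key][1] != v:
                    raise MatrixFormatError(
                        f"mirrored records disagree for bin pair {key}"
                    )
            else:
                mirrored[key] = ((a, b), v)
        for (a, b), (_, v) in mirrored.items():
            counts[a, b] = v
            counts[b, a] = v
    valid = counts.sum(axis=0) > 0
    return ContactMatrix(
        chrom=chrom, bin_size=bin_size, counts=counts, layer="raw",
        valid_mask=valid,
    )


def write_matrix(m: ContactMatrix, triplet_path, bins_path, first_bin_id: int = 0):
    """Write a matrix back to the triplet + bins dialect (upper triangle)."""
    n = m.n_bins
    rows = []
    for r in range(n):
        rows.append((m.chrom, r * m.bin_size, (r + 1) * m.bin_size, first_bin_id + r))
    pd.DataFrame(rows).to_csv(bins_path, sep="\t", header=False, index=False)
    iu = np.triu_indices(n)
    c = m.counts[iu]
    keep = np.isfinite(c) & (c != 0)
    trip = pd.DataFrame({
        "bin1": iu[0][keep] + first_bin_id,
        "bin2": iu[1][keep] + first_bin_id,
        "count": c[keep],
    })
    if np.allclose(trip["count"], np.round(trip["count"]), atol=0):
        trip["count"] = trip["count"].astype(np.int64)
    trip.to_csv(triplet_path, sep="\t", header=False, index=False)


def write_dense(m: ContactMatrix, path):
    """Dense TSV writer for small matrices (one row per bin)."""
    pd.DataFrame(m.counts).to_csv(path, sep="\t", header=False, index=False,
                                  float_format="%.10g")


def read_bed(path, names=("chrom", "start", "end", "name", "cls")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names)[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path, cols=None):
    out = df if cols is None else df[list(cols)]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"][: df.shape[1]] + \
        [f"extra{k}" for k in range(max(0, df.shape[1] - 6))]
    return df


def write_bedgraph(chrom: str, bin_size: int, values: np.ndarray, path):
    """Per-bin track as bedGraph; NaN bins are skipped."""
    values = np.asarray(values, dtype=float)
    idx = np.flatnonzero(np.isfinite(values))
    df = pd.DataFrame({
        "chrom": chrom,
        "start": idx * bin_size,
        "end": (idx + 1) * bin_size,
        "value": values[idx],
    })
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def write_tsv(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_de_table(path) -> pd.DataFrame:
    """Differential-expression table with header (gene, log2fc, fdr)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log2fc", "fdr"}
    if not required.issubset(df.columns):
        raise MatrixFormatError(f"DE table must have columns {sorted(required)}")
    return df


def write_json(obj, path):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_expected(e: ExpectedProfile, path):
    d = np.arange(e.values.size)
    df = pd.DataFrame({
        "distance_bp_low": d * e.bin_size,
        "distance_bp_high": (d + 1) * e.bin_size,
        "value": e.values,
    })
    write_tsv(df, path)


def write_decay(c: DecayCurve, path):
    df = pd.DataFrame({
        "distance_bp_low": c.bin_edges[:-1],
        "distance_bp_high": c.bin_edges[1:],
        "value": c.probabilities,
    })
    write_tsv(df, path)
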