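"""Pile-up (aggregate) analysis of O/E sub-matrices.

Aggregate maps average many O/E windows — boundary-centered squares along
the diagonal, or off-diagonal windows at anchor pairs — after interpolating
unequal window sizes onto a common grid.  Loop and enhancer-promoter
strengths are the mean O/E in a fixed neighborhood of the anchor-pair pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .matrix import ContactMatrix
from .domains import BoundarySet

__all__ = [
    "AggregateMap",
    "aggregate_map",
    "boundary_aggregate",
    "pair_windows",
    "pair_strength",
    "track_meta_profile",
    "anchor_pairs_from_bedpe",
]


@dataclass
class AggregateMap:
    values: np.ndarray
    n_windows: int
    source: str = "region"


def _resize(sub: np.ndarray, out_size: int, method: str = "bilinear") -> np.ndarray:
    """NaN-aware corner-aligned resize onto an out_size x out_size grid."""
    s0, s1 = sub.shape
    if (s0, s1) == (out_size, out_size):
        return sub.copy()
    r = np.linspace(0, s0 - 1, out_size)
    c = np.linspace(0, s1 - 1, out_size)
    rr, cc = np.meshgrid(r, c, indexing="ij")
    order = 1 if method == "bilinear" else 0
    finite = np.isfinite(sub)
    v = map_coordinates(np.where(finite, sub, 0.0), [rr, cc], order=order)
    w = map_coordinates(finite.astype(float), [rr, cc], order=order)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(w >= 0.5, v / np.maximum(w, 1e-12), np.nan)
    return out


def aggregate_map(
    m: ContactMatrix,
    windows,
    out_size: int,
    source: str = "region",
    method: str = "bilinear",
) -> AggregateMap:
    """Element-wise mean of O/E windows, each weighted equally.

    ``windows`` is a list of (row_start, row_end, col_start, col_end)
    half-open blocks.  Windows not fully inside the matrix are skipped with
    a warning; missing pixels are ignored per-element in the mean.
    """
    if m.layer != "oe":
        raise ValueError("aggregate_map requires the O/E layer")
    if out_size < 3:
        raise ValueError("out_size must be >= 3")
    if not windows:
        raise ValueError("empty window list")
    n = m.n_bins
    stack = []
    skipped = 0
    for r0, r1, c0, c1 in windows:
        if r0 < 0 or c0 < 0 or r1 > n or c1 > n or r1 <= r0 or c1 <= c0:
            skipped += 1
            continue
        stack.append(_resize(m.counts[r0:r1, c0:c1], out_size, method))
    if skipped:
        warnings.warn(f"skipped {skipped} off-chromosome windows", RuntimeWarning)
    if not stack:
        raise ValueError("no window fell inside the matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
        values = np.nanmean(np.stack(stack), axis=0)
    return AggregateMap(values=values, n_windows=len(stack), source=source)


def boundary_aggregate(
    m: ContactMatrix, b: BoundarySet, flank_bp: int, out_size: int | None = None
) -> AggregateMap:
    """Aggregate O/E in squares of +/- flank_bp centered on boundaries."""
    if flank_bp % m.bin_size:
        raise ValueError("flank_bp must be a multiple of bin_size")
    f = flank_bp // m.bin_size
    size = 2 * f + 1
    windows = [(x - f, x + f + 1, x - f, x + f + 1) for x in b.bins]
    return aggregate_map(
        m, windows, out_size if out_size is not None else size,
        source="boundary-centered",
    )


def pair_windows(pairs, halo_bins: int):
    """Off-diagonal windows of 2*halo_bins per side centered on anchor pixels."""
    h = int(halo_bins)
    return [(a1 - h, a1 + h, a2 - h, a2 + h) for a1, a2 in pairs]


def pair_strength(m: ContactMatrix, pair, halo_bins: int = 5) -> float:
    """Mean O/E in the anchor-pair pixel's neighborhood (loop/E-P strength).

    The window is the 2h x 2h block rows [a1-h, a1+h) x cols [a2-h, a2+h),
    i.e. the nearest 10 bins per axis at the default h=5, clipped to the
    matrix.  NaN if the window holds no valid entry.
    """
    if m.layer != "oe":
        raise ValueError("pair_strength requires the O/E layer")
    if halo_bins < 1:
        raise ValueError("halo_bins must be >= 1")
    a1, a2 = int(pair[0]), int(pair[1])
    n = m.n_bins
    if not (0 <= a1 < n and 0 <= a2 < n):
        raise IndexError(f"anchors ({a1}, {a2}) out of range for {n} bins")
    h = halo_bins
    block = m.counts[max(a1 - h, 0): min(a1 + h, n), max(a2 - h, 0): min(a2 + h, n)]
    vals = block[np.isfinite(block)]
    return float(vals.mean()) if vals.size else float("nan")


def track_meta_profile(track: np.ndarray, anchors, flank_bp: int, bin_size: int) -> np.ndarray:
    """Mean of a per-bin track over +/- flank windows centered at anchors.

    Windows running off the chromosome are padded with NaN; the mean at each
    offset ignores NaN.  Output has 2*flank/bin_size + 1 entries.
    """
    if flank_bp % bin_size:
        raise ValueError("flank_bp must be a multiple of bin_size")
    track = np.asarray(track, dtype=float)
    f = flank_bp // bin_size
    n = track.size
    rows = []
    for a in anchors:
        a = int(a)
        if a < 0 or a >= n:
            continue
        row = np.full(2 * f + 1, np.nan)
        lo, hi = a - f, a + f + 1
        src_lo, src_hi = max(lo, 0), min(hi, n)
        row[src_lo - lo: src_hi - lo] = track[src_lo:src_hi]
        rows.append(row)
    if not rows:
        raise ValueError("no anchors fall on the chromosome")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.stack(rows), axis=0)


def anchor_pairs_from_bedpe(df, chrom: str, bin_size: int):
    """Anchor bin pairs (a1 < a2) from a BEDPE frame; bin = interval midpoint."""
    sel = df[(df["chrom1"] == chrom) & (df["chrom2"] == chrom)]
    mid1 = ((sel["start1"] + sel["end1"]) // 2).to_numpy() // bin_size
    mid2 = ((sel["start2"] + sel["end2"]) // 2).to_numpy() // bin_size
    lo = np.minimum(mid1, mid2)
    hi = np.maximum(mid1, mid2)
    keep = hi - lo >= 2
    return list(zip(lo[keep].astype(int), hi[keep].astype(int)))
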