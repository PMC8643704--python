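"""Contact-matrix data model and core transforms.

A Hi-C experiment yields, per chromosome, a symmetric matrix of contact
counts between fixed-size genomic bins.  This module carries that matrix
through its three standard layers — raw counts, iteratively corrected
(ICE-balanced) counts, and the distance-normalized observed/expected (O/E)
ratio — and derives the two classic one-dimensional summaries: the expected
contact profile E(d) and the log-binned contact-probability decay curve P(s).

Masked (invalid) bins are represented as NaN in the balanced and O/E layers,
never as zeros: a zero is a measurement, a NaN is the absence of one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .exceptions import DegenerateMatrixError, DimensionError

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "DecayCurve",
    "ice_balance",
    "expected_by_distance",
    "oe_transform",
    "decay_curve",
]


@dataclass
class ContactMatrix:
    """Symmetric per-chromosome binned contact matrix.

    Parameters
    ----------
    chrom : chromosome name.
    bin_size : bin width in bp.
    counts : (n, n) symmetric non-negative array; NaN marks masked entries
        in the ``balanced``/``oe`` layers.
    layer : one of ``raw``, ``balanced``, ``oe``.
    valid_mask : boolean vector, True where the bin participates in analysis.
    meta : free-form provenance (balancing iterations, convergence CV, ...).
    """

    chrom: str
    bin_size: int
    counts: np.ndarray
    layer: str = "raw"
    valid_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise DimensionError(f"counts must be square, got {self.counts.shape}")
        if self.layer not in ("raw", "balanced", "oe"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.n_bins, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != (self.n_bins,):
                raise DimensionError("valid_mask length must equal n_bins")
        finite = np.isfinite(self.counts)
        if not np.array_equal(finite, finite.T):
            raise ValueError("contact matrix must be symmetric")
        if finite.any():
            scale = np.nanmax(np.abs(self.counts))
            asym = np.nanmax(np.abs(self.counts - self.counts.T))
            if asym > 1e-12 + 1e-9 * max(scale, 1.0):
                raise ValueError("contact matrix must be symmetric")
            if self.layer != "oe" and np.nanmin(self.counts) < 0:
                raise ValueError("negative counts are not allowed")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def chrom_length(self) -> int:
        return self.n_bins * self.bin_size

    def bin_of(self, pos_bp: int) -> int:
        """Bin index containing a genomic position (0-based bp)."""
        return int(pos_bp // self.bin_size)

    def total_counts(self) -> float:
        """Total cis counts, each unordered pair counted once (diag included)."""
        return float(np.nansum(np.triu(self.counts)))


@dataclass
class ExpectedProfile:
    """Mean contact intensity at each bin separation d = 0..n_bins-1."""

    chrom: str
    bin_size: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(self.values[np.isfinite(self.values)] < 0):
                raise ValueError("expected values must be non-negative")


@dataclass
class DecayCurve:
    """Contact probability per log2-spaced distance bin.

    ``bin_edges`` holds the log2 bin bounds in bp (length m+1 for m
    probabilities); probabilities sum to 1 over all included cis contacts.
    """

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.bin_edges.size != self.probabilities.size + 1:
            raise DimensionError("need len(bin_edges) == len(probabilities) + 1")

    def mass_between(self, lo_bp: float, hi_bp: float) -> float:
        """Probability mass in log2 bins fully or partly inside [lo, hi).

        A log2 bin contributes its whole mass if its midpoint falls in the
        range; used for coarse short-/long-range comparisons.
        """
        mid = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        sel = (mid >= lo_bp) & (mid < hi_bp)
        return float(self.probabilities[sel].sum())


def _marginals(counts: np.ndarray) -> np.ndarray:
    return np.nansum(counts, axis=0)


def ice_balance(
    m: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-4,
    mask_frac: float = 0.02,
) -> ContactMatrix:
    """Iterative-correction (ICE) balancing of a raw contact matrix.

    Bins with zero marginal, plus those in the lowest ``mask_frac`` quantile
    of nonzero marginals, are masked before balancing.  Rows/columns are then
    repeatedly divided by their (mean-normalized) marginals until the
    coefficient of variation of valid-bin marginals drops below ``tol`` or
    ``max_iter`` is reached (non-convergence sets ``meta['converged']=False``
    rather than raising).  The result is rescaled so the valid-entry total
    matches the input's, keeping decay curves comparable across conditions.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    counts = np.where(np.isfinite(m.counts), m.counts, 0.0)
    marg = counts.sum(axis=0)
    valid = m.valid_mask & (marg > 0)
    nonzero = marg[m.valid_mask & (marg > 0)]
    if nonzero.size and mask_frac > 0:
        cut = np.quantile(nonzero, mask_frac)
        valid &= marg >= cut
    if not valid.any():
        raise DegenerateMatrixError("all bins masked; nothing to balance")

    w0 = counts[np.ix_(valid, valid)]
    total_in = w0.sum()
    if total_in <= 0:
        raise DegenerateMatrixError("no counts among valid bins")

    # Track the cumulative bin bias b instead of rescaling the full matrix:
    # the balanced matrix is w0 / outer(b, b), whose marginal is
    # (1/b) * (w0 @ (1/b)) — one matvec per iteration.
    b = np.ones(w0.shape[0])
    cv = np.inf
    iters = 0
    converged = False
    for iters in range(1, max_iter + 1):
        inv_b = 1.0 / b
        s = inv_b * (w0 @ inv_b)
        mean_s = s.mean()
        cv = s.std() / mean_s
        if cv < tol:
            converged = True
            break
        b *= s / mean_s
    else:
        # loop exhausted: recompute the final CV after the last update
        inv_b = 1.0 / b
        s = inv_b * (w0 @ inv_b)
        cv = s.std() / s.mean()
        converged = cv < tol

    inv_b = 1.0 / b
    w = w0 * np.outer(inv_b, inv_b)
    w *= total_in / w.sum()
    if not converged:
        warnings.warn(
            f"ICE did not converge in {max_iter} iterations (CV={cv:.3g})",
            RuntimeWarning,
        )

    out = np.full_like(counts, np.nan)
    out[np.ix_(valid, valid)] = w
    return ContactMatrix(
        chrom=m.chrom,
        bin_size=m.bin_size,
        counts=out,
        layer="balanced",
        valid_mask=valid,
        meta={**m.meta, "ice_iterations": iters, "ice_cv": float(cv),
              "converged": bool(converged)},
    )


def expected_by_distance(m: ContactMatrix) -> ExpectedProfile:
    """Mean balanced contact per bin separation, over valid-bin pairs only.

    Distances with no valid pair get NaN.
    """
    if m.layer != "balanced":
        raise ValueError("expected_by_distance requires the balanced layer")
    n = m.n_bins
    values = np.full(n, np.nan)
    v = m.valid_mask
    for d in range(n):
        diag = np.diagonal(m.counts, offset=d)
        pair_ok = v[: n - d] & v[d:] & np.isfinite(diag)
        if pair_ok.any():
            values[d] = diag[pair_ok].mean()
    return ExpectedProfile(chrom=m.chrom, bin_size=m.bin_size, values=values)


def oe_transform(m: ContactMatrix, e: ExpectedProfile) -> ContactMatrix:
    """Observed/expected ratio: each balanced entry divided by E(|i-j|)."""
    if m.layer != "balanced":
        raise ValueError("oe_transform requires the balanced layer")
    if m.bin_size != e.bin_size or m.chrom != e.chrom:
        raise DimensionError("matrix and expected profile are on different grids")
    if e.values.size != m.n_bins:
        raise DimensionError("expected profile length must equal n_bins")
    emat = scipy.linalg.toeplitz(e.values)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(emat > 0, m.counts / emat, np.nan)
    invalid = ~m.valid_mask
    oe[invalid, :] = np.nan
    oe[:, invalid] = np.nan
    return ContactMatrix(
        chrom=m.chrom, bin_size=m.bin_size, counts=oe, layer="oe",
        valid_mask=m.valid_mask.copy(), meta=dict(m.meta),
    )


def decay_curve(m: ContactMatrix, min_dist_bp: int | None = None) -> DecayCurve:
    """Contact probability P(s) per log2 distance bin from raw counts.

    Each unordered pair at separation >= ``min_dist_bp`` contributes once;
    the per-bin sums are divided by the grand total only — no bin-width
    normalization.  ``min_dist_bp`` defaults to 2 bins to skip self- and
    adjacent-ligation artifacts.
    """
    if m.layer != "raw":
        raise ValueError("decay_curve is defined on raw counts")
    if min_dist_bp is None:
        min_dist_bp = 2 * m.bin_size
    if min_dist_bp < m.bin_size:
        raise ValueError("min_dist_bp must be >= bin_size")
    n = m.n_bins
    d_min = int(np.ceil(min_dist_bp / m.bin_size))
    if d_min >= n:
        raise DegenerateMatrixError("min_dist_bp beyond chromosome span")
    seps = np.arange(d_min, n) * m.bin_size
    sums = np.array(
        [np.diagonal(m.counts, offset=d).sum() for d in range(d_min, n)]
    )
    total = sums.sum()
    if total <= 0:
        raise DegenerateMatrixError("no cis counts beyond min_dist_bp")
    k_lo = int(np.floor(np.log2(seps[0])))
    k_hi = int(np.floor(np.log2(seps[-1])))
    edges = 2.0 ** np.arange(k_lo, k_hi + 2)
    which = np.digitize(seps, edges) - 1
    probs = np.zeros(edges.size - 1)
    np.add.at(probs, which, sums)
    probs /= total
    return DecayCurve(bin_edges=edges, probabilities=probs)
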