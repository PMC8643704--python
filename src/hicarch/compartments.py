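"""A/B compartment analysis from the O/E matrix.

Compartments are called as the sign of the leading eigenvector (PC1) of the
Pearson correlation matrix of the O/E contact map: positive bins form the A
(active) compartment, negative bins B.  Compartmentalization strength is the
classic (AA + BB) / 2AB ratio of mean O/E contact within versus between
compartments, and two conditions are compared by per-bin switch
classification (A→B, B→A, stable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg

from .exceptions import DimensionError, InsufficientDataError, UndefinedStrengthError
from .matrix import ContactMatrix

__all__ = [
    "CompartmentProfile",
    "SwitchSummary",
    "compute_pc1",
    "compartment_strength",
    "classify_switches",
]

SWITCH_CLASSES = ("A->B", "B->A", "stable-A", "stable-B")


@dataclass
class CompartmentProfile:
    chrom: str
    bin_size: int
    pc1: np.ndarray            # NaN at invalid bins
    labels: np.ndarray         # 'A' | 'B' | 'NA' per bin

    @property
    def n_bins(self) -> int:
        return self.pc1.size


@dataclass
class SwitchSummary:
    """Per-bin compartment switch classes between two conditions."""

    classes: np.ndarray                      # object array over SWITCH_CLASSES + 'NA'
    fractions: dict = field(default_factory=dict)  # over classifiable bins

    @property
    def n_classifiable(self) -> int:
        return int(np.sum(self.classes != "NA"))


def _labels_from_pc1(pc1: np.ndarray) -> np.ndarray:
    labels = np.full(pc1.size, "NA", dtype=object)
    labels[np.nan_to_num(pc1, nan=0.0) > 0] = "A"
    labels[np.nan_to_num(pc1, nan=0.0) < 0] = "B"
    return labels


def compute_pc1(
    m: ContactMatrix,
    orientation_track: np.ndarray | None = None,
) -> CompartmentProfile:
    """Leading eigenvector of the O/E correlation matrix.

    Zero-variance rows are excluded with a warning.  The eigenvector sign is
    intrinsically arbitrary; if ``orientation_track`` is given the sign is
    chosen so that corr(pc1, track) >= 0, otherwise the sign is left as
    computed and a warning is emitted — orientation is biology the matrix
    alone cannot supply.
    """
    if m.layer != "oe":
        raise ValueError("compute_pc1 requires the O/E layer")
    valid = m.valid_mask.copy()
    sub = m.counts[np.ix_(valid, valid)]
    # rows may still contain NaN at distances with undefined expected values
    sub = np.where(np.isfinite(sub), sub, 1.0)  # O/E-neutral fill
    sd = sub.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"excluding {int(flat.sum())} zero-variance rows", RuntimeWarning)
        keep = ~flat
        idx = np.flatnonzero(valid)
        valid[idx[flat]] = False
        sub = sub[np.ix_(keep, keep)]
    if valid.sum() < 10:
        raise InsufficientDataError("fewer than 10 valid bins for PC1")
    # Leading eigenvector of corrcoef(sub) without forming the full
    # correlation matrix: with R the row-standardized data, corr = R Rᵀ,
    # so Lanczos on v ↦ R (Rᵀ v) needs only matvecs.  v0 fixed for
    # determinism.
    xc = sub - sub.mean(axis=1, keepdims=True)
    r = xc / np.linalg.norm(xc, axis=1, keepdims=True)
    k = r.shape[0]
    op = scipy.sparse.linalg.LinearOperator(
        (k, k), matvec=lambda v: r @ (r.T @ v), dtype=float
    )
    _, evecs = scipy.sparse.linalg.eigsh(op, k=1, v0=np.ones(k))
    vec = evecs[:, 0]

    pc1 = np.full(m.n_bins, np.nan)
    pc1[valid] = vec
    if orientation_track is not None:
        track = np.asarray(orientation_track, dtype=float)
        if track.size != m.n_bins:
            raise DimensionError("orientation track length must equal n_bins")
        ok = np.isfinite(pc1) & np.isfinite(track)
        if ok.any() and np.corrcoef(pc1[ok], track[ok])[0, 1] < 0:
            pc1 = -pc1
    else:
        warnings.warn(
            "no orientation track given; PC1 sign (hence A/B polarity) is arbitrary",
            RuntimeWarning,
        )
    return CompartmentProfile(
        chrom=m.chrom, bin_size=m.bin_size, pc1=pc1, labels=_labels_from_pc1(pc1)
    )


def compartment_strength(
    m: ContactMatrix,
    profile: CompartmentProfile,
    min_sep_bins: int = 2,
) -> float:
    """Compartmentalization strength (AA + BB) / 2AB.

    AA, BB and AB are mean O/E values over valid bin pairs (i < j) of the
    corresponding label combination at separation >= ``min_sep_bins``
    (the near-diagonal is excluded because it is dominated by distance,
    not compartment, structure).
    """
    if m.layer != "oe":
        raise ValueError("compartment_strength requires the O/E layer")
    if profile.n_bins != m.n_bins:
        raise DimensionError("profile and matrix grids differ")
    labels = profile.labels
    n = m.n_bins
    # integer label codes keep the pair-wise comparisons out of object dtype
    code = np.zeros(n, dtype=np.int8)
    code[labels == "A"] = 1
    code[labels == "B"] = 2
    ii, jj = np.triu_indices(n, k=max(min_sep_bins, 1))
    vals = m.counts[ii, jj]
    ok = np.isfinite(vals)
    li, lj = code[ii], code[jj]
    means = {}
    for name, sel in (
        ("AA", (li == 1) & (lj == 1)),
        ("BB", (li == 2) & (lj == 2)),
        ("AB", ((li == 1) & (lj == 2)) | ((li == 2) & (lj == 1))),
    ):
        sel = sel & ok
        if not sel.any():
            raise UndefinedStrengthError(f"no valid {name} pairs")
        means[name] = vals[sel].mean()
    return float((means["AA"] + means["BB"]) / (2.0 * means["AB"]))


def classify_switches(p1: CompartmentProfile, p2: CompartmentProfile) -> SwitchSummary:
    """Per-bin A/B switch classes between two conditions and their fractions.

    Fractions are computed over bins classifiable (label A or B) in both
    profiles and sum to 1 over the four classes.
    """
    if (p1.chrom, p1.bin_size, p1.n_bins) != (p2.chrom, p2.bin_size, p2.n_bins):
        raise DimensionError("profiles are on different grids")
    l1, l2 = p1.labels, p2.labels
    classes = np.full(l1.size, "NA", dtype=object)
    both = (l1 != "NA") & (l2 != "NA")
    classes[both & (l1 == "A") & (l2 == "B")] = "A->B"
    classes[both & (l1 == "B") & (l2 == "A")] = "B->A"
    classes[both & (l1 == "A") & (l2 == "A")] = "stable-A"
    classes[both & (l1 == "B") & (l2 == "B")] = "stable-B"
    n_cls = int(both.sum())
    fractions = {
        c: (float(np.sum(classes == c)) / n_cls if n_cls else float("nan"))
        for c in SWITCH_CLASSES
    }
    return SwitchSummary(classes=classes, fractions=fractions)
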