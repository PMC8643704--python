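"""Gene/enhancer interval statistics.

Consumes a differential-expression table and BED-style feature tables to
reproduce the regulatory-geometry statistics of the analysis: DE class
assignment, distance from TSS to the nearest enhancer with per-class
cumulative curves and Kolmogorov-Smirnov comparison, compartment-switch
annotation of gene sets, and the boundary-presence enrichment between
promoters and their nearest enhancers with a point-mirrored control site.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "classify_genes",
    "nearest_distance",
    "cumulative_curves_ks",
    "annotate_switch_overlap",
    "boundary_enrichment",
    "EnrichmentResult",
]


def classify_genes(de: pd.DataFrame, fdr_max: float = 0.05, lfc_min: float = 1.5) -> pd.Series:
    """Assign up/down/non classes from a DE table (gene, log2fc, fdr).

    up: fdr < fdr_max and log2fc > lfc_min; down: fdr < fdr_max and
    log2fc < -lfc_min; everything else (strict inequalities) is non.
    Genes with missing fdr fall into non with a warning.
    """
    if fdr_max <= 0 or lfc_min <= 0:
        raise ValueError("thresholds must be positive")
    fdr = pd.to_numeric(de["fdr"], errors="coerce")
    lfc = pd.to_numeric(de["log2fc"], errors="coerce")
    missing = fdr.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} genes with missing FDR set to 'non'",
                      RuntimeWarning)
    cls = pd.Series("non", index=de.index, dtype=object)
    sig = ~missing & (fdr < fdr_max)
    cls[sig & (lfc > lfc_min)] = "up"
    cls[sig & (lfc < -lfc_min)] = "down"
    return cls


def _point_to_intervals(t: int, starts: np.ndarray, ends: np.ndarray) -> float:
    """Distance from a point to the nearest [start, end) interval (sorted input)."""
    if starts.size == 0:
        return np.nan
    k = np.searchsorted(starts, t, side="right")
    best = np.inf
    if k > 0:
        e = ends[:k].max()  # intervals may nest; guard with running max
        best = 0.0 if t < e else t - e
    if k < starts.size:
        best = min(best, starts[k] - t)
    return float(max(best, 0.0))


def nearest_distance(tss: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Unsigned bp distance from each TSS to its nearest target interval.

    TSS is the start of its (point) interval; distance 0 inside a target;
    genes on chromosomes without targets get NaN.  Strand-free throughout.
    """
    out = np.full(len(tss), np.nan)
    by_chrom = {}
    for chrom, grp in targets.groupby("chrom"):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy(dtype=float)
        ends = grp["end"].to_numpy(dtype=float)
        # running max of ends for nested/unordered interval safety
        by_chrom[chrom] = (starts, np.maximum.accumulate(ends))
    for idx, (chrom, t) in enumerate(zip(tss["chrom"], tss["start"])):
        if chrom in by_chrom:
            starts, ends = by_chrom[chrom]
            out[idx] = _point_to_intervals(int(t), starts, ends)
    return out


def cumulative_curves_ks(distances_by_class: dict, pairs=None, min_n: int = 5):
    """Empirical CDFs of distances per class plus pairwise two-sided KS tests.

    Classes with fewer than ``min_n`` finite distances are excluded with a
    warning.  Returns (curves, ks) as long-format DataFrames; KS p-values are
    reported raw.
    """
    clean = {}
    for cls, d in distances_by_class.items():
        d = np.asarray(d, dtype=float)
        d = d[np.isfinite(d)]
        if d.size < min_n:
            warnings.warn(f"class {cls!r} has < {min_n} distances; excluded",
                          RuntimeWarning)
            continue
        clean[cls] = np.sort(d)
    if len(clean) < 2:
        raise ValueError("need at least two classes with enough distances")
    curves = pd.concat(
        [
            pd.DataFrame({
                "cls": cls,
                "distance": d,
                "cdf": np.arange(1, d.size + 1) / d.size,
            })
            for cls, d in clean.items()
        ],
        ignore_index=True,
    )
    if pairs is None:
        pairs = list(itertools.combinations(sorted(clean), 2))
    rows = []
    for c1, c2 in pairs:
        if c1 not in clean or c2 not in clean:
            continue
        res = stats.ks_2samp(clean[c1], clean[c2], alternative="two-sided")
        rows.append({"class1": c1, "class2": c2,
                     "ks_d": float(res.statistic), "p_value": float(res.pvalue)})
    return curves, pd.DataFrame(rows)


def annotate_switch_overlap(genes: pd.DataFrame, switch_classes: np.ndarray,
                            bin_size: int):
    """Assign each gene the compartment-switch class of its TSS bin.

    Returns (per-gene class Series, per-gene-class fraction table).  Genes
    whose TSS falls off the bin grid get 'NA'; fractions are over genes with
    a defined switch class.
    """
    n_bins = len(switch_classes)
    tss_bin = (genes["start"] // bin_size).to_numpy()
    ok = (tss_bin >= 0) & (tss_bin < n_bins)
    per_gene = pd.Series("NA", index=genes.index, dtype=object)
    per_gene[ok] = np.asarray(switch_classes, dtype=object)[tss_bin[ok].astype(int)]
    rows = []
    for gcls, grp in per_gene.groupby(genes["cls"]):
        defined = grp[grp != "NA"]
        for scls in sorted(set(defined)):
            rows.append({
                "gene_class": gcls,
                "switch_class": scls,
                "n": int((defined == scls).sum()),
                "fraction": float((defined == scls).mean()),
            })
    return per_gene, pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    gene_class: str
    n_genes: int
    observed_count: int
    control_count: int

    @property
    def enrichment(self) -> float:
        if self.control_count == 0:
            return float("nan")
        return self.observed_count / self.control_count


def _hit_between(a: float, b: float, positions: np.ndarray) -> bool:
    """True iff some position lies strictly within the open interval (a, b)."""
    lo, hi = (a, b) if a <= b else (b, a)
    k = np.searchsorted(positions, lo, side="right")
    return k < positions.size and positions[k] < hi


def boundary_enrichment(
    genes: pd.DataFrame,
    enhancers: pd.DataFrame,
    boundary_positions: dict,
    chrom_sizes: dict,
    classes=("up", "down", "non"),
) -> list:
    """Enrichment of boundary presence between promoters and nearest enhancers.

    For each gene with promoter (TSS) p and nearest-enhancer midpoint e, an
    observed hit is a boundary strictly inside (p, e); the control reflects e
    across the promoter (c = 2p - e) and asks the same question.  Genes whose
    control site falls off the chromosome are dropped from both counts.
    Per-class enrichment = observed_count / control_count.
    """
    enh = enhancers.copy()
    enh["mid"] = (enh["start"] + enh["end"]) // 2
    mids = {c: np.sort(g["mid"].to_numpy()) for c, g in enh.groupby("chrom")}
    bpos = {c: np.sort(np.asarray(p)) for c, p in boundary_positions.items()}
    results = []
    for gcls in classes:
        sub = genes[genes["cls"] == gcls]
        if sub.empty:
            continue
        n_used = obs = ctl = 0
        for chrom, p in zip(sub["chrom"], sub["start"]):
            if chrom not in mids or mids[chrom].size == 0:
                continue
            mm = mids[chrom]
            e = int(mm[np.argmin(np.abs(mm - p))])
            c = 2 * int(p) - e
            if c < 0 or c > chrom_sizes.get(chrom, np.inf):
                continue  # mirror site off-chromosome: drop from both counts
            pos = bpos.get(chrom, np.array([]))
            n_used += 1
            obs += _hit_between(p, e, pos)
            ctl += _hit_between(p, c, pos)
        res = EnrichmentResult(gcls, n_used, int(obs), int(ctl))
        if res.control_count == 0:
            warnings.warn(f"class {gcls!r}: control count 0, enrichment undefined",
                          RuntimeWarning)
        results.append(res)
    return results
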