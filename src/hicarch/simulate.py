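"""Synthetic Hi-C matrices and feature tracks with known ground truth.

The generator produces per-chromosome contact matrices under the standard
multiplicative Poisson model of Hi-C counts: a power-law distance decay
modulated by a checkerboard compartment term, block-TAD enrichment and
punctate Gaussian loop bumps, scaled to a target sequencing depth.  Matched
feature tracks (genes with planted DE classes, enhancer sets at controlled
distances, boundaries planted between promoters and enhancers at controlled
rates) give every downstream statistic a known truth to recover.

Every draw is a pure function of (spec, truth, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import GenerationError
from .matrix import ContactMatrix

__all__ = [
    "GenomeSpec",
    "ArchitectureTruth",
    "FeatureTruth",
    "FeatureSet",
    "default_genome",
    "default_truth",
    "simulate_matrix",
    "simulate_condition_pair",
    "simulate_features",
]


@dataclass(frozen=True)
class GenomeSpec:
    """One synthetic chromosome: name, length, bin size and master seed."""

    chrom: str = "chrS"
    length_bp: int = 50_000_000
    bin_size: int = 25_000
    seed: int = 0

    def __post_init__(self):
        if self.length_bp % self.bin_size:
            raise ValueError("length_bp must be divisible by bin_size")

    @property
    def n_bins(self) -> int:
        return self.length_bp // self.bin_size


@dataclass
class ArchitectureTruth:
    """Ground-truth 3D architecture parameters of a simulated chromosome.

    comp_signs : +/-1 per bin (A-like / B-like), amplitude ``delta_comp``.
    tads : non-overlapping [start_bin, end_bin) intervals, enrichment
        ``delta_tad`` for intra-TAD pairs.
    loops / ep_pairs : anchor bin pairs receiving a focal Gaussian bump of
        amplitude ``lam`` (loops sit at TAD corners, E-P pairs inside TADs).
    alpha : power-law contact-decay exponent (< 0).
    depth : expected total cis counts (distinct pairs).
    """

    comp_signs: np.ndarray
    delta_comp: float
    tads: list
    delta_tad: float
    loops: list
    ep_pairs: list
    lam: float
    alpha: float = -1.0
    depth: float = 1e6

    def __post_init__(self):
        if min(self.delta_comp, self.delta_tad, self.lam) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.alpha >= 0:
            raise ValueError("decay exponent must be negative")
        iv = sorted(self.tads)
        for (a0, b0), (a1, _) in zip(iv, iv[1:]):
            if a1 < b0:
                raise ValueError("TADs must be non-overlapping")

    def boundary_bins(self) -> np.ndarray:
        """Interior TAD boundary bins (shared edges of consecutive TADs)."""
        cuts = sorted({b for iv in self.tads for b in iv})
        n_max = max(b for _, b in self.tads)
        return np.array([c for c in cuts if 0 < c < n_max], dtype=int)


def default_genome(seed: int = 0, length_bp: int = 50_000_000,
                   bin_size: int = 25_000) -> GenomeSpec:
    return GenomeSpec(length_bp=length_bp, bin_size=bin_size, seed=seed)


def boundary_benchmark(seed: int = 0, n_tads: int = 20, delta_tad: float = 0.6,
                       depth: float = 5e5):
    """The TAD-only boundary-calling benchmark instance.

    Twenty TADs at delta_tad = 0.6 and depth 5e5 on the default chromosome,
    with no compartment or loop structure so the planted domain edges are
    the only true insulation boundaries.  Returns (genome, truth, matrix).
    """
    g = default_genome(seed=seed)
    truth = default_truth(g, n_tads=n_tads, delta_comp=0.0,
                          delta_tad=delta_tad, lam=0.0, depth=depth)
    return g, truth, simulate_matrix(g, truth)


def default_truth(
    g: GenomeSpec,
    n_tads: int = 20,
    delta_comp: float = 0.4,
    delta_tad: float = 0.6,
    lam: float = 1.0,
    alpha: float = -1.0,
    depth: float = 1e6,
    comp_block_mean_bins: int = 10,
    n_loops: int = 100,
    n_ep_pairs: int = 60,
) -> ArchitectureTruth:
    """Benchmark architecture: alternating compartment blocks of geometric
    length, ``n_tads`` TADs tiling the chromosome with sizes uniform within
    0.6-1.4x the mean, loops at uniformly placed anchor pairs (0.75-2.5 Mb
    separation, so the pile-up background O/E is 1 by construction) and
    random intra-TAD enhancer-promoter pairs.  Deterministic given ``g.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([g.seed, 101]))
    n = g.n_bins

    signs = np.empty(n, dtype=float)
    pos, s = 0, 1.0
    while pos < n:
        block = int(rng.geometric(1.0 / comp_block_mean_bins))
        signs[pos: pos + block] = s
        s = -s
        pos += block

    raw_sizes = rng.uniform(0.6, 1.4, size=n_tads)
    sizes = np.maximum(np.round(raw_sizes / raw_sizes.sum() * n).astype(int), 3)
    cuts = np.concatenate([[0], np.cumsum(sizes)])
    cuts[-1] = n
    tads = [(int(a), int(b)) for a, b in zip(cuts, cuts[1:]) if b > a]

    sep_lo = max(2, (750_000 // g.bin_size))
    sep_hi = max(sep_lo + 1, 2_500_000 // g.bin_size)
    loops = []
    for _ in range(n_loops):
        sep = int(rng.integers(sep_lo, sep_hi + 1))
        a1 = int(rng.integers(8, n - sep - 8))
        loops.append((a1, a1 + sep))

    ep_pairs = []
    for _ in range(n_ep_pairs):
        t0, t1 = tads[rng.integers(len(tads))]
        size = t1 - t0
        if size < 12:
            continue
        sep = int(rng.integers(8, min(40, size - 2)))
        a1 = int(rng.integers(t0 + 1, t1 - sep - 1))
        ep_pairs.append((a1, a1 + sep))

    return ArchitectureTruth(
        comp_signs=signs, delta_comp=delta_comp, tads=tads, delta_tad=delta_tad,
        loops=loops, ep_pairs=ep_pairs, lam=lam, alpha=alpha, depth=depth,
    )


def _intensity(g: GenomeSpec, truth: ArchitectureTruth) -> np.ndarray:
    from scipy.linalg import toeplitz

    n = g.n_bins
    decay_by_d = np.zeros(n)
    dd = np.arange(1, n, dtype=float)
    decay_by_d[1:] = (dd * g.bin_size) ** truth.alpha
    mu = toeplitz(decay_by_d)

    comp = 1.0 + truth.delta_comp * np.outer(truth.comp_signs, truth.comp_signs)
    n_clip = int(np.sum(comp < 0))
    if n_clip:
        warnings.warn(f"{n_clip} negative compartment intensities clipped to 0",
                      RuntimeWarning)
        comp = np.clip(comp, 0.0, None)
    mu *= comp

    tad_id = np.full(n, -1)
    for k, (a, b) in enumerate(truth.tads):
        tad_id[a:b] = k
    same = (tad_id[:, None] == tad_id[None, :]) & (tad_id[:, None] >= 0)
    mu *= 1.0 + truth.delta_tad * same

    if truth.lam > 0:
        bump = np.zeros((n, n))
        offs = [(di, dj) for di in range(-2, 3) for dj in range(-2, 3)]
        for a1, a2 in list(truth.loops) + list(truth.ep_pairs):
            for di, dj in offs:
                i, j = a1 + di, a2 + dj
                if 0 <= i < n and 0 <= j < n:
                    k = np.exp(-(di * di + dj * dj) / 2.0)
                    bump[i, j] += k
                    bump[j, i] += k
        mu *= 1.0 + truth.lam * bump

    np.fill_diagonal(mu, 0.0)
    total = np.triu(mu, k=1).sum()
    if total <= 0:
        raise GenerationError("zero total intensity; check depth/architecture")
    mu *= truth.depth / total
    return mu


def _poisson_icdf(u: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Vectorized Poisson inverse CDF (monotone in u for every mu).

    Using the inverse CDF on a shared uniform stream — rather than a native
    Poisson sampler whose per-draw consumption of randomness varies — keeps
    paired condition draws coupled pixel by pixel (common random numbers).
    Small intensities go through direct series accumulation; the few large
    ones fall back to scipy.
    """
    from scipy import stats

    x = np.zeros(mu.shape, dtype=np.int64)
    small = mu < 4.0
    if small.any():
        k_small = np.zeros(int(small.sum()), dtype=np.int64)
        # shrink the active set as entries resolve; most intensities are
        # tiny, so nearly everything settles within the first couple of terms
        idx = np.arange(k_small.size)
        m = mu[small]
        us = u[small]
        p = np.exp(-m)
        cdf = p.copy()
        k = 0
        while idx.size and k < 40:
            done = us <= cdf
            k_small[idx[done]] = k
            keep = ~done
            idx, m, us, p, cdf = idx[keep], m[keep], us[keep], p[keep], cdf[keep]
            if not idx.size:
                break
            k += 1
            p *= m / k
            cdf += p
        if idx.size:  # numerically extreme tail; exact fallback
            k_small[idx] = stats.poisson.ppf(us, m)
        x[small] = k_small
    big = ~small
    if big.any():
        x[big] = stats.poisson.ppf(u[big], mu[big]).astype(np.int64)
    return x


def simulate_matrix(g: GenomeSpec, truth: ArchitectureTruth,
                    seed: int | None = None) -> ContactMatrix:
    """Draw a symmetric Poisson contact matrix from the truth intensity."""
    if truth.depth <= 0:
        raise GenerationError("sequencing depth must be positive")
    mu = _intensity(g, truth)
    rng = np.random.default_rng(
        np.random.SeedSequence([g.seed if seed is None else int(seed), 202])
    )
    n = g.n_bins
    iu = np.triu_indices(n, k=1)
    u = rng.random(iu[0].size)
    counts = np.zeros((n, n), dtype=np.int64)
    counts[iu] = _poisson_icdf(u, mu[iu])
    counts = counts + counts.T
    return ContactMatrix(
        chrom=g.chrom, bin_size=g.bin_size, counts=counts.astype(float),
        layer="raw", valid_mask=counts.sum(axis=0) > 0,
        meta={"depth": truth.depth, "seed": g.seed if seed is None else int(seed)},
    )


def simulate_condition_pair(
    g: GenomeSpec,
    truth: ArchitectureTruth,
    relax_comp: float = 1.0,
    relax_tad: float = 1.0,
    relax_loop: float = 1.0,
    seed: int | None = None,
):
    """Paired draws: condition 1 from ``truth``, condition 2 from the relaxed
    truth (amplitudes scaled by the relax factors in [0, 1]).  Both draws use
    the same seed stream so the Poisson noise is coupled across conditions.

    Returns (m1, m2, truth2).
    """
    for f in (relax_comp, relax_tad, relax_loop):
        if not 0 <= f <= 1:
            raise ValueError("relax factors must be in [0, 1]")
    truth2 = replace(
        truth,
        comp_signs=truth.comp_signs.copy(),
        delta_comp=truth.delta_comp * relax_comp,
        delta_tad=truth.delta_tad * relax_tad,
        lam=truth.lam * relax_loop,
    )
    m1 = simulate_matrix(g, truth, seed=seed)
    m2 = simulate_matrix(g, truth2, seed=seed)
    return m1, m2, truth2


@dataclass
class FeatureTruth:
    """Parameters of the synthetic gene/enhancer geometry.

    Up-regulated genes get nearest putative-2C enhancers at a shorter
    distance scale than other genes (and down-regulated genes sit closer to
    ESC enhancers); a boundary is planted strictly between an up-gene
    promoter and its 2C enhancer with probability ``q_between`` versus
    ``q_background`` on the point-mirrored control side.
    """

    n_up: int = 100
    n_down: int = 60
    n_non: int = 340
    c2_scale_up: float = 10_000.0
    c2_scale_other: float = 30_000.0
    esc_scale_down: float = 10_000.0
    esc_scale_other: float = 30_000.0
    min_gap_bp: float = 5_000.0
    q_between: float = 0.6
    q_background: float = 0.2
    enhancer_width: int = 2_000
    n_super: int = 20
    margin_bp: int = 500_000

    def __post_init__(self):
        for q in (self.q_between, self.q_background):
            if not 0 <= q <= 1:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class FeatureSet:
    genes: pd.DataFrame
    de: pd.DataFrame
    enhancers: dict = field(default_factory=dict)   # 'esc' | 'super' | '2c'
    boundaries_bp: np.ndarray = field(default_factory=lambda: np.array([]))
    truth: FeatureTruth | None = None


def _de_row(rng, cls):
    if cls == "up":
        return rng.uniform(1.6, 6.0), rng.uniform(0.0, 0.049)
    if cls == "down":
        return rng.uniform(-6.0, -1.6), rng.uniform(0.0, 0.049)
    # non: |log2fc| <= 1.4 keeps the class unambiguous at the 1.5 threshold
    return rng.uniform(-1.4, 1.4), rng.uniform(0.0, 1.0)


def _place_enhancer(rng, chrom, tss, scale, min_gap, width, length_bp, name):
    for _ in range(100):
        dist = min_gap + rng.exponential(scale)
        sign = 1 if rng.random() < 0.5 else -1
        mid = int(tss + sign * dist)
        if width // 2 <= mid <= length_bp - width // 2:
            return {"chrom": chrom, "start": mid - width // 2,
                    "end": mid + width - width // 2, "name": name}, mid
    raise GenerationError("could not place an enhancer inside the chromosome")


def simulate_features(g: GenomeSpec, truth: ArchitectureTruth,
                      f: FeatureTruth | None = None,
                      seed: int | None = None) -> FeatureSet:
    """Genes, DE table, enhancer sets and planted boundaries for one genome."""
    f = f or FeatureTruth()
    rng = np.random.default_rng(
        np.random.SeedSequence([g.seed if seed is None else int(seed), 303])
    )
    n_total = f.n_up + f.n_down + f.n_non
    span = g.length_bp - 2 * f.margin_bp
    if span <= n_total:
        raise GenerationError("chromosome too short for the requested gene count")
    tss = np.sort(rng.choice(span, size=n_total, replace=False)) + f.margin_bp
    classes = np.array(["up"] * f.n_up + ["down"] * f.n_down + ["non"] * f.n_non,
                       dtype=object)
    rng.shuffle(classes)

    genes = pd.DataFrame({
        "chrom": g.chrom,
        "start": tss,
        "end": tss + 1,
        "name": [f"gene{k:05d}" for k in range(n_total)],
        "cls": classes,
    })
    lfc_fdr = [_de_row(rng, c) for c in classes]
    de = pd.DataFrame({
        "gene": genes["name"],
        "log2fc": [x[0] for x in lfc_fdr],
        "fdr": [x[1] for x in lfc_fdr],
    })

    esc_rows, c2_rows = [], []
    c2_mids = np.empty(n_total, dtype=np.int64)
    super_candidates = []
    for k, (p, cls) in enumerate(zip(tss, classes)):
        esc_scale = f.esc_scale_down if cls == "down" else f.esc_scale_other
        row, _ = _place_enhancer(rng, g.chrom, p, esc_scale, f.min_gap_bp,
                                 f.enhancer_width, g.length_bp, f"esc{k:05d}")
        esc_rows.append(row)
        if cls == "down":
            super_candidates.append(row)

        c2_scale = f.c2_scale_up if cls == "up" else f.c2_scale_other
        row, e_mid = _place_enhancer(rng, g.chrom, p, c2_scale, f.min_gap_bp,
                                     f.enhancer_width, g.length_bp, f"c2_{k:05d}")
        c2_rows.append(row)
        c2_mids[k] = e_mid

    # Boundaries are planted against the *nearest* 2C enhancer midpoint —
    # the same site the enrichment statistic interrogates — not against the
    # gene's own enhancer, which another gene's enhancer can pre-empt.
    boundaries = []
    for p, cls in zip(tss, classes):
        if cls != "up":
            continue
        e_mid = int(c2_mids[np.argmin(np.abs(c2_mids - p))])
        lo, hi = (p, e_mid) if p < e_mid else (e_mid, p)
        if hi - lo > 2:
            if rng.random() < f.q_between:
                boundaries.append(int(rng.integers(lo + 1, hi)))
            c = 2 * int(p) - e_mid
            lo2, hi2 = (p, c) if p < c else (c, p)
            if 0 < lo2 and hi2 < g.length_bp and hi2 - lo2 > 2:
                if rng.random() < f.q_background:
                    boundaries.append(int(rng.integers(lo2 + 1, hi2)))

    esc = pd.DataFrame(esc_rows).assign(cls="esc")
    c2 = pd.DataFrame(c2_rows).assign(cls="2c-putative")
    n_super = min(f.n_super, len(super_candidates))
    if n_super:
        pick = rng.choice(len(super_candidates), size=n_super, replace=False)
        sup = pd.DataFrame([super_candidates[i] for i in pick]).assign(cls="super")
        sup["start"] = np.maximum(sup["start"] - 4_000, 0)
        sup["end"] = sup["end"] + 4_000
    else:
        sup = pd.DataFrame(columns=["chrom", "start", "end", "name", "cls"])

    return FeatureSet(
        genes=genes, de=de,
        enhancers={"esc": esc.sort_values("start").reset_index(drop=True),
                   "super": sup.sort_values("start").reset_index(drop=True)
                   if len(sup) else sup,
                   "2c": c2.sort_values("start").reset_index(drop=True)},
        boundaries_bp=np.sort(np.array(boundaries, dtype=int)),
        truth=f,
    )
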