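"""Shared fixtures: random matrix builders and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import settings

from hicarch.matrix import ContactMatrix

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


def poisson_raw(n=100, seed=0, bin_size=25_000, chrom="chrT",
                bias=True, depth_scale=20.0):
    """Random symmetric Poisson raw matrix with power-law decay and,
    optionally, multiplicative per-bin biases (so ICE has work to do)."""
    rng = np.random.default_rng(seed)
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]).astype(float)
    mu = depth_scale / (d + 1.0)
    if bias:
        b = rng.lognormal(0.0, 0.4, size=n)
        mu = mu * np.outer(b, b)
    iu = np.triu_indices(n, k=1)
    counts = np.zeros((n, n))
    counts[iu] = rng.poisson(mu[iu])
    counts = counts + counts.T
    return ContactMatrix(chrom=chrom, bin_size=bin_size, counts=counts,
                         layer="raw", valid_mask=counts.sum(axis=0) > 0)


def random_balanced(n=120, seed=0, bin_size=25_000, chrom="chrT",
                    nan_frac=0.05):
    """Random positive symmetric matrix on the balanced layer with a few
    invalid bins (NaN rows/columns), for window-statistic oracles."""
    rng = np.random.default_rng(seed)
    a = rng.gamma(2.0, 1.0, size=(n, n))
    a = (a + a.T) / 2.0
    valid = np.ones(n, dtype=bool)
    n_bad = int(round(nan_frac * n))
    if n_bad:
        valid[rng.choice(n, size=n_bad, replace=False)] = False
    a[~valid, :] = np.nan
    a[:, ~valid] = np.nan
    return ContactMatrix(chrom=chrom, bin_size=bin_size, counts=a,
                         layer="balanced", valid_mask=valid)


# ---- brute-force oracles ----------------------------------------------------

def brute_insulation_raw(m, square_span_bp):
    w = square_span_bp // m.bin_size
    n = m.n_bins
    out = np.full(n, np.nan)
    for i in range(w, n - w):
        block = m.counts[i - w:i, i + 1:i + w + 1]
        vals = block[np.isfinite(block)]
        if vals.size >= (w * w) / 2.0:
            out[i] = vals.mean()
    return out


def brute_di(m, window_bp):
    w = window_bp // m.bin_size
    n = m.n_bins
    counts = np.where(np.isfinite(m.counts), m.counts, 0.0)
    out = np.full(n, np.nan)
    for i in range(w, n - w):
        A = counts[i, i - w:i].sum()
        B = counts[i, i + 1:i + w + 1].sum()
        if A + B <= 0:
            continue
        if A == B:
            out[i] = 0.0
            continue
        E = (A + B) / 2.0
        out[i] = np.sign(B - A) * ((A - E) ** 2 / E + (B - E) ** 2 / E)
    return out


def brute_expected(m):
    n = m.n_bins
    v = m.valid_mask
    out = np.full(n, np.nan)
    for d in range(n):
        vals = [m.counts[i, i + d] for i in range(n - d)
                if v[i] and v[i + d] and np.isfinite(m.counts[i, i + d])]
        if vals:
            out[d] = np.mean(vals)
    return out


def brute_nearest(tss_df, targets_df):
    out = np.full(len(tss_df), np.nan)
    for k, (chrom, t) in enumerate(zip(tss_df["chrom"], tss_df["start"])):
        best = np.inf
        for _, row in targets_df[targets_df["chrom"] == chrom].iterrows():
            s, e = row["start"], row["end"]
            if t < s:
                d = s - t
            elif t >= e:
                d = t - e
            else:
                d = 0.0
            best = min(best, d)
        if np.isfinite(best):
            out[k] = best
    return out


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small simulated two-condition dataset on disk (500-bin chromosome)."""
    from hicarch import pipeline

    out = tmp_path_factory.mktemp("dataset")
    cfg = pipeline.make_config({
        "outdir": str(out),
        "seed": 11,
        "genome": {"length_bp": 12_500_000},
        "truth": {"n_tads": 8, "depth": 4e5, "n_loops": 25, "n_ep_pairs": 15},
        "features": {"n_up": 30, "n_down": 15, "n_non": 75},
    })
    pipeline.run_simulate(cfg)
    return out, cfg
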