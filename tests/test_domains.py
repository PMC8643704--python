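"""Unit tests for insulation, boundaries, TADs, DI, and related statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hicarch.domains import (
    BoundarySet, InsulationProfile, TADSet, call_boundaries,
    directionality_index, insulation_normalize, insulation_raw, stable_tads,
    tad_strength, tads_from_boundaries, inter_tad_frequency,
)
from hicarch.exceptions import DimensionError, WindowError
from hicarch.matrix import ContactMatrix

from conftest import brute_di, brute_insulation_raw, poisson_raw, random_balanced


# ---- insulation --------------------------------------------------------------

def test_insulation_matches_brute_force():
    m = random_balanced(n=130, seed=0)
    p = insulation_raw(m, square_span_bp=10 * m.bin_size)
    assert np.allclose(p.raw, brute_insulation_raw(m, 10 * m.bin_size),
                       equal_nan=True)


@given(st.integers(0, 5_000))
def test_insulation_brute_force_property(seed):
    m = random_balanced(n=80, seed=seed, nan_frac=0.1)
    span = 6 * m.bin_size
    p = insulation_raw(m, span)
    assert np.allclose(p.raw, brute_insulation_raw(m, span), equal_nan=True)


def test_insulation_window_too_large():
    m = random_balanced(n=20, seed=1, nan_frac=0.0)
    with pytest.raises(WindowError):
        insulation_raw(m, square_span_bp=10 * m.bin_size)


def test_insulation_span_multiple_of_bin():
    m = random_balanced(n=40, seed=2, nan_frac=0.0)
    with pytest.raises(ValueError):
        insulation_raw(m, square_span_bp=m.bin_size + 1)


def test_insulation_requires_balanced():
    with pytest.raises(ValueError):
        insulation_raw(poisson_raw(n=40), 5 * 25_000)


def test_constant_profile_normalizes_to_zero():
    m = ContactMatrix("chrT", 10, np.full((60, 60), 3.0), layer="balanced")
    p = insulation_normalize(insulation_raw(m, 50), 200)
    finite = np.isfinite(p.normalized)
    assert finite.any()
    assert np.allclose(p.normalized[finite], 0.0, atol=1e-12)


def test_normalize_sign_convention():
    # a dip in raw insulation (more insulating) must map to positive values
    raw = np.full(100, 2.0)
    raw[50] = 1.0
    p = InsulationProfile("chrT", 10, raw=raw, square_span_bp=50)
    out = insulation_normalize(p, norm_span_bp=400)
    assert out.normalized[50] > 0
    assert abs(out.normalized[10]) < abs(out.normalized[50])


# ---- boundary calling ----------------------------------------------------------

def _triangle_profile(n=200, peaks=(60, 140), width=12, amp=1.0):
    """Normalized insulation with triangular peaks at the given bins."""
    x = np.zeros(n)
    for p in peaks:
        for k in range(-width, width + 1):
            if 0 <= p + k < n:
                x[p + k] = max(x[p + k], amp * (1 - abs(k) / width))
    return InsulationProfile("chrT", 10, raw=np.ones(n), normalized=x,
                             square_span_bp=50, norm_span_bp=200)


def test_call_boundaries_finds_peaks():
    p = _triangle_profile()
    b = call_boundaries(p, delta_span_bp=40, min_strength=0.1,
                        smooth_span_bp=30)
    assert len(b) == 2
    assert abs(b.bins[0] - 60) <= 1
    assert abs(b.bins[1] - 140) <= 1
    assert (b.strengths > 0.1).all()


def test_call_boundaries_min_strength_filters():
    p = _triangle_profile(amp=0.2)
    strong = call_boundaries(p, delta_span_bp=40, min_strength=0.05,
                             smooth_span_bp=30)
    weak = call_boundaries(p, delta_span_bp=40, min_strength=5.0,
                           smooth_span_bp=30)
    assert len(strong) == 2
    assert len(weak) == 0


def test_call_boundaries_all_nan_warns():
    p = InsulationProfile("chrT", 10, raw=np.full(50, np.nan),
                          normalized=np.full(50, np.nan))
    with pytest.warns(RuntimeWarning, match="all-NA"):
        b = call_boundaries(p, delta_span_bp=40)
    assert len(b) == 0


def test_call_boundaries_requires_normalized():
    p = InsulationProfile("chrT", 10, raw=np.ones(50))
    with pytest.raises(ValueError):
        call_boundaries(p, delta_span_bp=40)


def test_boundary_set_monotone():
    with pytest.raises(ValueError):
        BoundarySet("chrT", 10, np.array([5, 3]), np.array([1.0, 1.0]))


def test_boundary_positions_bp():
    b = BoundarySet("chrT", 25, np.array([2, 8]), np.array([1.0, 1.0]))
    assert list(b.positions_bp()) == [50, 200]


# ---- TADs ----------------------------------------------------------------------

def test_tads_from_boundaries():
    b = BoundarySet("chrT", 10, np.array([10, 30, 32]), np.ones(3))
    ts = tads_from_boundaries(b, chrom_bins=50, min_tad_bins=3)
    # (30, 32) is shorter than 3 bins and dropped
    assert ts.intervals == [(0, 10), (10, 30), (32, 50)]


def test_tadset_overlap_rejected():
    with pytest.raises(ValueError):
        TADSet("chrT", 10, [(0, 10), (5, 15)])


def test_stable_tads_exact_match():
    a = TADSet("chrT", 10, [(0, 10), (10, 25), (25, 40)])
    b = TADSet("chrT", 10, [(0, 10), (10, 25), (25, 40)])
    stable, only_a, only_b = stable_tads(a, b, tol_bp=50)
    assert len(stable) == 3 and len(only_a) == 0 and len(only_b) == 0


def test_stable_tads_tolerance_and_uniques():
    a = TADSet("chrT", 10, [(0, 10), (20, 30)])
    b = TADSet("chrT", 10, [(0, 11), (60, 80)])
    stable, only_a, only_b = stable_tads(a, b, tol_bp=20)  # tol = 2 bins
    assert stable.intervals == [(0, 10)]
    assert only_a.intervals == [(20, 30)]
    assert only_b.intervals == [(60, 80)]


def test_stable_tads_mutual_nearest():
    # two a-TADs near one b-TAD: only one may match it
    a = TADSet("chrT", 10, [(0, 10), (11, 21)])
    b = TADSet("chrT", 10, [(0, 10)])
    stable, only_a, only_b = stable_tads(a, b, tol_bp=1000)
    assert len(stable) == 1
    assert len(only_a) == 1
    assert len(only_b) == 0


def test_stable_tads_grid_mismatch():
    a = TADSet("chrT", 10, [(0, 10)])
    b = TADSet("chrZ", 10, [(0, 10)])
    with pytest.raises(DimensionError):
        stable_tads(a, b)


# ---- directionality index -------------------------------------------------------

def test_di_matches_brute_force():
    m = random_balanced(n=150, seed=3)
    p = directionality_index(m, window_bp=12 * m.bin_size)
    assert np.allclose(p.di, brute_di(m, 12 * m.bin_size), equal_nan=True)


@given(st.integers(0, 5_000))
def test_di_brute_force_property(seed):
    m = random_balanced(n=70, seed=seed, nan_frac=0.1)
    w = 8 * m.bin_size
    p = directionality_index(m, w)
    assert np.allclose(p.di, brute_di(m, w), equal_nan=True)


def test_di_closed_form_plus_ten():
    n = 11
    a = np.zeros((n, n))
    a[5, 6] = a[6, 5] = 10.0
    m = ContactMatrix("chrT", 1, a, layer="balanced")
    p = directionality_index(m, window_bp=2)
    # bin 5: A = 0 (cols 3,4), B = 10 (cols 6,7) -> DI = +10
    assert p.di[5] == pytest.approx(10.0, abs=1e-12)
    # bin 6 mirrors it
    assert p.di[6] == pytest.approx(-10.0, abs=1e-12)


def test_di_symmetric_window_is_zero():
    n = 21
    a = np.zeros((n, n))
    a[10, 8] = a[8, 10] = 4.0
    a[10, 12] = a[12, 10] = 4.0
    m = ContactMatrix("chrT", 1, a, layer="balanced")
    p = directionality_index(m, window_bp=3)
    assert p.di[10] == 0.0


def test_di_window_validation():
    m = random_balanced(n=30, seed=4, nan_frac=0.0)
    with pytest.raises(WindowError):
        directionality_index(m, window_bp=15 * m.bin_size)
    with pytest.raises(ValueError):
        directionality_index(m, window_bp=m.bin_size + 1)


# ---- TAD strength / inter-TAD ----------------------------------------------------

def test_tad_strength_oracle():
    n = 6
    oe = np.full((n, n), 0.5)
    oe[1:4, 1:4] = 2.0
    m = ContactMatrix("chrT", 10, oe, layer="oe")
    # diagonal excluded: six off-diagonal entries, all 2.0
    assert tad_strength(m, (1, 4)) == pytest.approx(2.0)


def test_tad_strength_empty_warns():
    oe = np.full((6, 6), np.nan)
    m = ContactMatrix("chrT", 10, oe, layer="oe",
                      valid_mask=np.zeros(6, bool))
    with pytest.warns(RuntimeWarning, match="no valid"):
        assert np.isnan(tad_strength(m, (0, 3)))


def test_tad_strength_bounds_checked():
    m = ContactMatrix("chrT", 10, np.ones((6, 6)), layer="oe")
    with pytest.raises(DimensionError):
        tad_strength(m, (4, 9))


def test_inter_tad_frequency_oracle():
    n = 6
    a = np.zeros((n, n))
    a[0, 3] = a[3, 0] = 4.0    # TAD0 x TAD1
    a[1, 2] = a[2, 1] = 6.0    # within TAD0
    a[4, 5] = a[5, 4] = 2.0    # within TAD1
    m = ContactMatrix("chrT", 10, a)
    tads = TADSet("chrT", 10, [(0, 3), (3, 6)])
    freq = inter_tad_frequency(m, tads)
    total = 4.0 + 6.0 + 2.0
    assert freq[0, 1] == pytest.approx(4.0 / total)
    assert freq[1, 0] == freq[0, 1]
    assert freq[0, 0] == 0.0


def test_inter_tad_needs_two_tads():
    m = poisson_raw(n=20, seed=5)
    with pytest.raises(ValueError):
        inter_tad_frequency(m, TADSet("chrT", 25_000, [(0, 20)]))


def test_inter_tad_layer_check():
    from hicarch.matrix import ice_balance
    m = poisson_raw(n=30, seed=6)
    bal = ice_balance(m)
    tads = TADSet("chrT", 25_000, [(0, 15), (15, 30)])
    with pytest.raises(ValueError):
        inter_tad_frequency(bal, tads)                      # wrong layer
    inter_tad_frequency(bal, tads, use_balanced=True)       # correct flag
    with pytest.raises(ValueError):
        inter_tad_frequency(m, tads, use_balanced=True)
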