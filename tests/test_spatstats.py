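import numpy as np
import pytest

from axonseg import spatstats as sps
from axonseg.core import InstanceMap

UNIT = sps.Window(0, 1, 0, 1)
R = np.linspace(0.0, 0.2, 21)


def csr(n, seed, window=UNIT):
    rng = np.random.default_rng(seed)
    return sps.PointPattern(window.sample_uniform(n, rng), window)


# ---------------------------------------------------------------------------
# centroids


def test_centroid_of_small_square_in_micrometres():
    m = np.zeros((32, 32), np.int32)
    m[10:13, 10:13] = 1  # centroid at pixel (11, 11)
    pp = sps.centroids(InstanceMap(m), resolution_nm_per_px=12.0)
    assert pp.n == 1
    assert pp.points[0] == pytest.approx((0.132, 0.132))


def test_one_point_per_instance_inside_its_hull(fiber_fixture):
    from scipy.spatial import ConvexHull, Delaunay

    _, mask = fiber_fixture
    pp = sps.centroids(mask, 11.9)
    assert pp.n == mask.n_instances
    um = 11.9 / 1000.0
    for k, (x, y) in zip(mask.ids, pp.points):
        rows, cols = np.nonzero(mask.labels == k)
        pts = np.column_stack([cols * um, rows * um])
        hull = Delaunay(pts[ConvexHull(pts).vertices])
        assert hull.find_simplex([x, y]) >= 0


def test_empty_mask_gives_empty_pattern():
    pp = sps.centroids(InstanceMap(np.zeros((16, 16), np.int32)), 12.0)
    assert pp.n == 0


# ---------------------------------------------------------------------------
# K estimator


def test_two_point_closed_form_no_correction():
    pp = sps.PointPattern([[0.4, 0.5], [0.6, 0.5]], UNIT)  # distance 0.2
    k = sps.k_est(pp, np.array([0.1, 0.19, 0.2, 0.3]), correction="none")
    # W/(n(n-1)) * (pair counted both ways) = 1/2 * 2 = W = 1 once r >= d
    assert k == pytest.approx([0.0, 0.0, 1.0, 1.0])


def test_k_requires_two_points():
    with pytest.raises(ValueError, match="at least 2"):
        sps.k_est(csr(1, 0), R)


def test_csr_mean_k_matches_pi_r_squared():
    """Translation-corrected K on simulated CSR: mean within 5% of pi r^2."""
    ks = np.array([sps.k_est(csr(500, seed), R) for seed in range(1, 31)])
    mean_k = ks.mean(axis=0)
    theo = np.pi * R**2
    rel = np.abs(mean_k[R > 0.05] - theo[R > 0.05]) / theo[R > 0.05]
    assert rel.max() < 0.05


def test_k_scaling_dimensional_analysis():
    pp = csr(100, 5)
    k1 = sps.k_est(pp, R)
    big = sps.PointPattern(pp.points * 3.0, sps.Window(0, 3, 0, 3))
    k3 = sps.k_est(big, 3.0 * R)
    assert np.allclose(k3, 9.0 * k1)


def test_k_invariant_to_random_thinning_in_expectation():
    rs = np.linspace(0.02, 0.15, 8)
    full = np.zeros(len(rs))
    thin = np.zeros(len(rs))
    for seed in range(40):
        pp = csr(400, 1000 + seed)
        full += sps.k_est(pp, rs) / 40
        rng = np.random.default_rng(seed)
        keep = rng.random(pp.n) < 0.5
        sub = sps.PointPattern(pp.points[keep], UNIT)
        thin += sps.k_est(sub, rs) / 40
    assert np.abs(thin - full).max() < 0.15 * np.pi * rs.max() ** 2


def test_translation_and_isotropic_agree_on_interior_range():
    pp = csr(150, 3)
    rs = np.linspace(0.02, 0.1, 5)  # r <= 10% of window side
    kt = sps.k_est(pp, rs, "translation")
    ki = sps.k_est(pp, rs, "isotropic")
    assert np.abs(ki / kt - 1.0).max() < 0.03


# ---------------------------------------------------------------------------
# centered L


def test_l_centered_identities():
    assert np.allclose(sps.l_centered(np.pi * R**2, R), 0.0)
    assert np.allclose(sps.l_centered(np.zeros_like(R), R), -R)
    with pytest.raises(ValueError, match="negative"):
        sps.l_centered(np.array([-0.1]), np.array([0.1]))


def test_hard_core_grid_pattern_is_negative_below_spacing():
    xs = np.linspace(0.05, 0.95, 10)
    pts = np.array([(x, y) for x in xs for y in xs])  # spacing 0.1
    pp = sps.PointPattern(pts, UNIT)
    rs = np.array([0.03, 0.06, 0.09])
    lc = sps.l_centered(sps.k_est(pp, rs), rs)
    assert (lc < 0).all()
    assert np.allclose(lc, -rs)  # no pairs at all below the spacing


# ---------------------------------------------------------------------------
# kernel intensity


def test_single_point_mass_conservation():
    pp = sps.PointPattern([[0.3, 0.7]], UNIT)
    lam = sps.intensity_kernel(pp, bandwidth=0.15)
    gx = np.linspace(0.005, 0.995, 100)
    xy = np.array([(x, y) for x in gx for y in gx])
    integral = lam(xy).sum() * (0.01) ** 2
    assert integral == pytest.approx(1.0, abs=0.01)


def test_uniform_pattern_recovers_flat_intensity():
    pp = csr(1000, 8)
    lam = sps.intensity_kernel(pp, bandwidth=0.1)
    gx = np.linspace(0.1, 0.9, 15)
    vals = lam(np.array([(x, y) for x in gx for y in gx]))
    assert vals.std() / vals.mean() < 0.2


def test_two_clusters_peak_over_midpoint():
    rng = np.random.default_rng(9)
    c1 = rng.normal([0.25, 0.5], 0.04, (100, 2)).clip(0.01, 0.99)
    c2 = rng.normal([0.75, 0.5], 0.04, (100, 2)).clip(0.01, 0.99)
    pp = sps.PointPattern(np.vstack([c1, c2]), UNIT)
    lam = sps.intensity_kernel(pp, bandwidth=0.05)
    peaks = lam(np.array([[0.25, 0.5], [0.75, 0.5]]))
    mid = lam(np.array([[0.5, 0.5]]))[0]
    assert (peaks > 5 * mid).all()


def test_bad_bandwidth_fails():
    with pytest.raises(ValueError, match="bandwidth"):
        sps.intensity_kernel(csr(10, 0), bandwidth=0.0)


# ---------------------------------------------------------------------------
# inhomogeneous K


def test_constant_intensity_reduces_to_homogeneous():
    pp = csr(100, 5)
    lam = np.full(pp.n, pp.n / UNIT.area)
    ki = sps.k_inhom(pp, lam, R, p=2)
    kh = sps.k_est(pp, R)
    assert np.allclose(ki, kh * (pp.n - 1) / pp.n)


def test_k_inhom_monotone_in_r():
    pp = csr(80, 6)
    lam = sps.intensity_kernel(pp, bandwidth=0.2)
    ki = sps.k_inhom(pp, lam, R)
    assert (np.diff(ki) >= -1e-12).all()


def test_k_inhom_linear_trend_recovers_poisson():
    """Inhomogeneous Poisson with linear intensity, true lambda supplied:
    mean K_inh near pi r^2."""
    rs = np.linspace(0.02, 0.15, 8)
    acc = np.zeros(len(rs))
    n_sim = 60
    for seed in range(n_sim):
        rng = np.random.default_rng(2000 + seed)
        # thinning construction: lambda(x, y) = lam_max * (0.25 + 0.75 x)
        cand = rng.uniform(0, 1, (900, 2))
        keep = rng.random(900) < (0.25 + 0.75 * cand[:, 0])
        pts = cand[keep]
        pp = sps.PointPattern(pts, UNIT)
        lam_true = 900 * (0.25 + 0.75 * pts[:, 0]) / 1.0
        acc += sps.k_inhom(pp, lam_true, rs, p=2) / n_sim
    assert np.abs(acc / (np.pi * rs**2) - 1.0).max() < 0.10


def test_k_inhom_rejects_nonpositive_intensity():
    pp = csr(20, 1)
    lam = np.ones(pp.n)
    lam[3] = 0.0
    with pytest.raises(ValueError, match="non-positive"):
        sps.k_inhom(pp, lam, R)


# ---------------------------------------------------------------------------
# envelopes and bootstrap


def test_envelope_straddles_zero_and_is_deterministic():
    lo1, hi1 = sps.csr_envelope(UNIT, 100, R, n_sim=39, seed=4)
    lo2, hi2 = sps.csr_envelope(UNIT, 100, R, n_sim=39, seed=4)
    assert np.array_equal(lo1, lo2) and np.array_equal(hi1, hi2)
    assert (lo1 <= 0).all() and (hi1 >= 0).all()
    assert (lo1 <= hi1).all()


def test_fresh_csr_inside_envelope_at_nominal_level():
    """Rank-1 envelope over 39 sims is pointwise exact at level 2/40 = 5%,
    so the expected inside fraction is 0.95; check calibration within
    Monte-Carlo error of the trial average."""
    inside = []
    for trial in range(20):
        lo, hi = sps.csr_envelope(UNIT, 150, R, n_sim=39, seed=300 + trial)
        pp = csr(150, 800 + trial)
        lc = sps.l_centered(sps.k_est(pp, R), R)
        inside.append(((lc >= lo) & (lc <= hi)).mean())
    se = np.std(inside, ddof=1) / np.sqrt(len(inside))
    assert np.mean(inside) >= 0.95 - 2 * se
    assert np.mean(inside) > 0.85  # and never grossly miscalibrated


def test_bootstrap_bands_contain_estimate_and_shrink_with_n():
    rs = np.linspace(0.02, 0.12, 6)
    widths = {}
    for n in (250, 1000):
        acc = 0.0
        for seed in range(5):
            pp = csr(n, 50 + seed)
            lo, hi = sps.loh_bootstrap(pp, rs, n_boot=200, seed=seed)
            lc = sps.l_centered(sps.k_est(pp, rs), rs)
            assert ((lc >= lo) & (lc <= hi)).all()
            acc += (hi - lo).mean() / 5
        widths[n] = acc
    assert widths[1000] < widths[250]


def test_bootstrap_bands_of_equal_csr_patterns_overlap():
    rs = np.linspace(0.02, 0.12, 6)
    lo1, hi1 = sps.loh_bootstrap(csr(300, 21), rs, n_boot=200, seed=1)
    lo2, hi2 = sps.loh_bootstrap(csr(300, 22), rs, n_boot=200, seed=2)
    assert sps.band_overlap_fraction(lo1, hi1, lo2, hi2) > 0.9


def test_comparison_plot_writes_figure(tmp_path):
    rs = np.linspace(0.02, 0.12, 6)
    ests = {}
    for name, seed in [("manual", 31), ("automated", 32)]:
        pp = csr(200, seed)
        k = sps.k_est(pp, rs)
        lo, hi = sps.loh_bootstrap(pp, rs, n_boot=100, seed=seed)
        ests[name] = sps.LEstimate(rs, k, sps.l_centered(k, rs), lo, hi)
    out = tmp_path / "l_comparison.png"
    sps.plot_l_comparison(ests, out_path=out)
    assert out.exists() and out.stat().st_size > 0


def test_polygon_window_area_and_containment():
    tri = np.array([[0, 0], [2, 0], [0, 2]])
    win = sps.Window(polygon=tri)
    assert win.area == pytest.approx(2.0)
    assert win.contains(np.array([[0.5, 0.5]]))[0]
    assert not win.contains(np.array([[1.8, 1.8]]))[0]
    rng = np.random.default_rng(0)
    pts = win.sample_uniform(50, rng)
    assert win.contains(pts).all()
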