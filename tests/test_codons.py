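import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcmosaic import (
    CodonGC,
    OrthologPair,
    ZeroVarianceError,
    codon_gc,
    gc_distributions,
    histogram_overlap,
    orthogonal_regression,
    pairwise_position_fits,
)
from oracles import brute_force_codon_counts


class TestCodonGC:
    def test_single_codon_atg(self):
        out = codon_gc("ATG")
        assert (out.gc1, out.gc2, out.gc3) == (0.0, 0.0, 100.0)
        assert out.gc == pytest.approx(100.0 / 3.0)

    def test_two_codons(self):
        out = codon_gc("GCAGCT")
        assert (out.gc1, out.gc2, out.gc3) == (100.0, 100.0, 0.0)
        assert out.gc == pytest.approx(200.0 / 3.0)

    def test_length_not_multiple_of_3_errors(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            codon_gc("ATGA")

    def test_ambiguous_codon_skipped_at_all_positions(self):
        # GNC is dropped entirely; only ATG and GGG are counted.
        assert codon_gc("ATGGNCGGG") == codon_gc("ATGGGG")

    def test_exclude_stop_option(self):
        with_stop = codon_gc("ATGGGGTAA")
        without = codon_gc("ATGGGGTAA", include_stop=False)
        assert without == codon_gc("ATGGGG")
        assert with_stop.gc3 < without.gc3

    def test_matches_brute_force_on_random_cds(self, rng):
        bases = np.array(list("ACGTN"))
        for _ in range(1000):
            n_codons = rng.integers(2, 40)
            seq = "".join(rng.choice(bases, 3 * n_codons, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            if all(b == "N" for b in seq):
                continue
            try:
                out = codon_gc(seq)
            except ValueError:
                assert all(
                    any(b == "N" for b in seq[i : i + 3]) for i in range(0, len(seq), 3)
                )
                continue
            expected = brute_force_codon_counts(seq)
            assert out.gc1 == pytest.approx(expected["gc1"])
            assert out.gc2 == pytest.approx(expected["gc2"])
            assert out.gc3 == pytest.approx(expected["gc3"])
            assert out.gc == pytest.approx(expected["gc"])

    @given(st.lists(st.sampled_from(["ATG", "GCC", "TTT", "CAG", "GAT", "TAA"]), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_gc_identity(self, codons):
        out = codon_gc("".join(codons))
        assert out.gc == pytest.approx((out.gc1 + out.gc2 + out.gc3) / 3.0, abs=1e-9)


class TestOrthogonalRegression:
    def test_exact_on_identity_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fit = orthogonal_regression(x, x)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r == pytest.approx(1.0, abs=1e-12)
        assert fit.n == 5

    def test_collinear_agrees_with_direct_line(self):
        x = np.linspace(30, 60, 20)
        y = 0.7 * x + 12.0
        fit = orthogonal_regression(x, y)
        assert fit.slope == pytest.approx(0.7, abs=1e-9)
        assert fit.intercept == pytest.approx(12.0, abs=1e-9)

    def test_swap_inverts_slope_and_keeps_r(self, rng):
        x = rng.normal(45, 8, 500)
        y = 0.8 * x + rng.normal(0, 3, 500)
        f_xy = orthogonal_regression(x, y)
        f_yx = orthogonal_regression(y, x)
        assert f_yx.slope == pytest.approx(1.0 / f_xy.slope, rel=1e-9)
        assert f_yx.r == pytest.approx(f_xy.r, abs=1e-12)

    def test_shift_changes_only_intercept(self, rng):
        x = rng.normal(45, 8, 300)
        y = 0.8 * x + rng.normal(0, 3, 300)
        base = orthogonal_regression(x, y)
        shifted = orthogonal_regression(x + 5.0, y + 5.0)
        assert shifted.slope == pytest.approx(base.slope, rel=1e-9)
        assert shifted.r == pytest.approx(base.r, abs=1e-12)
        assert shifted.intercept == pytest.approx(base.intercept + 5.0 * (1 - base.slope), abs=1e-9)

    def test_r_equals_pearson(self, rng):
        x = rng.normal(40, 10, 200)
        y = rng.normal(50, 5, 200) + 0.3 * x
        fit = orthogonal_regression(x, y)
        assert fit.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_recovers_known_major_axis(self):
        # Bivariate normal whose leading principal axis has slope 0.8.
        slope_true = 0.8
        u = np.array([1.0, slope_true]) / np.hypot(1.0, slope_true)
        v = np.array([-u[1], u[0]])
        cov = 25.0 * np.outer(u, u) + 1.0 * np.outer(v, v)
        rng = np.random.default_rng(42)
        pts = rng.multivariate_normal([45.0, 40.0], cov, size=5000)
        fit = orthogonal_regression(pts[:, 0], pts[:, 1])
        r_pop = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        assert fit.slope == pytest.approx(slope_true, abs=0.02)
        assert fit.r == pytest.approx(r_pop, abs=0.01)

    def test_rma_slope(self, rng):
        x = rng.normal(45, 8, 400)
        y = 0.8 * x + rng.normal(0, 3, 400)
        fit = orthogonal_regression(x, y, method="rma")
        assert fit.slope == pytest.approx(np.std(y, ddof=1) / np.std(x, ddof=1))

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            orthogonal_regression([1.0, 2.0], [1.0, 2.0])

    def test_zero_variance_errors(self):
        with pytest.raises(ZeroVarianceError):
            orthogonal_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ZeroVarianceError):
            orthogonal_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


def _pairs_from_latent(a: np.ndarray, b: np.ndarray) -> list[OrthologPair]:
    """Build OrthologPair objects directly from (n, 3) latent gc1/gc2/gc3 arrays."""
    pairs = []
    for i in range(a.shape[0]):
        ca = CodonGC(gc=a[i].mean(), gc1=a[i, 0], gc2=a[i, 1], gc3=a[i, 2])
        cb = CodonGC(gc=b[i].mean(), gc1=b[i, 0], gc2=b[i, 1], gc3=b[i, 2])
        pairs.append(OrthologPair(f"a{i}", f"b{i}", ca, cb))
    return pairs


class TestGcDistributions:
    def test_identical_sets_overlap_fully(self, rng):
        lat = rng.uniform(20, 70, size=(100, 3))
        dist = gc_distributions(_pairs_from_latent(lat, lat))
        assert all(v == pytest.approx(1.0) for v in dist["overlap"].values())

    def test_disjoint_gc3_overlap_near_zero(self, rng):
        a = np.column_stack([rng.normal(50, 5, 2000)] * 2 + [rng.normal(60, 5, 2000)])
        b = a.copy()
        b[:, 2] = rng.normal(20, 5, 2000)
        dist = gc_distributions(_pairs_from_latent(a, b))
        assert dist["overlap"]["gc3"] < 0.01
        assert dist["means"][("a", "gc3")] == pytest.approx(60.0, abs=0.5)
        assert dist["means"][("b", "gc3")] == pytest.approx(20.0, abs=0.5)

    def test_single_pair_no_error(self):
        lat = np.array([[40.0, 45.0, 50.0]])
        dist = gc_distributions(_pairs_from_latent(lat, lat))
        assert dist["counts"][("a", "gc1")].sum() == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gc_distributions([])

    def test_overlap_is_min_of_normalized_histograms(self, rng):
        x = rng.normal(40, 5, 500)
        y = rng.normal(44, 5, 500)
        edges = np.arange(0, 102.5, 2.5)
        hx, _ = np.histogram(x, bins=edges)
        hy, _ = np.histogram(y, bins=edges)
        expected = np.minimum(hx / hx.sum(), hy / hy.sum()).sum()
        assert histogram_overlap(x, y) == pytest.approx(expected)


class TestPairwisePositionFits:
    def test_constant_statistic_reported_absent(self, rng):
        a = np.column_stack([rng.normal(50, 5, 50), rng.normal(40, 5, 50), np.full(50, 30.0)])
        fits = pairwise_position_fits(_pairs_from_latent(a, a))
        row = fits[(fits.scope == "species_a") & (fits.x_stat == "gc1") & (fits.y_stat == "gc3")]
        assert row.slope.isna().all() and row.r.isna().all()

    def test_independent_positions_have_near_zero_r(self, rng):
        a = rng.normal(45, 8, size=(10_000, 3))
        fits = pairwise_position_fits(_pairs_from_latent(a, a))
        row = fits[(fits.scope == "species_a") & (fits.x_stat == "gc1") & (fits.y_stat == "gc2")]
        assert abs(row.r.iloc[0]) < 0.05

    def test_correlated_positions_recovered(self, rng):
        gc2 = rng.normal(42, 8, 4000)
        gc1 = gc2 + rng.normal(0, 2, 4000)
        a = np.column_stack([gc1, gc2, rng.normal(50, 8, 4000)])
        fits = pairwise_position_fits(_pairs_from_latent(a, a))
        row = fits[(fits.scope == "species_a") & (fits.x_stat == "gc1") & (fits.y_stat == "gc2")]
        assert row.r.iloc[0] > 0.9

    def test_identical_species_between_fits_are_identity(self, rng):
        a = rng.uniform(25, 65, size=(200, 3))
        fits = pairwise_position_fits(_pairs_from_latent(a, a))
        between = fits[fits.scope == "between"]
        assert np.allclose(between.slope, 1.0)
        assert np.allclose(between.intercept, 0.0, atol=1e-9)
        assert np.allclose(between.r, 1.0)

    def test_scope_and_stat_coverage(self, rng):
        a = rng.uniform(25, 65, size=(10, 3))
        fits = pairwise_position_fits(_pairs_from_latent(a, a))
        # 6 within-species combinations per species + 4 between-species fits.
        assert len(fits[fits.scope == "species_a"]) == 6
        assert len(fits[fits.scope == "species_b"]) == 6
        assert len(fits[fits.scope == "between"]) == 4

    def test_too_few_pairs_errors(self, rng):
        a = rng.uniform(25, 65, size=(2, 3))
        with pytest.raises(ValueError):
            pairwise_position_fits(_pairs_from_latent(a, a))
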