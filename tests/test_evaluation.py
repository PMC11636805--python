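import numpy as np
import pytest

from causalflow.datatypes import ArrayGeometry, CFMatrix, ICMatrix
from causalflow.evaluation import (
    cf_hierarchy_pca,
    default_geometry,
    gini,
    prediction_tests,
    residualize_distance,
    spatial_footprint,
)


def brute_force_gini(v):
    v = np.maximum(np.asarray(v, float), 0.0)
    m = len(v)
    return sum(abs(a - b) for a in v for b in v) / (2 * m * m * v.mean())


class TestGini:
    def test_constant_vector_is_zero(self):
        assert gini(np.full(50, 3.3)) == pytest.approx(0.0, abs=1e-12)

    def test_exponential_distribution_is_half(self):
        draws = np.random.default_rng(0).exponential(size=100_000)
        assert gini(draws) == pytest.approx(0.5, abs=0.005)

    def test_two_point_example(self):
        assert gini(np.array([0.0, 1.0])) == pytest.approx(0.5)

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(100):
            v = rng.exponential(size=rng.integers(2, 40))
            assert gini(v) == pytest.approx(brute_force_gini(v), abs=1e-12)

    def test_negative_entries_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            g = gini(np.array([-1.0, 1.0]))
        assert g == pytest.approx(0.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="Gini"):
            gini(np.zeros(5))


def _grid_matrices(n=20, seed=0, kind="exp"):
    rng = np.random.default_rng(seed)
    ids = [f"u{i}" for i in range(n)]
    geom = default_geometry(ids)
    D = geom.distance_matrix()
    if kind == "exp":
        vals = np.exp(-D)
    else:
        vals = np.ones((n, n))
    np.fill_diagonal(vals, np.nan)
    cf = CFMatrix(values=vals, unit_ids=ids)
    return cf, geom


class TestSpatialFootprint:
    def test_exponential_decay_recovered(self):
        cf, geom = _grid_matrices()
        fp = spatial_footprint(cf, geom, bins=6)
        ok = fp["count"] > 0
        # bin means track exp(-center) up to within-bin curvature
        assert np.allclose(fp["mean"][ok], np.exp(-fp["centers"][ok]), atol=0.05)

    def test_invariant_under_joint_relabeling(self, rng):
        cf, geom = _grid_matrices()
        perm = rng.permutation(cf.n_units)
        ids_p = [cf.unit_ids[i] for i in perm]
        cf_p = CFMatrix(values=cf.values[np.ix_(perm, perm)], unit_ids=ids_p)
        geom_p = ArrayGeometry(ids_p, geom.coordinates[perm])
        a = spatial_footprint(cf, geom, bins=6)
        b = spatial_footprint(cf_p, geom_p, bins=6)
        assert np.allclose(a["mean"], b["mean"], equal_nan=True)

    def test_flat_matrix_gives_flat_curve(self):
        cf, geom = _grid_matrices(kind="flat")
        fp = spatial_footprint(cf, geom, bins=5)
        ok = fp["count"] > 0
        assert np.allclose(fp["mean"][ok], 1.0)
        assert np.allclose(fp["sem"][ok], 0.0)


class TestResidualizeDistance:
    def test_pure_distance_function_residuals_vanish(self):
        # bin-mean detrending removes a pure distance function up to the
        # within-bin curvature, which shrinks with bin width
        cf, geom = _grid_matrices()
        coarse = residualize_distance(cf, geom, bins=6)
        fine = residualize_distance(cf, geom, bins=20)
        ok = np.isfinite(fine)
        assert np.abs(fine[ok]).max() < 0.02
        assert np.abs(fine[ok]).max() < np.abs(coarse[np.isfinite(coarse)]).max()

    def test_constant_offset_cancels(self):
        cf, geom = _grid_matrices()
        shifted = CFMatrix(values=cf.values + 5.0, unit_ids=list(cf.unit_ids))
        a = residualize_distance(cf, geom, bins=6)
        b = residualize_distance(shifted, geom, bins=6)
        ok = np.isfinite(a)
        assert np.allclose(a[ok], b[ok])

    def test_residual_prediction_survives_distance_confound(self, rng):
        # CF and IC share a distance-independent coupling structure on top of
        # a common spatial decay; residualization must keep them correlated
        n = 20
        ids = [f"u{i}" for i in range(n)]
        geom = default_geometry(ids)
        D = geom.distance_matrix()
        coupling = rng.exponential(size=(n, n))
        cf_vals = np.exp(-D / 3) + 0.5 * coupling
        ic_vals = np.exp(-D / 3) + 0.4 * coupling + 0.1 * rng.standard_normal((n, n))
        np.fill_diagonal(cf_vals, np.nan)
        np.fill_diagonal(ic_vals, np.nan)
        cf = CFMatrix(values=cf_vals, unit_ids=ids)
        ic = ICMatrix(values=np.clip(ic_vals, 0, None), unit_ids=ids)
        rep = prediction_tests(cf, ic, geom=geom)
        assert rep.residual.pearson_r > 0.3


class TestPredictionTests:
    def _pair(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"u{i}" for i in range(n)]
        f = rng.standard_normal((n, n))
        np.fill_diagonal(f, np.nan)
        return ids, f

    def test_proportional_matrices_give_perfect_correlation(self):
        ids, f = self._pair()
        s = 0.3 * (f - np.nanmin(f)) / (np.nanmax(f) - np.nanmin(f))
        sig = np.zeros_like(f, dtype=bool)
        sig[np.nan_to_num(f) > 0.5] = True
        cf = CFMatrix(values=f, unit_ids=ids, sig_mask=sig)
        ic = ICMatrix(values=s, unit_ids=ids)
        rep = prediction_tests(cf, ic)
        assert rep.pearson_r == pytest.approx(1.0)
        # CF-significant pairs have larger mean IC by construction
        assert rep.group_means_ic_by_cf[0] > rep.group_means_ic_by_cf[1]

    def test_shuffled_ic_kills_correlation(self):
        ids, f = self._pair(seed=1)
        rng = np.random.default_rng(2)
        sig = np.zeros_like(f, dtype=bool)
        sig[np.nan_to_num(f) > 0.8] = True
        cf = CFMatrix(values=f, unit_ids=ids, sig_mask=sig)
        rejected = 0
        n_shuffles = 30
        for _ in range(n_shuffles):
            s = np.abs(f.copy())
            mask = ~np.isnan(s)
            vals = s[mask]
            rng.shuffle(vals)
            s[mask] = vals
            rep = prediction_tests(cf, ICMatrix(values=s, unit_ids=ids))
            rejected += abs(rep.pearson_r) > 2 / np.sqrt(rep.n_pairs) or (
                rep.group_test_ic_by_cf[1] < 0.05
            )
        assert n_shuffles - rejected >= 0.75 * n_shuffles

    def test_mismatched_units_rejected(self):
        ids, f = self._pair()
        cf = CFMatrix(values=f, unit_ids=ids)
        ic = ICMatrix(values=np.abs(f), unit_ids=list(reversed(ids)))
        with pytest.raises(ValueError, match="same units"):
            prediction_tests(cf, ic)


class TestHierarchyPCA:
    def test_two_block_structure_perfectly_separated(self):
        n = 12
        ids = [f"u{i}" for i in range(n)]
        vals = np.zeros((n, n))
        vals[:6, :6] = 3.0
        vals[6:, 6:] = 1.0
        vals += np.random.default_rng(0).normal(0, 0.05, (n, n))
        np.fill_diagonal(vals, np.nan)
        cf = CFMatrix(values=vals, unit_ids=ids)
        out = cf_hierarchy_pca(cf)
        labels = out["labels"]
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]
        assert out["silhouette"] > 0.5

    def test_identical_columns_flagged_degenerate(self):
        n = 8
        vals = np.tile(np.linspace(0, 1, n)[:, None], (1, n))
        cf = CFMatrix(values=vals, unit_ids=[f"u{i}" for i in range(n)])
        out = cf_hierarchy_pca(cf)
        assert np.isnan(out["silhouette"])

    def test_too_few_units_rejected(self):
        cf = CFMatrix(values=np.full((2, 2), np.nan), unit_ids=["a", "b"])
        with pytest.raises(ValueError, match="3"):
            cf_hierarchy_pca(cf)

    def test_simulator_subnetworks_form_two_clusters(self, short_run):
        from causalflow.embedding import compute_cf_matrix
        from sklearn.metrics import adjusted_rand_score

        sub = short_run.subset(["x1", "x2", "x3", "y4", "y20", "y40", "y60", "y80"]).bin(0.1)
        cf = compute_cf_matrix(sub, d=6, tau=8)
        out = cf_hierarchy_pca(cf)
        truth = [0, 0, 0, 1, 1, 1, 1, 1]
        assert adjusted_rand_score(truth, out["labels"]) == 1.0
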