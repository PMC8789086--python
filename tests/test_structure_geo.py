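"""Ancestry estimation, ordination, and geography regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes

import popgenkit as pk
from popgenkit.fstats import DistanceMatrix

from conftest import make_panel


@pytest.fixture(scope="module")
def reference_setup():
    """Two diverged sources and samples of pure/mixed origin."""
    rng = np.random.default_rng(10)
    s = 6000
    p0 = rng.uniform(0.1, 0.9, s)

    def bn(f):
        return rng.beta(p0 * (1 - f) / f, (1 - p0) * (1 - f) / f)

    fa, fb = bn(0.2), bn(0.2)
    freqs = np.vstack([fa, fb])
    import pandas as pd

    snp = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(s) * 20_000 + 1,
            "cm": np.arange(s) * 0.02,
            "ref": "A",
            "alt": "T",
            "id": [f"v{i}" for i in range(s)],
        }
    )
    ft = pk.FrequencyTable(["SRC_A", "SRC_B"], freqs, np.full((2, s), 2000.0), snp)

    def draw(q):
        mix = q * fa + (1 - q) * fb
        return (rng.random((2, s)) < mix).sum(0).astype(np.int8)

    geno = np.vstack([draw(1.0), draw(1.0), draw(0.5), draw(0.0)])
    panel = make_panel(geno, cm=snp["cm"].to_numpy(), populations=["x"] * 4)
    return panel, ft


class TestSupervisedAncestry:
    def test_pure_sample_assigned_to_its_source(self, reference_setup):
        panel, ft = reference_setup
        res = pk.supervised_ancestry(panel, ft)
        k = res.components.index("SRC_A")
        assert res.q[0, k] >= 0.95
        assert res.q[3, k] <= 0.05

    def test_half_admixed_recovered(self, reference_setup):
        panel, ft = reference_setup
        res = pk.supervised_ancestry(panel, ft)
        assert res.q[2, 0] == pytest.approx(0.5, abs=0.05)

    def test_admixture_flag_threshold(self, reference_setup):
        panel, ft = reference_setup
        res = pk.supervised_ancestry(panel, ft)
        flags = res.admixed_flags("SRC_A", max_other=0.01)
        assert bool(flags[2]) and bool(flags[3])

    def test_loglik_nondecreasing_over_iterations(self, reference_setup):
        panel, ft = reference_setup
        lls = [
            pk.supervised_ancestry(panel.take_samples([2]), ft, max_iter=n).log_likelihood
            for n in (1, 3, 10, 50)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_needs_two_components(self, reference_setup):
        panel, ft = reference_setup
        one = pk.FrequencyTable(
            ["SRC_A"], ft.freqs[:1], ft.counts[:1], ft.snp_table
        )
        with pytest.raises(ValueError):
            pk.supervised_ancestry(panel, one)


class TestPca:
    def test_two_demes_separate_on_pc1(self, two_deme_panel):
        panel, _ = two_deme_panel
        res = pk.pca(panel, n_components=2)
        labels = np.array(
            [0 if s.startswith("A") else 1 for s in panel.sample_ids]
        )
        from sklearn.metrics import silhouette_score

        assert silhouette_score(res.coords[:, :1], labels) > 0.8

    def test_duplicated_sample_identical_coordinates(self, two_deme_panel):
        panel, _ = two_deme_panel
        g = np.vstack([panel.genotypes, panel.genotypes[:1]])
        st = pd.concat(
            [panel.sample_table, panel.sample_table.iloc[:1].assign(id="dup0")],
            ignore_index=True,
        )
        dup = pk.GenotypePanel(g, panel.snp_table, st, None)
        res = pk.pca(dup, n_components=2)
        assert np.allclose(res.coords[0], res.coords[-1], atol=1e-8)

    def test_variance_explained_sums_to_at_most_one(self, two_deme_panel):
        panel, _ = two_deme_panel
        res = pk.pca(panel, n_components=5)
        assert res.variance_explained.sum() <= 1.0 + 1e-9


class TestClassicalMds:
    def test_exact_recovery_of_planted_configuration(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(0, 1, (12, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pk.classical_mds(DistanceMatrix([f"p{i}" for i in range(12)], d), 2)
        _, _, disparity = procrustes(pts, res.coords)
        assert disparity < 1e-12

    def test_two_point_matrix(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        res = pk.classical_mds(DistanceMatrix(["a", "b"], d), 1)
        assert np.allclose(np.abs(res.coords[:, 0]), 1.5)

    def test_constant_shift_preserves_rank_order(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(0, 1, (8, 1))
        d = np.abs(pts - pts.T)
        res1 = pk.classical_mds(DistanceMatrix(list("abcdefgh"), d), 1)
        d2 = d + 0.5
        np.fill_diagonal(d2, 0.0)
        res2 = pk.classical_mds(DistanceMatrix(list("abcdefgh"), d2), 1)
        order1 = np.argsort(res1.coords[:, 0])
        order2 = np.argsort(res2.coords[:, 0])
        assert np.array_equal(order1, order2) or np.array_equal(
            order1, order2[::-1]
        )

    def test_too_many_dimensions_rejected(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            pk.classical_mds(DistanceMatrix(["a", "b"], d), 2)

    def test_pca_and_mds_agree_on_euclidean_data(self, two_deme_panel):
        panel, _ = two_deme_panel
        res_pca = pk.pca(panel, n_components=2)
        # Euclidean distances in the standardized dosage space
        g = panel.genotypes.astype(float)
        mean = g.mean(0)
        p = mean / 2
        x = (g - mean) / np.sqrt(np.clip(p * (1 - p), 1e-12, None))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        res_mds = pk.classical_mds(DistanceMatrix(panel.sample_ids, d), 2)
        _, _, disparity = procrustes(res_pca.coords, res_mds.coords)
        assert disparity < 1e-9


class TestGeoRegression:
    def test_exact_linear_relationship(self):
        rng = np.random.default_rng(13)
        lon = rng.uniform(-70, -40, 30)
        coords = np.column_stack([np.zeros(30), lon])
        res = pk.geo_regression(2.0 * lon, coords, axis="longitude")
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(14)
        rejections = 0
        n_sim = 200
        lon = rng.uniform(-70, -40, 40)
        coords = np.column_stack([np.zeros(40), lon])
        for _ in range(n_sim):
            y = rng.normal(0, 1, 40)
            if pk.geo_regression(y, coords).p_value < 0.05:
                rejections += 1
        # binomial 3-sigma band around 5% of 200
        assert 1 <= rejections <= 20

    def test_zero_variance_predictor_rejected(self):
        coords = np.zeros((5, 2))
        with pytest.raises(ValueError):
            pk.geo_regression(np.arange(5.0), coords)


class TestGreatCircle:
    def test_identical_points_zero(self):
        m = pk.great_circle_matrix(["a", "b"], np.array([[10.0, 20.0], [10.0, 20.0]]))
        assert m.matrix[0, 1] == 0.0

    def test_antipodal_half_circumference(self):
        m = pk.great_circle_matrix(["a", "b"], np.array([[0.0, 0.0], [0.0, 180.0]]))
        assert m.matrix[0, 1] == pytest.approx(np.pi * 6371.0088, rel=1e-6)

    def test_one_degree_longitude_at_equator(self):
        m = pk.great_circle_matrix(["a", "b"], np.array([[0.0, 0.0], [0.0, 1.0]]))
        # R * 1 degree in radians = 6371.0088 * pi/180 = 111.1950
        assert m.matrix[0, 1] == pytest.approx(111.195, abs=0.001)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pk.great_circle_matrix(["a"], np.array([[95.0, 0.0]]))


class TestIsolationByDistance:
    def test_affine_relationship_saturates_permutation_p(self):
        rng = np.random.default_rng(15)
        n = 12
        coords = np.column_stack([np.zeros(n), np.sort(rng.uniform(-70, -40, n))])
        geo = pk.great_circle_matrix([f"p{i}" for i in range(n)], coords)
        gen = DistanceMatrix(geo.labels, 0.001 * geo.matrix + 0.01 * (geo.matrix > 0))
        res = pk.isolation_by_distance(gen, geo, n_perm=199, seed=1)
        assert res.r_squared == pytest.approx(1.0)
        assert res.p_permutation == pytest.approx(1 / 200)

    def test_label_permuted_genetic_matrix_null_slope(self):
        rng = np.random.default_rng(16)
        n = 10
        coords = np.column_stack([np.zeros(n), np.sort(rng.uniform(-70, -40, n))])
        geo = pk.great_circle_matrix([f"p{i}" for i in range(n)], coords)
        slopes = []
        base = 0.001 * geo.matrix
        for _ in range(100):
            perm = rng.permutation(n)
            gen = DistanceMatrix(geo.labels, base[np.ix_(perm, perm)])
            slopes.append(pk.isolation_by_distance(gen, geo, n_perm=9, seed=2).slope)
        assert abs(np.mean(slopes)) < 3 * np.std(slopes) / np.sqrt(len(slopes)) + 1e-4

    def test_mismatched_labels_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError):
            pk.isolation_by_distance(
                DistanceMatrix(["a", "b"], d), DistanceMatrix(["a", "c"], d)
            )
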