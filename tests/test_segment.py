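import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist, pdist, squareform

from audseg.segment import (
    SegmentModel,
    assign_nearest_centroid,
    bootstrap_move_threshold,
    embed_mds,
    excise_central,
    one_step_reassign,
    polar_sector_segments,
    qda_allocate,
    rebuild_match_rate,
    run_kmeans_stable,
    segment_respondents,
)
from tests.conftest import make_blobs_df


class TestKmeansStable:
    def test_separated_blobs_fully_stable(self):
        rng = np.random.default_rng(0)
        F, _ = make_blobs_df(rng, np.eye(4) * 20, n_per=40)
        model, stability = run_kmeans_stable(F, 4, n_runs=6, seed=1)
        assert stability == pytest.approx(1.0)
        assert model.k == 4

    def test_k1_convention(self):
        rng = np.random.default_rng(1)
        F, _ = make_blobs_df(rng, [[0, 0]], n_per=30)
        _, stability = run_kmeans_stable(F, 1, n_runs=3, seed=0)
        assert stability == 1.0

    def test_overlapping_blobs_unstable_not_fatal(self):
        rng = np.random.default_rng(2)
        F, _ = make_blobs_df(rng, np.zeros((5, 3)), n_per=60, sd=1.0)
        _, stability = run_kmeans_stable(F, 5, n_runs=6, seed=0)
        assert stability < 1.0

    def test_k_exceeds_n(self):
        rng = np.random.default_rng(3)
        F, _ = make_blobs_df(rng, [[0.0, 0.0]], n_per=3)
        with pytest.raises(ValueError):
            run_kmeans_stable(F, 10, n_runs=2, seed=0)


class TestMds:
    def test_exact_at_true_dimension(self):
        rng = np.random.default_rng(4)
        pts = pd.DataFrame(rng.normal(size=(25, 2)))
        emb = embed_mds(pts)
        assert np.allclose(pdist(emb.to_numpy()), pdist(pts.to_numpy()), atol=1e-8)

    def test_equilateral_triangle(self):
        tri = pd.DataFrame([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        emb = embed_mds(tri)
        d = pdist(emb.to_numpy())
        assert np.allclose(d, d[0])

    def test_distance_matrix_path_matches_pcoa_oracle(self):
        """Torgerson scaling agrees with scikit-bio's PCoA."""
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(30, 6))
        D = squareform(pdist(pts))
        ids = [f"p{i}" for i in range(30)]
        mine = embed_mds(pd.DataFrame(D, index=ids, columns=ids))
        ref = pcoa(D, number_of_dimensions=2).samples.to_numpy()
        r = np.corrcoef(pdist(mine.to_numpy()), pdist(ref))[0, 1]
        assert r > 1 - 1e-10

    def test_nonsymmetric_rejected(self):
        D = pd.DataFrame([[0, 1], [2, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            embed_mds(D.astype(float))

    def test_high_dim_geometry_preserved(self):
        """Embedded distances track true distances on centroid-like geometry."""
        from audseg.synth import SynthConfig

        rng = np.random.default_rng(6)
        centroids = SynthConfig(n_respondents=0).factor_centroids
        F, _ = make_blobs_df(rng, centroids, n_per=60, sd=1.0)
        emb = embed_mds(F)
        r = np.corrcoef(pdist(emb.to_numpy()), pdist(F.to_numpy()))[0, 1]
        assert r >= 0.9


class TestPolarSectors:
    def test_origin_is_central_and_theta0_in_sector0(self):
        coords = pd.DataFrame([[0.0, 0.0], [2.0, 0.0]], columns=["dim_1", "dim_2"])
        sectors, central = polar_sector_segments(coords, radius_cutoff=0.5)
        assert central.iloc[0] and not central.iloc[1]
        assert sectors.iloc[1] == 0

    def test_uniform_angles_multinomial(self):
        rng = np.random.default_rng(7)
        n = 36_000
        theta = rng.uniform(0, 2 * np.pi, n)
        coords = pd.DataFrame({"dim_1": np.cos(theta), "dim_2": np.sin(theta)})
        sectors, central = polar_sector_segments(coords, radius_cutoff=0.0, n_sectors=36)
        assert not central.any()
        counts = sectors.value_counts()
        p = 1 / 36
        bound = 4 * np.sqrt(n * p * (1 - p))
        assert (abs(counts - n * p) < bound).all()

    def test_bad_sector_count(self):
        coords = pd.DataFrame([[1.0, 0.0]], columns=["dim_1", "dim_2"])
        with pytest.raises(ValueError):
            polar_sector_segments(coords, 0.1, n_sectors=1)


class TestExciseCentral:
    def test_counting(self):
        rng = np.random.default_rng(8)
        pts = pd.DataFrame(rng.normal(size=(5000, 2)))
        assert excise_central(pts, 0.0).sum() == 0
        assert excise_central(pts, 0.02).sum() == 100

    def test_all_identical_all_central(self):
        pts = pd.DataFrame(np.ones((7, 2)))
        # identical radii: ties broken by id, count still ceil(f*n)
        assert excise_central(pts, 0.5).sum() == 4


class TestNearestCentroid:
    def _instance(self, rng, n=200, k=5, d=4):
        F = pd.DataFrame(rng.normal(size=(n, d)), index=[f"r{i}" for i in range(n)])
        C = pd.DataFrame(rng.normal(size=(k, d)), index=[f"s{j}" for j in range(k)],
                         columns=F.columns)
        return F, SegmentModel(centroids=C)

    def test_exact_centroid_and_tie_rule(self):
        C = pd.DataFrame([[0.0, 0.0], [2.0, 0.0]], index=["s0", "s1"], columns=["x", "y"])
        model = SegmentModel(centroids=C)
        F = pd.DataFrame([[0.0, 0.0], [1.0, 0.0]], index=["a", "b"], columns=["x", "y"])
        out, _ = assign_nearest_centroid(F, model)
        assert out.at["a", "label"] == "s0" and out.at["a", "dist_s0"] == 0
        assert out.at["b", "label"] == "s0"  # equidistant -> lowest index

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            F, model = self._instance(rng)
            out, _ = assign_nearest_centroid(F, model)
            D = cdist(F.to_numpy(), model.centroids.to_numpy())
            expect = [model.names[j] for j in D.argmin(axis=1)]
            assert list(out["label"]) == expect

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(10)
        F, model = self._instance(rng, d=4)
        with pytest.raises(ValueError, match="dimension"):
            assign_nearest_centroid(F.iloc[:, :3], model)


class TestOneStepReassign:
    def test_converged_kmeans_is_fixed_point(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(11)
        F, _ = make_blobs_df(rng, np.eye(3) * 10, n_per=50)
        km = KMeans(n_clusters=3, n_init=5, random_state=0).fit(F.to_numpy())
        names = [f"s{j}" for j in range(3)]
        model = SegmentModel(
            centroids=pd.DataFrame(km.cluster_centers_, index=names, columns=F.columns)
        )
        labels = pd.Series([names[j] for j in km.labels_], index=F.index)
        new_labels, new_model, n_moved = one_step_reassign(F, labels, model)
        assert n_moved == 0
        assert (new_labels == labels).all()

    def test_single_mislabeled_moves_once(self):
        F = pd.DataFrame(
            [[0.0, 0.0], [0.1, 0.0], [5.0, 5.0], [5.1, 5.0]],
            index=list("abcd"), columns=["x", "y"],
        )
        model = SegmentModel(
            centroids=pd.DataFrame([[0.05, 0.0], [5.05, 5.0]], index=["s0", "s1"],
                                   columns=["x", "y"])
        )
        labels = pd.Series(["s0", "s1", "s1", "s1"], index=F.index)  # b mislabeled
        _, _, n_moved = one_step_reassign(F, labels, model)
        assert n_moved == 1


class TestBootstrapThreshold:
    def test_noiseless_near_zero(self):
        F = pd.DataFrame(
            np.vstack([np.zeros((30, 2)), np.full((30, 2), 50.0)]),
            index=[f"r{i}" for i in range(60)],
        )
        model = SegmentModel(
            centroids=pd.DataFrame([[0, 0], [50, 50]], index=["a", "b"], columns=F.columns)
        )
        labels = pd.Series(["a"] * 30 + ["b"] * 30, index=F.index)
        delta = bootstrap_move_threshold(F, labels, model, n_boot=40, seed=0)
        assert delta < 1e-6 * 50

    def test_quantile_monotone_and_deterministic(self):
        rng = np.random.default_rng(12)
        F, truth = make_blobs_df(rng, [[0, 0], [3, 0]], n_per=50, sd=1.0)
        model = SegmentModel(
            centroids=pd.DataFrame([[0, 0], [3, 0]], index=["blob_0", "blob_1"],
                                   columns=F.columns)
        )
        d90 = bootstrap_move_threshold(F, truth, model, n_boot=30, quantile=0.90, seed=5)
        d99 = bootstrap_move_threshold(F, truth, model, n_boot=30, quantile=0.99, seed=5)
        again = bootstrap_move_threshold(F, truth, model, n_boot=30, quantile=0.90, seed=5)
        assert d99 >= d90
        assert d90 == again


class TestRebuildMatchRate:
    def _assignments(self, labels, model, F):
        out, _ = assign_nearest_centroid(F, model)
        out["label"] = labels
        return out

    def test_identity_and_counting_and_threshold(self):
        rng = np.random.default_rng(13)
        F, truth = make_blobs_df(rng, [[0, 0], [8, 0]], n_per=25, sd=0.2)
        model = SegmentModel(
            centroids=pd.DataFrame([[0, 0], [8, 0]], index=["blob_0", "blob_1"],
                                   columns=F.columns)
        )
        a, _ = assign_nearest_centroid(F, model)
        assert rebuild_match_rate(a, a, 0.0) == 1.0
        b = a.copy()
        b.loc[b.index[0], "label"] = "blob_1"  # big improvement gap -> real move
        assert rebuild_match_rate(b, a, 0.0) == pytest.approx(49 / 50)
        # edge respondent: improvement below delta still matches
        assert rebuild_match_rate(b, a, delta=100.0) == 1.0

    def test_id_mismatch(self):
        rng = np.random.default_rng(14)
        F, truth = make_blobs_df(rng, [[0, 0]], n_per=5)
        model = SegmentModel(centroids=pd.DataFrame([[0.0, 0.0]], index=["s"],
                                                    columns=F.columns))
        a, _ = assign_nearest_centroid(F, model)
        b = a.copy()
        b.index = [f"x{i}" for i in range(5)]
        with pytest.raises(ValueError):
            rebuild_match_rate(a, b, 0.0)


class TestQda:
    def test_separated_classes(self):
        rng = np.random.default_rng(15)
        F, truth = make_blobs_df(rng, [[0, 0, 0], [8, 8, 8]], n_per=150, sd=1.0)
        labels_new, acc, report = qda_allocate(F, truth, F)
        assert acc >= 0.99
        assert (labels_new == pd.Series(report["confusion"].columns[0], index=F.index)).sum() > 0

    def test_consistency_on_training_data(self):
        rng = np.random.default_rng(16)
        F, truth = make_blobs_df(rng, [[0, 0], [2, 0], [0, 2]], n_per=80, sd=0.8)
        labels_new, acc, _ = qda_allocate(F, truth, F)
        again, _, _ = qda_allocate(F, truth, F)
        assert (labels_new == again).all()

    def test_matches_sklearn_qda_on_well_conditioned_data(self):
        """Independent cross-check against sklearn's QDA."""
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

        rng = np.random.default_rng(19)
        F, truth = make_blobs_df(rng, [[0, 0], [2.0, 0.5], [0.5, 2.0]], n_per=120, sd=1.0)
        labels_new, _, _ = qda_allocate(F, truth, F)
        ref = QuadraticDiscriminantAnalysis().fit(F.to_numpy(), truth.to_numpy())
        assert (labels_new.to_numpy() == ref.predict(F.to_numpy())).mean() > 0.99

    def test_tiny_class_regularized(self):
        rng = np.random.default_rng(17)
        F, truth = make_blobs_df(rng, [[0, 0, 0], [9, 9, 9]], n_per=50, sd=0.5)
        extra = pd.DataFrame([[20.0, 20.0, 20.0]], index=["solo"], columns=F.columns)
        F2 = pd.concat([F, extra])
        truth2 = pd.concat([truth, pd.Series({"solo": "blob_2"})])
        labels_new, acc, report = qda_allocate(F2, truth2, F2)
        assert report["regularized"]
        assert acc > 0.9


def test_central_group_reinstatement_preserves_noncentral_labels():
    """Carving out then reinstating the central group leaves the outer
    segment structure intact under delta-thresholded matching."""
    rng = np.random.default_rng(18)
    centers = np.array([[6, 0], [-6, 0], [0, 6]], dtype=float)
    F, truth = make_blobs_df(rng, centers, n_per=80, sd=0.7)
    central_pts = pd.DataFrame(
        rng.normal(scale=0.2, size=(10, 2)),
        index=[f"c{i}" for i in range(10)], columns=F.columns,
    )
    Fall = pd.concat([F, central_pts])
    with_central = segment_respondents(Fall, k=3, central_fraction=10 / len(Fall),
                                       n_runs=4, seed=0)
    no_central = segment_respondents(Fall, k=3, central_fraction=0.0, n_runs=4, seed=0)
    outer = F.index
    delta = bootstrap_move_threshold(
        Fall, with_central.assignments["label"], with_central.model, n_boot=30, seed=0
    )
    a = with_central.assignments.loc[outer]
    b = no_central.assignments.loc[outer]
    # label names differ between builds; compare partition agreement instead
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(a["label"], b["label"]) == pytest.approx(1.0)
    assert rebuild_match_rate(a, with_central.assignments.loc[outer], delta) == 1.0
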