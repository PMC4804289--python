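"""Preprocessing, outlier screen, PCA/HCA and supercluster discovery."""
import numpy as np
import pandas as pd
import pytest

from cocageo import dataio, explore, synthetic_data as sd


class TestPreprocess:
    def test_autoscale_definition(self, default_dataset):
        _, X = explore.preprocess_features(default_dataset)
        assert np.nanmean(X, axis=0) == pytest.approx(np.zeros(7), abs=1e-9)
        assert np.nanstd(X, axis=0, ddof=1) == pytest.approx(np.ones(7), abs=1e-9)

    def test_deterministic(self, default_dataset):
        m1, X1 = explore.preprocess_features(default_dataset)
        m2, X2 = explore.preprocess_features(default_dataset)
        assert np.array_equal(m1.center, m2.center)
        assert np.array_equal(X1, X2, equal_nan=True)

    def test_log10_closed_form(self, small_dataset):
        model, _ = explore.preprocess_features(small_dataset)
        values = small_dataset.values.iloc[:3].copy()
        values["tropacocaine"] = [1.0, 10.0, 100.0]
        raw = explore.PreprocessModel(model.transform, np.zeros(7), np.ones(7))
        out = raw.transform_values(values)
        assert out[:, 0] == pytest.approx([0.0, 1.0, 2.0])

    def test_constant_variable_rejected(self, small_dataset):
        ds = small_dataset.subset(range(10))
        ds.frame.loc[:, "d18O"] = 5.0
        with pytest.raises(dataio.DataError, match="constant"):
            explore.preprocess_features(ds)


class TestOutlierScreen:
    def test_single_gross_outlier_flagged_extreme(self):
        # values 1..9 plus 100: the Tukey fences must grade 100 extreme
        counts = {"Chapare": 10, "UHV": 10}
        ds = sd.simulate_dataset(per_region_n=counts, seed=1)
        ds.frame.loc[0, "d18O"] = 100.0
        report = explore.screen_outliers(ds)
        flagged = report.univariate.query("variable == 'd18O' and grade == 'extreme'")
        assert ds.frame.loc[0, "sample_id"] in set(flagged["sample_id"])

    def test_tukey_fences_on_known_values(self):
        vals = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100.0])
        q1, q3 = np.percentile(vals, [25, 75])
        assert 100 > q3 + 3.0 * (q3 - q1)  # the oracle for the grade

    def test_gaussian_false_positive_rate(self, default_dataset):
        report = explore.screen_outliers(default_dataset, d2_quantile=0.975)
        frac = len(report.multivariate) / len(default_dataset)
        # clean-by-construction classes: close to the 2.5% nominal rate
        assert 0.005 < frac < 0.06

    def test_idempotent_and_side_effect_free(self, small_dataset):
        before = small_dataset.frame.copy()
        r1 = explore.screen_outliers(small_dataset)
        r2 = explore.screen_outliers(small_dataset)
        pd.testing.assert_frame_equal(small_dataset.frame, before)
        pd.testing.assert_frame_equal(r1.univariate, r2.univariate)

    def test_injected_contamination_detected(self):
        cfg = sd.ArtifactConfig(outlier_fraction=0.07, outlier_inflation=4.0, seed=2)
        ds = sd.simulate_dataset(cfg=cfg, seed=2)
        report = explore.screen_outliers(ds)
        truth = ds.outlier_truth
        flagged = set(report.univariate["sample_id"]) | set(report.multivariate["sample_id"])
        hit = ds.frame["sample_id"].isin(flagged).to_numpy()
        # inflated rows are recovered far above the base false-positive rate
        recall = hit[truth.to_numpy()].mean()
        assert recall > 1 / 3
        assert truth.mean() * 0.5 < report.flagged_fraction < 0.3


class TestPCA:
    def test_rank_one_matrix(self, rng):
        u = rng.normal(size=(30, 1))
        v = rng.normal(size=(1, 7))
        scores, loadings, frac = explore.pca_summary(u @ v, 3)
        assert frac[0] == pytest.approx(1.0)

    def test_reconstruction_identity(self, rng):
        X = rng.normal(size=(25, 7))
        scores, loadings, frac = explore.pca_summary(X, 7)
        recon = scores @ loadings.T + X.mean(axis=0)
        assert recon == pytest.approx(X, abs=1e-9)
        assert loadings.T @ loadings == pytest.approx(np.eye(7), abs=1e-9)

    def test_matches_covariance_eigendecomposition(self, rng):
        X = rng.normal(size=(10, 7))
        _, loadings, frac = explore.pca_summary(X, 7)
        w = np.linalg.eigvalsh(np.cov(X, rowvar=False))[::-1]
        assert frac == pytest.approx(w / w.sum(), abs=1e-9)

    def test_variance_fractions_monotone(self, default_dataset):
        _, X = explore.preprocess_features(default_dataset)
        _, _, frac = explore.pca_summary(explore.complete_matrix(X), 7)
        assert np.all(np.diff(frac) <= 1e-12)
        assert frac.sum() <= 1 + 1e-9


class TestHCA:
    def test_identical_classes_merge_first(self, params_by_name):
        p = params_by_name["Chapare"]
        a = sd.sample_region(p, 60, seed=1).to_numpy()
        b = sd.sample_region(p, 60, seed=2).to_numpy()  # same generative law
        c = sd.sample_region(params_by_name["Arauca"], 60, seed=3).to_numpy()
        X = np.vstack([a, b, c])
        labels = ["twin1"] * 60 + ["twin2"] * 60 + ["other"] * 60
        Z, names = explore.hca_dendrogram(X, labels, metric="euclidean")
        first = {names[int(Z[0, 0])], names[int(Z[0, 1])]}
        assert first == {"twin1", "twin2"}
        assert np.all(np.diff(Z[:, 2]) >= -1e-9)  # non-decreasing merge heights

    def test_euclidean_matches_bruteforce_average_linkage(self, rng):
        # 5 singleton classes -> centroids are the points themselves
        pts = rng.normal(size=(5, 7))
        labels = [f"c{i}" for i in range(5)]
        Z, names = explore.hca_dendrogram(pts, labels, metric="euclidean")
        # brute-force average linkage over all merge orders
        clusters = {i: [i] for i in range(5)}
        heights = []
        while len(clusters) > 1:
            best = None
            for a in clusters:
                for b in clusters:
                    if a >= b:
                        continue
                    d = np.mean([np.linalg.norm(pts[i] - pts[j])
                                 for i in clusters[a] for j in clusters[b]])
                    if best is None or d < best[0]:
                        best = (d, a, b)
            d, a, b = best
            heights.append(d)
            clusters[min(a, b)] = clusters.pop(a) + clusters.pop(b)
        assert Z[:, 2] == pytest.approx(np.array(heights), rel=1e-9)

    def test_row_order_invariance(self, small_dataset):
        _, X = explore.preprocess_features(small_dataset)
        labels = small_dataset.regions.to_numpy()
        Z1, _ = explore.hca_dendrogram(X, labels)
        perm = np.random.default_rng(0).permutation(len(X))
        Z2, _ = explore.hca_dendrogram(X[perm], labels[perm])
        assert Z1[:, 2] == pytest.approx(Z2[:, 2], rel=1e-9)


class TestSuperclusters:
    def test_three_separated_blobs(self, rng):
        centers = np.array([[0, 0], [40, 0], [0, 40]], float)
        X = np.vstack([rng.normal(c, 1.0, size=(60, 2)) for c in centers])
        labels = np.repeat([f"r{i}{j}" for i in range(3) for j in range(2)], 30)
        tree = explore.mbc_superclusters(X, labels, k_range=range(2, 7), seed=0)
        assert 3 in tree.bic_trace
        best_k = min(tree.bic_trace, key=tree.bic_trace.get)
        assert best_k == 3
        top = {frozenset(c.labels) for c in tree.children}
        assert frozenset({"r00", "r01"}) in top

    def test_identical_labels_share_supercluster(self, params_by_name):
        counts = {"Chapare": 50, "Arauca": 50, "Vichada": 50}
        ds = sd.simulate_dataset(per_region_n=counts, seed=4)
        _, X = explore.preprocess_features(ds)
        labels = ds.regions.to_numpy().copy()
        # relabel half of Chapare so two labels share one generative law
        ch = np.flatnonzero(labels == "Chapare")
        labels[ch[:25]] = "UHV"
        tree = explore.mbc_superclusters(X, labels, k_range=range(2, 5), seed=0)
        for child in tree.children:
            if "Chapare" in child.labels:
                assert "UHV" in child.labels

    def test_leaves_enumerate_all_labels_once(self, default_dataset):
        _, X = explore.preprocess_features(default_dataset)
        tree = explore.mbc_superclusters(X, default_dataset.regions.to_numpy(), seed=0)
        leaves = tree.leaves()
        assert sorted(leaves) == sorted(dataio.REGION_NAMES)
        for node in _walk(tree):
            if node.children:
                assert len(node.children) >= 2
                kids = [l for c in node.children for l in c.labels]
                assert sorted(kids) == sorted(node.labels)

    def test_pinned_node(self, default_dataset):
        _, X = explore.preprocess_features(default_dataset)
        tree = explore.mbc_superclusters(X, default_dataset.regions.to_numpy(),
                                         seed=0, pin=("UHV", "Cusco", "Valle de Cauca"))
        top = {frozenset(c.labels) for c in tree.children}
        assert frozenset({"UHV", "Cusco", "Valle de Cauca"}) in top
        assert sorted(tree.leaves()) == sorted(dataio.REGION_NAMES)

    def test_empty_k_range_rejected(self, rng):
        with pytest.raises(dataio.DataError, match="k_range"):
            explore.mbc_superclusters(rng.normal(size=(10, 2)),
                                      ["a"] * 5 + ["b"] * 5, k_range=[])


def _walk(node):
    yield node
    for c in node.children:
        yield from _walk(c)
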