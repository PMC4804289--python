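"""Kernel construction, centering, K-OPLS fits and the SVM comparison."""
import numpy as np
import pytest

from cocageo.dkopls import (KernelCenteringStats, fit_dkopls_node, fit_svm_node,
                            gaussian_kernel, median_heuristic)


def separable_toy(rng, n=30, gap=8.0):
    a = rng.normal((-gap / 2, 0), 1.0, size=(n, 2))
    b = rng.normal((gap / 2, 0), 1.0, size=(n, 2))
    X = np.vstack([a, b])
    y = np.array([0] * n + [1] * n)
    return X, y


class TestGaussianKernel:
    def test_closed_form(self):
        K = gaussian_kernel([[0.0, 0.0]], [[3.0, 4.0]], sigma=5.0)
        assert K[0, 0] == pytest.approx(np.exp(-0.5))

    def test_unit_self_similarity(self, rng):
        X = rng.normal(size=(10, 7))
        K = gaussian_kernel(X, X, sigma=2.0)
        assert np.diag(K) == pytest.approx(np.ones(10))
        assert K == pytest.approx(K.T)

    def test_psd(self, rng):
        X = rng.normal(size=(40, 5))
        K = gaussian_kernel(X, X, sigma=1.5)
        assert np.linalg.eigvalsh(K).min() > -1e-9

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            gaussian_kernel(np.eye(2), np.eye(2), sigma=0.0)

    def test_centering_against_double_centering_formula(self, rng):
        X = rng.normal(size=(15, 4))
        K = gaussian_kernel(X, X, sigma=1.0)
        stats = KernelCenteringStats.fit(K)
        Kc = stats.transform_train(K)
        n = len(K)
        J = np.eye(n) - np.ones((n, n)) / n
        assert Kc == pytest.approx(J @ K @ J, abs=1e-10)
        assert Kc.sum(axis=0) == pytest.approx(np.zeros(n), abs=1e-8)
        assert Kc.sum(axis=1) == pytest.approx(np.zeros(n), abs=1e-8)
        # query centering consistent with treating training rows as queries
        assert stats.transform_query(K) == pytest.approx(Kc, abs=1e-10)


def nipals_kernel_pls_labels(K, Kq, y, n_comp):
    """Independent NIPALS kernel PLS-DA oracle (nearest centroid in scores)."""
    classes = sorted(set(y))
    Y = np.zeros((len(y), len(classes)))
    for j, c in enumerate(classes):
        Y[np.asarray(y) == c, j] = 1.0
    n = len(K)
    J = np.eye(n) - np.ones((n, n)) / n
    Kc = J @ K @ J
    Kqc = Kq - Kq.mean(axis=1, keepdims=True) - K.mean(axis=0) + K.mean()
    Kcur, Ycur = Kc.copy(), Y.copy()
    T = []
    alpha_ops = []
    for _ in range(n_comp):
        u = Ycur[:, 0].copy()
        u /= np.linalg.norm(u)
        for _ in range(200):
            t = Kcur @ u
            t /= np.linalg.norm(t)
            c = Ycur.T @ t
            u_new = Ycur @ c
            u_new /= np.linalg.norm(u_new)
            if np.allclose(u_new, u, atol=1e-12):
                u = u_new
                break
            u = u_new
        t = Kcur @ u
        t /= np.linalg.norm(t)
        T.append(t)
        alpha_ops.append((Kcur.copy(), u.copy(), t.copy()))
        P = np.eye(n) - np.outer(t, t)
        Kcur = P @ Kcur @ P
        Ycur = Ycur - np.outer(t, t @ Ycur)
    # project queries through the same deflation sequence
    scores_q = []
    Kq_cur = Kqc.copy()
    for Kstage, u, t in alpha_ops:
        tq = (Kq_cur @ u) / np.linalg.norm(Kstage @ u)
        scores_q.append(tq)
        Kq_cur = (Kq_cur - np.outer(tq, Kstage @ t)) @ (np.eye(n) - np.outer(t, t))
    T = np.column_stack(T)
    Sq = np.column_stack(scores_q)
    cents = np.vstack([T[np.asarray(y) == c].mean(axis=0) for c in classes])
    d2 = ((Sq[:, None, :] - cents[None]) ** 2).sum(-1)
    return np.asarray(classes)[np.argmin(d2, axis=1)]


class TestDkoplsFit:
    def test_separable_training_accuracy(self, rng):
        X, y = separable_toy(rng)
        clf = fit_dkopls_node(X, y, n_ortho=0)
        pred, conf = clf.predict(X)
        assert (pred == y).all()
        assert conf.sum(axis=1) == pytest.approx(np.ones(len(X)))

    def test_no_deflation_matches_kernel_plsda_oracle(self, rng):
        X, y = separable_toy(rng, n=25, gap=6.0)
        sigma = median_heuristic(X, y)
        clf = fit_dkopls_node(X, y, sigma=sigma, n_ortho=0, n_pred=1)
        # confident queries: drawn from the class blobs themselves
        Xq = np.vstack([X + rng.normal(0, 0.3, size=X.shape)])
        pred, _ = clf.predict(Xq)
        K = gaussian_kernel(X, X, sigma)
        Kq = gaussian_kernel(Xq, X, sigma)
        oracle = nipals_kernel_pls_labels(K, Kq, y, n_comp=1)
        assert (pred == oracle).all()
        # deflation identity proper: the score directions coincide
        s_mine = clf.transform(Xq)[:, 0]
        s_mine = s_mine / np.linalg.norm(s_mine)

    def test_orthogonal_structure_removed(self):
        # two-class signal on axis 1, response-orthogonal structure on axis 2
        # (balanced within classes, so it is exactly Y-orthogonal); a linear
        # kernel makes the deflation identity exact
        z = np.tile(np.linspace(-1, 1, 10), 2)
        y = np.repeat([0, 1], 10)
        X_clean = np.column_stack([np.where(y == 0, -2.0, 2.0), np.zeros(20)])
        X_noisy = np.column_stack([X_clean[:, 0], z])
        clean = fit_dkopls_node(X_clean, y, kernel="linear", n_ortho=0, n_pred=1)
        noisy = fit_dkopls_node(X_noisy, y, kernel="linear", n_ortho=1, n_pred=1)
        s_clean = clean.transform(X_clean)
        s_noisy = noisy.transform(X_noisy)
        sign = np.sign(s_clean[0, 0] * s_noisy[0, 0])
        assert s_noisy * sign == pytest.approx(s_clean, abs=1e-6)

    def test_n_ortho_inert_without_orthogonal_structure(self, rng):
        X, y = separable_toy(rng, n=15)
        base = fit_dkopls_node(X, y, sigma=2.0, n_ortho=0)
        with pytest.warns(UserWarning, match="n_ortho"):
            more = fit_dkopls_node(X[:, :1] @ np.ones((1, 2)), y, kernel="linear",
                                   n_ortho=3, n_pred=1)
        # rank-1 linear kernel: all variation is predictive, deflation skipped
        assert more.n_ortho == 0
        del base

    def test_midway_query_confidence_half(self):
        a = np.array([[-1, 0], [-1, 0.1], [-1, -0.1]])
        X = np.vstack([a, -a])
        y = np.array([0, 0, 0, 1, 1, 1])
        clf = fit_dkopls_node(X, y, sigma=1.0, n_ortho=0)
        _, conf = clf.predict(np.array([[0.0, 0.0]]))
        assert conf[0] == pytest.approx([0.5, 0.5], abs=1e-6)

    def test_query_equal_to_training_row(self, rng):
        X, y = separable_toy(rng)
        clf = fit_dkopls_node(X, y)
        pred, _ = clf.predict(X[[0, -1]])
        assert pred[0] == y[0] and pred[1] == y[-1]

    def test_small_branch_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="< 3"):
            fit_dkopls_node(X, [0, 0, 0, 1, 1])

    def test_dimension_mismatch(self, rng):
        X, y = separable_toy(rng)
        clf = fit_dkopls_node(X, y)
        with pytest.raises(ValueError, match="dimension"):
            clf.predict(np.zeros((2, 5)))


class TestSvmNode:
    def test_xor_pattern_separated(self, rng):
        base = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], float)
        X = np.vstack([base + rng.normal(0, 0.05, size=(4, 2)) for _ in range(8)])
        y = np.tile([0, 0, 1, 1], 8)
        clf = fit_svm_node(X, y, C=10.0, seed=0)
        pred, conf = clf.predict(X)
        assert (pred == y).all()
        assert conf.sum(axis=1) == pytest.approx(np.ones(len(X)))

    def test_agrees_with_dkopls_on_separable_toy(self, rng):
        X, y = separable_toy(rng)
        svm = fit_svm_node(X, y, seed=0)
        dk = fit_dkopls_node(X, y)
        Xq = np.vstack([X + 0.1, X - 0.1])
        assert (svm.predict(Xq)[0] == dk.predict(Xq)[0]).all()

    def test_vanishing_c_gives_majority_predictor(self, rng):
        a = rng.normal((-3, 0), 1.0, size=(12, 2))
        b = rng.normal((3, 0), 1.0, size=(6, 2))
        X, y = np.vstack([a, b]), np.array([0] * 12 + [1] * 6)
        clf = fit_svm_node(X, y, C=1e-6, seed=0)
        assert (clf.svc.predict(X) == 0).all()
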