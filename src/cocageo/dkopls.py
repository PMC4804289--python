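"""Node-level classifiers: kernel-OPLS discriminant (DKOPLS-C) and SVM-C.

The discriminant model projects node training data through a Gaussian
kernel, removes ``n_ortho`` response-orthogonal components by deflating the
centered kernel (kernel-space O-PLS), then extracts ``n_pred`` predictive
components against the class-indicator matrix.  Queries are assigned to the
branch with the nearest class centroid in predictive-score space
(variance-weighted Mahalanobis), with confidences given by a softmax over
negative squared distances.  All linear algebra is deterministic.

The SVM comparison classifier is a soft-margin Gaussian-kernel SVM with
Platt-scaled confidences, exposed through the same predict interface.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse.linalg import eigsh
from scipy.spatial.distance import cdist
from sklearn.svm import SVC


def gaussian_kernel(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    """K[i, j] = exp(-||a_i - b_j||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("dimension mismatch")
    d2 = cdist(A, B, "sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


def linear_kernel(A, B, sigma=None) -> np.ndarray:
    return np.atleast_2d(np.asarray(A, float)) @ np.atleast_2d(np.asarray(B, float)).T


_KERNELS = {"gaussian": gaussian_kernel, "linear": linear_kernel}


def median_heuristic(X: np.ndarray, y=None) -> float:
    """Median pairwise Euclidean distance (default kernel width).

    When branch labels ``y`` are given, the median is taken over
    within-branch pairs only: the pooled median conflates branch separation
    with branch spread and over-smooths tight classes.
    """
    X = np.atleast_2d(np.asarray(X, float))

    def _pair_dists(B):
        if len(B) > 600:  # subsample; deterministic stride
            B = B[:: max(1, len(B) // 600)]
        d = cdist(B, B)
        return d[np.triu_indices_from(d, k=1)]

    if y is None:
        vals = _pair_dists(X)
    else:
        y = np.asarray(y)
        chunks = [_pair_dists(X[y == c]) for c in np.unique(y)
                  if (y == c).sum() > 1]
        vals = np.concatenate(chunks) if chunks else _pair_dists(X)
    vals = vals[vals > 0]
    med = float(np.median(vals)) if len(vals) else 1.0
    return med if med > 0 else 1.0


@dataclass
class KernelCenteringStats:
    """Training-kernel row means and grand mean for double centering."""

    row_means: np.ndarray
    grand_mean: float

    @classmethod
    def fit(cls, K: np.ndarray) -> "KernelCenteringStats":
        return cls(K.mean(axis=0), float(K.mean()))

    def transform_train(self, K: np.ndarray) -> np.ndarray:
        return K - self.row_means[None, :] - self.row_means[:, None] + self.grand_mean

    def transform_query(self, Kq: np.ndarray) -> np.ndarray:
        """Center query-vs-training kernel rows with training statistics."""
        return Kq - Kq.mean(axis=1, keepdims=True) - self.row_means[None, :] + self.grand_mean


@dataclass
class NodeClassifier:
    kind: str                                  # "dkopls" | "svm"
    classes: tuple
    kernel_name: str = "gaussian"
    sigma: float = 1.0
    X_ref: np.ndarray | None = None
    centering: KernelCenteringStats | None = None
    n_ortho: int = 0
    n_pred: int = 1
    Up: np.ndarray | None = None               # dual predictive weights (n x A)
    score_norms: np.ndarray | None = None
    ortho: list = field(default_factory=list)  # [(t, Kt, tKt), ...]
    centroids: np.ndarray | None = None        # (c x A)
    score_precisions: np.ndarray | None = None  # (c x A x A) inverse covariances
    svc: SVC | None = None
    svm_params: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    def predict(self, Xq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(labels, confidence matrix); confidences sum to one per row."""
        if self.kind == "svm":
            Xq = np.atleast_2d(np.asarray(Xq, float))
            proba = self.svc.predict_proba(Xq)
            # align probability columns to self.classes order
            cols = {c: j for j, c in enumerate(self.svc.classes_)}
            conf = np.column_stack([proba[:, cols[c]] for c in self.classes])
            labels = np.asarray(self.classes)[np.argmax(conf, axis=1)]
            return labels, conf
        scores = self.transform(Xq)
        d2 = np.stack([np.einsum("ij,jk,ik->i", scores - self.centroids[k],
                                 self.score_precisions[k], scores - self.centroids[k])
                       for k in range(len(self.classes))], axis=1)
        conf = _softmax(-d2)
        labels = np.asarray(self.classes)[np.argmin(d2, axis=1)]
        return labels, conf

    def transform(self, Xq: np.ndarray) -> np.ndarray:
        """Predictive scores of query rows."""
        Xq = np.atleast_2d(np.asarray(Xq, float))
        if Xq.shape[1] != self.X_ref.shape[1]:
            raise ValueError("query dimension does not match training representation")
        Kq = _KERNELS[self.kernel_name](Xq, self.X_ref, self.sigma)
        Kq = self.centering.transform_query(Kq)
        for t, Kt, tKt in self.ortho:
            # project the orthogonal loading direction out of the query rows
            Kq = Kq - np.outer((Kq @ t) / tKt, Kt)
        return (Kq @ self.Up) / self.score_norms


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _indicator(y, classes) -> np.ndarray:
    Y = np.zeros((len(y), len(classes)))
    for j, c in enumerate(classes):
        Y[np.asarray(y) == c, j] = 1.0
    return Y


def _predictive_weights(K: np.ndarray, Y: np.ndarray, n_pred: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Top eigenvectors of Y'KY -> dual weights Up = Y Cp and raw scores K Up."""
    M = Y.T @ K @ Y
    M = (M + M.T) / 2.0
    w, V = np.linalg.eigh(M)
    order = np.argsort(w)[::-1][:n_pred]
    Cp = V[:, order]
    Up = Y @ Cp
    return Up, K @ Up


def fit_dkopls_node(X: np.ndarray, y: Sequence, sigma: float | None = None,
                    n_ortho: int = 1, n_pred: int | None = None,
                    kernel: str = "gaussian") -> NodeClassifier:
    """Fit a kernel-OPLS discriminant node on (discretized or continuous) X."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y)
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 branches")
    counts = {c: int((y == c).sum()) for c in classes}
    small = [c for c, n in counts.items() if n < 3]
    if small:
        raise ValueError(f"branches with < 3 training samples: {small}")
    if n_pred is None:
        n_pred = max(1, len(classes) - 1)
    n_pred = min(n_pred, len(classes))
    if sigma is None and kernel == "gaussian":
        sigma = median_heuristic(X, y)
    sigma = float(sigma) if sigma is not None else 1.0

    K = _KERNELS[kernel](X, X, sigma)
    centering = KernelCenteringStats.fit(K)
    Kc = centering.transform_train(K)
    Y = _indicator(y, classes)

    ortho_comps: list[tuple[np.ndarray, np.ndarray, float]] = []
    Kcur = Kc
    trace0 = max(float(np.trace(Kc)), 1e-12)
    for _ in range(n_ortho):
        Up, Tp_raw = _predictive_weights(Kcur, Y, n_pred)
        Q, _ = np.linalg.qr(Tp_raw)
        R = Kcur - Q @ (Q.T @ Kcur)
        R = R - (R @ Q) @ Q.T
        R = (R + R.T) / 2.0
        n = len(R)
        if n > 2:
            try:
                v0 = np.full(n, 1.0 / np.sqrt(n))  # deterministic ARPACK start
                lam, vec = eigsh(R, k=1, which="LA", v0=v0)
                lam, t = float(lam[0]), vec[:, 0]
            except Exception:
                w, V = np.linalg.eigh(R)
                lam, t = float(w[-1]), V[:, -1]
        else:
            w, V = np.linalg.eigh(R)
            lam, t = float(w[-1]), V[:, -1]
        if lam <= 1e-10 * trace0:
            warnings.warn("no response-orthogonal variation left; "
                          f"n_ortho reduced to {len(ortho_comps)}")
            break
        t = t / np.linalg.norm(t)
        Kt = Kcur @ t
        tKt = float(t @ Kt)
        if tKt <= 1e-10 * trace0:
            warnings.warn("degenerate orthogonal component; "
                          f"n_ortho reduced to {len(ortho_comps)}")
            break
        ortho_comps.append((t, Kt, tKt))
        # feature-space projection out of the orthogonal loading:
        # K <- K - (Kt)(Kt)'/t'Kt, identical rule for queries
        Kcur = Kcur - np.outer(Kt, Kt) / tKt

    Up, Tp_raw = _predictive_weights(Kcur, Y, n_pred)
    norms = np.linalg.norm(Tp_raw, axis=0)
    norms[norms == 0] = 1.0
    Tp = Tp_raw / norms

    centroids = np.vstack([Tp[y == c].mean(axis=0) for c in classes])
    A = Tp.shape[1]
    pooled = np.zeros((A, A))
    dof = 0
    per_class = []
    for c in classes:
        block = Tp[y == c]
        S = np.atleast_2d(np.cov(block, rowvar=False)) if len(block) > 1 else np.zeros((A, A))
        per_class.append(S)
        pooled += S * max(len(block) - 1, 0)
        dof += max(len(block) - 1, 0)
    pooled = pooled / max(dof, 1)
    ridge = max(float(np.trace(pooled)) / A, 1e-12) * 1e-6
    # class covariances shrunk toward the pooled covariance for stability
    precisions = np.stack([
        np.linalg.inv(0.8 * S + 0.2 * pooled + ridge * np.eye(A))
        for S in per_class])

    return NodeClassifier(kind="dkopls", classes=classes, kernel_name=kernel,
                          sigma=sigma, X_ref=X, centering=centering,
                          n_ortho=len(ortho_comps), n_pred=n_pred, Up=Up,
                          score_norms=norms, ortho=ortho_comps,
                          centroids=centroids, score_precisions=precisions)


def predict_dkopls_node(model: NodeClassifier, Xq: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Branch labels and per-branch confidences for query rows."""
    return model.predict(Xq)


def fit_svm_node(X: np.ndarray, y: Sequence, C: float = 10.0,
                 sigma: float | None = None, seed: int = 0,
                 grid_search: bool = False) -> NodeClassifier:
    """Soft-margin Gaussian-kernel SVM node with Platt-style confidences.

    ``grid_search`` runs a small inner 3-fold search over C and the kernel
    width multiplier; tuned solutions should still be judged on held-out
    data, never on the training fit.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y)
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 branches")
    if sigma is None:
        sigma = median_heuristic(X)
    gamma = 1.0 / (2.0 * sigma**2)
    if grid_search:
        from sklearn.model_selection import GridSearchCV

        grid = {"C": [1.0, 10.0, 100.0], "gamma": [gamma / 4, gamma, gamma * 4]}
        svc = GridSearchCV(SVC(kernel="rbf", probability=True, random_state=seed),
                           grid, cv=3).fit(X, y).best_estimator_
        params = {"C": svc.C, "gamma": svc.gamma, "seed": seed}
    else:
        svc = SVC(kernel="rbf", C=C, gamma=gamma, probability=True,
                  random_state=seed).fit(X, y)
        params = {"C": C, "gamma": gamma, "seed": seed}
    return NodeClassifier(kind="svm", classes=classes, sigma=float(sigma),
                          X_ref=X, svc=svc,
                          svm_params={**params, "y": y.tolist()})
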