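"""Exploratory stage: scaling, outlier screening, clustering, superclusters.

The seven variables mix percent-scale alkaloids (right-skewed, spanning two
orders of magnitude) with per-mil isotope ratios, so alkaloids are log10
transformed and every variable is autoscaled to zero mean / unit variance on
the training data.  Outliers are screened univariately (Tukey fences) and
multivariately (within-class squared Mahalanobis distance against a chi2
quantile); flagged samples are reported, never removed.

Supercluster discovery fits Gaussian mixtures over a range of component
counts, picks the count by BIC, maps each region label to the component
holding the majority of its samples, and recurses within each group.  The
resulting label tree fixes the topology of the hierarchical classifier.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import chi2
from sklearn.mixture import GaussianMixture

from .dataio import ALKALOIDS, VARIABLES, DataError, Dataset


@dataclass
class PreprocessModel:
    transform: dict[str, str]          # "log10" | "identity" per variable
    center: np.ndarray                 # per-variable mean after transform
    scale: np.ndarray                  # per-variable SD after transform
    fitted_on: dict = field(default_factory=dict)

    def transform_values(self, values: pd.DataFrame,
                         censor_mask: pd.DataFrame | None = None) -> np.ndarray:
        """Apply transform + autoscaling; missing cells stay NaN.

        Censored cells (stored at the LOD) are imputed at LOD/2 before the
        transform — the standard substitution for left-censored geochemical
        data.
        """
        X = values.loc[:, list(VARIABLES)].to_numpy(float).copy()
        if censor_mask is not None:
            cm = censor_mask.loc[:, list(VARIABLES)].to_numpy(bool)
            X[cm] = X[cm] / 2.0
        for j, v in enumerate(VARIABLES):
            if self.transform[v] == "log10":
                col = X[:, j]
                col[col <= 0] = np.nan  # negative alkaloid cannot be transformed
                X[:, j] = np.log10(col)
        return (X - self.center) / self.scale


def preprocess_features(dataset: Dataset, policy: str = "default"
                        ) -> tuple[PreprocessModel, np.ndarray]:
    """Fit the transform/autoscale model on a dataset and return (model, X)."""
    transform = {v: ("log10" if (policy == "default" and v in ALKALOIDS) else "identity")
                 for v in VARIABLES}
    probe = PreprocessModel(transform, np.zeros(7), np.ones(7))
    raw = probe.transform_values(dataset.values, dataset.censor_mask)
    center = np.nanmean(raw, axis=0)
    scale = np.nanstd(raw, axis=0, ddof=1)
    if np.any(~np.isfinite(scale)) or np.any(scale <= 0):
        bad = [VARIABLES[j] for j in np.flatnonzero(~(scale > 0))]
        raise DataError(f"constant or empty variable(s) in training data: {bad}")
    model = PreprocessModel(transform, center, scale,
                            fitted_on={"n": len(dataset), "policy": policy})
    return model, (raw - center) / scale


def complete_matrix(X: np.ndarray, labels=None) -> np.ndarray:
    """Impute NaNs by per-class mean (global mean fallback)."""
    X = X.copy()
    col_mean = np.nanmean(X, axis=0)
    if labels is not None:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            rows = labels == lab
            m = np.nanmean(X[rows], axis=0)
            m = np.where(np.isfinite(m), m, col_mean)
            block = X[rows]
            idx = np.isnan(block)
            block[idx] = np.broadcast_to(m, block.shape)[idx]
            X[rows] = block
    idx = np.isnan(X)
    X[idx] = np.broadcast_to(col_mean, X.shape)[idx]
    return X


# ---------------------------------------------------------------------------
# outlier screening
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    univariate: pd.DataFrame   # sample_id, variable, side, grade
    multivariate: pd.DataFrame  # sample_id, region, d2, threshold, grade
    flagged_fraction: float


def screen_outliers(dataset: Dataset, preprocess: PreprocessModel | None = None,
                    fence_k: tuple[float, float] = (1.5, 3.0),
                    d2_quantile: float = 0.975) -> OutlierReport:
    """Tukey-fence and within-class Mahalanobis screening (report-only).

    Values beyond Q1 - k*IQR / Q3 + k*IQR are flagged (k = 1.5 mild,
    3.0 extreme); samples whose within-class squared Mahalanobis distance
    exceeds the chi2(7) quantile are flagged multivariately.  Classes with
    fewer than 8 samples skip the multivariate screen with a warning.
    """
    if preprocess is None:
        preprocess, X = preprocess_features(dataset)
    else:
        X = preprocess.transform_values(dataset.values, dataset.censor_mask)
    ids = dataset.frame["sample_id"]
    uni_rows = []
    mild_k, extreme_k = fence_k
    for j, v in enumerate(VARIABLES):
        col = X[:, j]
        finite = np.isfinite(col)
        q1, q3 = np.nanpercentile(col[finite], [25, 75])
        iqr = q3 - q1
        for i in np.flatnonzero(finite):
            x = col[i]
            if x < q1 - extreme_k * iqr or x > q3 + extreme_k * iqr:
                grade = "extreme"
            elif x < q1 - mild_k * iqr or x > q3 + mild_k * iqr:
                grade = "mild"
            else:
                continue
            side = "low" if x < q1 else "high"
            uni_rows.append((ids.iloc[i], v, side, grade))
    univariate = pd.DataFrame(uni_rows, columns=["sample_id", "variable", "side", "grade"])

    labels = dataset.regions.to_numpy()
    Xc = complete_matrix(X, labels)
    thr = chi2.ppf(d2_quantile, df=7)
    multi_rows = []
    for lab in np.unique(labels):
        rows = np.flatnonzero(labels == lab)
        if len(rows) < 8:
            warnings.warn(f"class {lab!r} has {len(rows)} samples; "
                          "multivariate screen skipped")
            continue
        block = Xc[rows]
        mu = block.mean(axis=0)
        cov = np.cov(block, rowvar=False) + 1e-8 * np.eye(7)
        inv = np.linalg.inv(cov)
        dev = block - mu
        d2 = np.einsum("ij,jk,ik->i", dev, inv, dev)
        for r, val in zip(rows, d2):
            if val > thr:
                grade = "extreme" if val > chi2.ppf(0.999, 7) else "moderate"
                multi_rows.append((ids.iloc[r], lab, float(val), float(thr), grade))
    multivariate = pd.DataFrame(
        multi_rows, columns=["sample_id", "region", "d2", "threshold", "grade"])
    flagged = set(univariate["sample_id"]) | set(multivariate["sample_id"])
    return OutlierReport(univariate, multivariate, len(flagged) / max(len(dataset), 1))


# ---------------------------------------------------------------------------
# PCA / HCA
# ---------------------------------------------------------------------------

def pca_summary(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scores, orthonormal loadings and variance fractions of the top-k PCs."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds {X.shape[1]} variables")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (len(X) - 1)
    frac = var / var.sum() if var.sum() > 0 else var
    scores = U[:, :k] * s[:k]
    return scores, Vt[:k].T, frac[:k]


def pooled_within_cov(X: np.ndarray, labels) -> np.ndarray:
    labels = np.asarray(labels)
    p = X.shape[1]
    S = np.zeros((p, p))
    dof = 0
    for lab in np.unique(labels):
        block = X[labels == lab]
        if len(block) > 1:
            S += (len(block) - 1) * np.cov(block, rowvar=False)
            dof += len(block) - 1
    S = S / max(dof, 1)
    # regularize if near-singular
    w = np.linalg.eigvalsh(S)
    if w.min() < 1e-8 * max(w.max(), 1.0):
        S = S + 1e-6 * np.trace(S) / p * np.eye(p)
    return S


def hca_dendrogram(X: np.ndarray, labels, metric: str = "pooled"
                   ) -> tuple[np.ndarray, list[str]]:
    """Average-linkage merge tree over class centroids.

    Distances between centroids are Mahalanobis in the pooled within-class
    metric (``metric="euclidean"`` uses the identity instead).  Returns the
    scipy linkage matrix and the centroid label order.
    """
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels))
    if len(classes) < 2:
        raise DataError("need at least 2 classes for a dendrogram")
    Xc = complete_matrix(X, labels)
    centroids = np.vstack([Xc[labels == c].mean(axis=0) for c in classes])
    if metric == "pooled":
        S = pooled_within_cov(Xc, labels)
        L = np.linalg.cholesky(np.linalg.inv(S))
        pts = centroids @ L
    else:
        pts = centroids
    d = squareform(np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)), checks=False)
    Z = sch.linkage(d, method="average")
    return Z, [str(c) for c in classes]


# ---------------------------------------------------------------------------
# model-based superclusters
# ---------------------------------------------------------------------------

@dataclass
class SuperclusterNode:
    """A node of the label tree: its label set and (for nonterminals) children."""

    labels: tuple[str, ...]
    children: list["SuperclusterNode"] = field(default_factory=list)
    bic_trace: dict[int, float] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return len(self.labels) == 1

    def leaves(self) -> list[str]:
        if not self.children:
            return list(self.labels)
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_dict(self) -> dict:
        return {"labels": list(self.labels),
                "children": [c.to_dict() for c in self.children],
                "bic_trace": {str(k): v for k, v in self.bic_trace.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "SuperclusterNode":
        node = cls(tuple(d["labels"]),
                   [cls.from_dict(c) for c in d["children"]],
                   {int(k): v for k, v in d.get("bic_trace", {}).items()})
        return node


def _bisect_by_centroids(X, labels, members) -> list[list[str]]:
    """Fallback 2-way split of a label set via centroid linkage."""
    Z, names = hca_dendrogram(X[np.isin(labels, members)],
                              labels[np.isin(labels, members)], metric="euclidean")
    assign = sch.fcluster(Z, t=2, criterion="maxclust")
    groups: dict[int, list[str]] = {}
    for name, g in zip(names, assign):
        groups.setdefault(g, []).append(name)
    if len(groups) < 2:  # degenerate: split off one label
        return [[names[0]], names[1:]]
    return list(groups.values())


def mbc_superclusters(X: np.ndarray, labels, k_range=range(2, 20),
                      seed: int = 0, pin: tuple[str, ...] | None = None
                      ) -> SuperclusterNode:
    """Build the supercluster label tree by recursive model-based clustering.

    At each node, Gaussian mixtures (full covariance, ridge-regularized) are
    fitted for every k in ``k_range`` (clipped to the node's label count);
    the BIC-optimal mixture partitions the labels by majority component
    membership (ties toward the component with the nearer centroid).  Nodes
    a mixture refuses to split fall back to a centroid bisection so every
    nonterminal has >= 2 children and leaves enumerate each label once.

    ``pin`` forces the given label set to form a single child of the root
    (regression-testing hook for a known real-data grouping).
    """
    if not list(k_range):
        raise DataError("empty k_range")
    labels = np.asarray(labels)
    X = complete_matrix(np.asarray(X, float), labels)

    def build(members: list[str], depth: int) -> SuperclusterNode:
        members = sorted(members)
        node = SuperclusterNode(tuple(members))
        if len(members) == 1:
            return node
        rows = np.isin(labels, members)
        Xn, yn = X[rows], labels[rows]
        groups = None
        if len(members) == 2:
            groups = [[members[0]], [members[1]]]
        else:
            ks = [k for k in k_range if 2 <= k <= len(members)]
            best = None
            for k in ks:
                gm = GaussianMixture(n_components=k, covariance_type="full",
                                     reg_covar=1e-6, n_init=10,
                                     random_state=(seed + 97 * depth + k) % (2**31))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gm.fit(Xn)
                bic = gm.bic(Xn)
                node.bic_trace[k] = float(bic)
                if best is None or bic < best[0]:
                    best = (bic, gm)
            if best is not None:
                gm = best[1]
                comp = gm.predict(Xn)
                assign: dict[str, int] = {}
                for m in members:
                    counts = np.bincount(comp[yn == m], minlength=gm.n_components)
                    top = np.flatnonzero(counts == counts.max())
                    if len(top) > 1:  # tie -> nearer component centroid
                        cen = X[labels == m].mean(axis=0)
                        top = [min(top, key=lambda c: np.sum((gm.means_[c] - cen) ** 2))]
                    assign[m] = int(top[0])
                part: dict[int, list[str]] = {}
                for m, c in assign.items():
                    part.setdefault(c, []).append(m)
                if len(part) >= 2:
                    groups = list(part.values())
        if groups is None:  # indivisible by the mixture -> centroid bisection
            groups = _bisect_by_centroids(X, labels, members)
        node.children = [build(g, depth + 1) for g in groups]
        return node

    all_labels = sorted(np.unique(labels))
    if pin:
        pin = tuple(sorted(pin))
        rest = [m for m in all_labels if m not in pin]
        root = SuperclusterNode(tuple(all_labels))
        pinned_child = build(list(pin), 1)
        rest_tree = build(rest, 1)
        # splice: root children = pinned subtree + the rest's partition
        others = rest_tree.children if rest_tree.children else [rest_tree]
        root.children = [pinned_child] + list(others)
        return root
    return build(all_labels, 0)
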