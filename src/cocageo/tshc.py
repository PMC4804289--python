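"""Tree-structured hierarchical classification (TSHC).

The supercluster label tree becomes a classifier tree: every nonterminal
node hosts one node classifier (DKOPLS-C by default, SVM-C optionally) over
its child partition, and every terminal node carries one region label.  A
query descends from the root, the candidate label set shrinking at each
step.  If the chosen branch's confidence falls below the threshold tau the
descent stops: when the labels still in play share one country the sample
is reported as "<Country>-RND" (region not determined), otherwise as
"unclassifiable".

A separate novelty screen compares a profile against every region's
diagonal moment envelope (squared Mahalanobis distance over the observed
variables vs a chi-square quantile) to surface samples unlike anything in
the reference collection — the mechanism that exposes previously unknown
growing areas.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .dataio import VARIABLES, DataError, Dataset, country_of
from .discretize import DiscretizationScheme, apply_scheme, fit_scheme
from .dkopls import NodeClassifier, fit_dkopls_node, fit_svm_node
from .explore import PreprocessModel, SuperclusterNode, preprocess_features
from .synthetic_data import RegionParams, lognormal_from_moments

MODEL_VERSION = "cocageo-tshc-1"

#: Per-variable SD floors for novelty distances — instrument repeatability
#: for the isotopes, the alkaloid LOD otherwise (keeps SD = 0 table rows
#: from producing infinite distances).
SD_FLOORS = {"tropacocaine": 0.01, "trimethoxycocaine": 0.01, "truxillines": 0.01,
             "d15N": 0.2, "d13C": 0.1, "d2H": 3.0, "d18O": 0.4}


@dataclass
class TreeNode:
    labels: tuple[str, ...]
    children: list["TreeNode"] = field(default_factory=list)
    classifier: NodeClassifier | None = None

    @property
    def is_terminal(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_terminal:
            return list(self.labels)
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PredictionResult:
    sample_id: str
    label: str                                  # region, "<Country>-RND", "unclassifiable"
    path: list[tuple[tuple[str, ...], float]]   # (chosen branch label set, confidence)
    novelty: dict | None = None
    model_version: str = MODEL_VERSION


@dataclass
class TSHCModel:
    root: TreeNode
    preprocess: PreprocessModel | None = None
    scheme: DiscretizationScheme | None = None
    tau: float = 0.5
    node_kind: str = "dkopls"
    discretize_root: bool = True
    region_means: dict[str, np.ndarray] = field(default_factory=dict)
    global_mean: np.ndarray | None = None
    config: dict = field(default_factory=dict)
    version: str = MODEL_VERSION

    def nonterminals(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            if not n.is_terminal:
                out.append(n)
                stack.extend(n.children)
        return out


def build_tree(supercluster_tree: SuperclusterNode, node_config: dict | None = None
               ) -> TSHCModel:
    """Untrained classifier skeleton mirroring the supercluster tree."""
    node_config = dict(node_config or {})

    def convert(sc: SuperclusterNode) -> TreeNode:
        node = TreeNode(tuple(sorted(sc.labels)))
        if not sc.is_leaf:
            if len(sc.children) < 2:
                raise DataError(f"nonterminal node {node.labels} lacks a partition")
            node.children = [convert(c) for c in sc.children]
        return node

    root = convert(supercluster_tree)
    leaves = sorted(root.leaves())
    if len(leaves) != len(set(leaves)):
        raise DataError("supercluster tree repeats a label")
    return TSHCModel(root=root,
                     node_kind=node_config.pop("kind", "dkopls"),
                     tau=node_config.pop("tau", 0.5),
                     discretize_root=node_config.pop("discretize_root", True),
                     config=node_config)


def fit_tree(model: TSHCModel, dataset: Dataset) -> TSHCModel:
    """Train preprocessing, root discretization and every node classifier.

    Each node sees only the samples belonging to its label set; the branch
    label of a sample is the child whose subtree contains its region.  The
    root classifier consumes CAIM-discretized integer codes (the missing
    bin absorbs incomplete profiles); deeper nodes consume continuous
    preprocessed values with per-region mean imputation.
    """
    leaves = set(model.root.leaves())
    present = set(dataset.regions.unique())
    missing = leaves - present
    if missing:
        raise DataError(f"dataset lacks samples for tree labels: {sorted(missing)}")

    model.preprocess, X = preprocess_features(dataset)
    regions = dataset.regions.to_numpy()

    # per-region means for sub-root imputation
    model.global_mean = np.nanmean(X, axis=0)
    for r in sorted(present):
        m = np.nanmean(X[regions == r], axis=0)
        model.region_means[r] = np.where(np.isfinite(m), m, model.global_mean)
    Xc = X.copy()
    for r in sorted(present):
        rows = regions == r
        block = Xc[rows]
        idx = np.isnan(block)
        block[idx] = np.broadcast_to(model.region_means[r], block.shape)[idx]
        Xc[rows] = block

    def branch_labels(node: TreeNode, rows: np.ndarray) -> np.ndarray:
        lab = np.empty(rows.sum(), dtype=object)
        sub = regions[rows]
        for j, child in enumerate(node.children):
            lab[np.isin(sub, child.labels)] = j
        return lab.astype(int)

    def fit_node(node: TreeNode, depth: int):
        if node.is_terminal:
            return
        rows = np.isin(regions, node.labels)
        y = branch_labels(node, rows)
        for j, child in enumerate(node.children):
            if (y == j).sum() < 3:
                raise DataError(
                    f"branch {child.labels} at node {node.labels} has "
                    f"{(y == j).sum()} samples (< 3)")
        if depth == 0 and model.discretize_root:
            frame = pd.DataFrame(X[rows], columns=list(VARIABLES))
            model.scheme = fit_scheme(frame, y)
            Xn = apply_scheme(frame, model.scheme)
        else:
            Xn = Xc[rows]
        if model.node_kind == "svm":
            node.classifier = fit_svm_node(Xn, y, seed=model.config.get("seed", 0),
                                           grid_search=model.config.get("grid_search", False))
        else:
            node.classifier = fit_dkopls_node(
                Xn, y,
                n_ortho=model.config.get("n_ortho", 1),
                n_pred=model.config.get("n_pred", None))
        for child in node.children:
            fit_node(child, depth + 1)

    fit_node(model.root, 0)
    return model


def fit(dataset: Dataset, supercluster_tree: SuperclusterNode,
        node_config: dict | None = None) -> TSHCModel:
    """Convenience: build the skeleton and train it."""
    return fit_tree(build_tree(supercluster_tree, node_config), dataset)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _rnd_label(labels: Sequence[str]) -> str:
    countries = {country_of(l) for l in labels}
    if len(countries) == 1:
        return f"{countries.pop()}-RND"
    return "unclassifiable"


def predict_dataset(model: TSHCModel, dataset: Dataset,
                    tau: float | None = None) -> list[PredictionResult]:
    """Descend every sample through the tree (batched per node)."""
    tau = model.tau if tau is None else tau
    X = model.preprocess.transform_values(dataset.values, dataset.censor_mask)
    if np.all(np.isnan(X), axis=1).any():
        raise DataError("sample with empty profile")
    frame = pd.DataFrame(X, columns=list(VARIABLES))
    Xroot = (apply_scheme(frame, model.scheme)
             if model.discretize_root and model.scheme is not None else None)
    # continuous representation: impute missing with the global training mean
    Xc = X.copy()
    idx = np.isnan(Xc)
    Xc[idx] = np.broadcast_to(model.global_mean, Xc.shape)[idx]

    ids = dataset.frame["sample_id"].tolist()
    results: list[PredictionResult | None] = [None] * len(dataset)

    def descend(node: TreeNode, rows: np.ndarray, depth: int,
                paths: dict[int, list]):
        if node.is_terminal:
            for i in rows:
                results[i] = PredictionResult(ids[i], node.labels[0], paths[i])
            return
        Xn = (Xroot if depth == 0 and Xroot is not None else Xc)[rows]
        branch, conf = node.classifier.predict(Xn)
        top = conf.max(axis=1)
        for j, child in enumerate(node.children):
            sel = branch == j
            confident = sel & (top >= tau)
            for local in np.flatnonzero(sel & ~confident):
                i = rows[local]
                p = paths[i] + [(node.labels, float(top[local]))]
                results[i] = PredictionResult(ids[i], _rnd_label(node.labels), p)
            sub = rows[confident]
            if len(sub):
                # candidate label set strictly shrinks at every step
                assert set(child.labels) < set(node.labels)
                new_paths = {i: paths[i] + [(child.labels, float(c))]
                             for i, c in zip(sub, top[confident])}
                paths.update(new_paths)
                descend(child, sub, depth + 1, paths)

    all_rows = np.arange(len(dataset))
    descend(model.root, all_rows, 0, {i: [] for i in all_rows})
    for r in results:  # path consistency: final region inside every chosen branch
        if r.label in model.root.leaves():
            assert all(r.label in step[0] for step in r.path)
    return results


def predict_sample(model: TSHCModel, record, tau: float | None = None
                   ) -> PredictionResult:
    """Classify one record (a Dataset row, Series or mapping)."""
    if isinstance(record, Dataset):
        ds = record
    else:
        if isinstance(record, pd.Series):
            record = record.to_dict()
        row = {c: record.get(c, np.nan) for c in
               ("sample_id", "region", "country", "lon", "lat", *VARIABLES,
                "censored", "source")}
        row.setdefault("sample_id", "query")
        row["sample_id"] = record.get("sample_id", "query")
        row["region"] = record.get("region", "unknown")
        row["country"] = record.get("country", "unknown")
        row["censored"] = record.get("censored", "")
        row["source"] = record.get("source", "seizure")
        ds = Dataset(pd.DataFrame([row]))
    return predict_dataset(model, ds, tau=tau)[0]


# ---------------------------------------------------------------------------
# novelty screen
# ---------------------------------------------------------------------------

def novelty_check(profile: Mapping[str, float],
                  params_list: Sequence[RegionParams],
                  quantile: float = 0.999) -> dict:
    """Compare a profile to every region's diagonal moment envelope.

    D^2 per region sums squared standardized deviations over the observed
    variables (alkaloids on the log scale, matching their log-normal
    family); the profile is flagged novel when the minimum D^2 exceeds the
    chi-square quantile at the observed dimensionality.  Per-region D^2
    values are returned so specific regions can be ruled out individually.
    """
    observed = [v for v in VARIABLES
                if v in profile and np.isfinite(profile[v])]
    if not observed:
        raise DataError("profile has no observed variables")
    if len(observed) < 2:
        warnings.warn("fewer than 2 observed variables; novelty screen has low power")
    d2: dict[str, float] = {}
    for p in params_list:
        total = 0.0
        for v in observed:
            m, s = p.means[v], max(p.sds[v], SD_FLOORS[v])
            x = float(profile[v])
            if p.families.get(v) == "lognormal" and x > 0:
                mu, sigma = lognormal_from_moments(m, max(s, SD_FLOORS[v]))
                total += ((np.log(x) - mu) / max(sigma, 1e-6)) ** 2
            else:
                total += ((x - m) / s) ** 2
        d2[p.region_name] = float(total)
    nearest = min(d2, key=d2.get)
    threshold = float(chi2.ppf(quantile, df=len(observed)))
    return {"novel": d2[nearest] > threshold, "nearest_region": nearest,
            "d2": d2, "min_d2": d2[nearest], "threshold": threshold,
            "df": len(observed)}


# ---------------------------------------------------------------------------
# serialization (single JSON document)
# ---------------------------------------------------------------------------

def _node_to_dict(node: TreeNode) -> dict:
    d: dict = {"labels": list(node.labels),
               "children": [_node_to_dict(c) for c in node.children]}
    clf = node.classifier
    if clf is not None:
        if clf.kind == "dkopls":
            d["classifier"] = {
                "kind": "dkopls", "classes": list(clf.classes),
                "kernel": clf.kernel_name, "sigma": clf.sigma,
                "n_ortho": clf.n_ortho, "n_pred": clf.n_pred,
                "X_ref": clf.X_ref.tolist(),
                "row_means": clf.centering.row_means.tolist(),
                "grand_mean": clf.centering.grand_mean,
                "Up": clf.Up.tolist(), "score_norms": clf.score_norms.tolist(),
                "ortho": [[t.tolist(), kt.tolist(), tkt] for t, kt, tkt in clf.ortho],
                "centroids": clf.centroids.tolist(),
                "score_precisions": clf.score_precisions.tolist(),
            }
        else:  # svm: store data + hyperparameters; refit deterministically on load
            d["classifier"] = {
                "kind": "svm", "classes": list(clf.classes), "sigma": clf.sigma,
                "X_ref": clf.X_ref.tolist(), "params": clf.svm_params,
            }
    return d


def _node_from_dict(d: dict) -> TreeNode:
    from .dkopls import KernelCenteringStats

    node = TreeNode(tuple(d["labels"]), [_node_from_dict(c) for c in d["children"]])
    c = d.get("classifier")
    if c is not None:
        if c["kind"] == "dkopls":
            node.classifier = NodeClassifier(
                kind="dkopls", classes=tuple(c["classes"]), kernel_name=c["kernel"],
                sigma=c["sigma"], X_ref=np.array(c["X_ref"], float),
                centering=KernelCenteringStats(np.array(c["row_means"], float),
                                               c["grand_mean"]),
                n_ortho=c["n_ortho"], n_pred=c["n_pred"],
                Up=np.array(c["Up"], float),
                score_norms=np.array(c["score_norms"], float),
                ortho=[(np.array(t, float), np.array(kt, float), tkt)
                       for t, kt, tkt in c["ortho"]],
                centroids=np.array(c["centroids"], float),
                score_precisions=np.array(c["score_precisions"], float))
        else:
            p = c["params"]
            node.classifier = fit_svm_node(
                np.array(c["X_ref"], float), np.array(p["y"]),
                C=p["C"], sigma=c["sigma"], seed=p["seed"])
            node.classifier.svm_params = p
    return node


def model_to_json(model: TSHCModel) -> str:
    doc = {
        "version": model.version, "tau": model.tau, "node_kind": model.node_kind,
        "discretize_root": model.discretize_root, "config": model.config,
        "tree": _node_to_dict(model.root),
        "preprocess": None if model.preprocess is None else {
            "transform": model.preprocess.transform,
            "center": model.preprocess.center.tolist(),
            "scale": model.preprocess.scale.tolist(),
            "fitted_on": model.preprocess.fitted_on,
        },
        "scheme": None if model.scheme is None else model.scheme.to_dict(),
        "region_means": {k: v.tolist() for k, v in model.region_means.items()},
        "global_mean": None if model.global_mean is None else model.global_mean.tolist(),
    }
    return json.dumps(doc, sort_keys=True)


def model_from_json(text: str) -> TSHCModel:
    doc = json.loads(text)
    model = TSHCModel(root=_node_from_dict(doc["tree"]), tau=doc["tau"],
                      node_kind=doc["node_kind"],
                      discretize_root=doc["discretize_root"], config=doc["config"],
                      version=doc["version"])
    if doc["preprocess"] is not None:
        model.preprocess = PreprocessModel(
            doc["preprocess"]["transform"],
            np.array(doc["preprocess"]["center"], float),
            np.array(doc["preprocess"]["scale"], float),
            doc["preprocess"]["fitted_on"])
    if doc["scheme"] is not None:
        model.scheme = DiscretizationScheme.from_dict(doc["scheme"])
    model.region_means = {k: np.array(v, float)
                          for k, v in doc["region_means"].items()}
    if doc["global_mean"] is not None:
        model.global_mean = np.array(doc["global_mean"], float)
    return model


def save_model(model: TSHCModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(model_to_json(model))


def load_model(path) -> TSHCModel:
    with open(path) as fh:
        return model_from_json(fh.read())
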