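"""Monte-Carlo stratified hold-out evaluation and summary metrics.

The predictive framework is judged by repeatedly splitting the labelled
collection into stratified train/hold-out parts, refitting the full
hierarchical classifier on the training part (the supercluster topology is
derived once per dataset), and scoring the held-out part end-to-end: a
prediction is correct only if the terminal region equals the generating
region (region-not-determined outcomes count as incorrect but are tabulated
separately).  Per-node branch decisions are additionally scored with the
Matthews correlation coefficient.
"""
from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import DataError, Dataset, country_of
from .explore import SuperclusterNode, mbc_superclusters, preprocess_features
from .tshc import TSHCModel, fit as fit_tshc, predict_dataset


def stratified_holdout(dataset: Dataset, fraction: float, seed: int = 0
                       ) -> tuple[Dataset, Dataset]:
    """Disjoint, exhaustive per-class split; ``fraction`` is held out.

    Rows are canonically ordered by sample_id before seeded shuffling so
    the split is invariant to input row order.  Classes with one sample
    stay in training with a warning.
    """
    if not 0.0 < fraction < 1.0:
        raise DataError(f"fraction must lie in (0, 1), got {fraction}")
    ds = dataset.sorted_by_id()
    regions = ds.regions.to_numpy()
    rng = np.random.default_rng(seed)
    test_idx = []
    for lab in sorted(np.unique(regions)):
        rows = np.flatnonzero(regions == lab)
        if len(rows) < 2:
            warnings.warn(f"class {lab!r} has one sample; kept in training")
            continue
        n_test = int(round(len(rows) * fraction))
        n_test = min(max(n_test, 1), len(rows) - 1)
        test_idx.extend(rng.permutation(rows)[:n_test].tolist())
    test_mask = np.zeros(len(ds), bool)
    test_mask[test_idx] = True
    return ds.subset(~test_mask), ds.subset(test_mask)


def confusion_matrix(true: Sequence, pred: Sequence,
                     labels: Sequence | None = None) -> pd.DataFrame:
    true, pred = np.asarray(true), np.asarray(pred)
    if labels is None:
        labels = sorted(set(true) | set(pred))
    table = pd.DataFrame(0, index=list(labels), columns=list(labels), dtype=int)
    for t, p in zip(true, pred):
        if p in table.columns:
            table.loc[t, p] += 1
        # predictions outside the label set (RND / unclassifiable) are
        # counted against accuracy but not inside the square table
    return table


def mcc_from_confusion(C) -> float:
    """Multiclass Matthews correlation coefficient (0 on zero denominator).

    For the binary 2x2 table this reduces to
    (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    C = np.asarray(C, float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise DataError("confusion table must be square")
    s = C.sum()
    c = np.trace(C)
    t = C.sum(axis=1)  # per-class true counts
    p = C.sum(axis=0)  # per-class predicted counts
    num = c * s - t @ p
    den = np.sqrt((s * s - p @ p) * (s * s - t @ t))
    return float(num / den) if den > 0 else 0.0


def node_metrics(confusion) -> dict:
    C = np.asarray(confusion, float)
    s = C.sum()
    acc = float(np.trace(C) / s) if s > 0 else 0.0
    return {"accuracy": acc, "misclassification": 1.0 - acc,
            "mcc": mcc_from_confusion(C)}


def _per_node_mccs(model: TSHCModel, test: Dataset) -> list[float]:
    """MCC of each nonterminal node's branch decision on applicable test rows."""
    regions = test.regions.to_numpy()
    mccs = []
    from .discretize import apply_scheme
    from .dataio import VARIABLES

    X = model.preprocess.transform_values(test.values, test.censor_mask)
    frame = pd.DataFrame(X, columns=list(VARIABLES))
    Xroot = (apply_scheme(frame, model.scheme)
             if model.discretize_root and model.scheme is not None else None)
    Xc = X.copy()
    idx = np.isnan(Xc)
    Xc[idx] = np.broadcast_to(model.global_mean, Xc.shape)[idx]

    def walk(node, depth):
        if node.is_terminal:
            return
        rows = np.flatnonzero(np.isin(regions, node.labels))
        if len(rows):
            true = np.empty(len(rows), int)
            for j, child in enumerate(node.children):
                true[np.isin(regions[rows], child.labels)] = j
            Xn = (Xroot if depth == 0 and Xroot is not None else Xc)[rows]
            pred, _ = node.classifier.predict(Xn)
            C = confusion_matrix(true, pred, labels=range(len(node.children)))
            mccs.append(mcc_from_confusion(C))
        for child in node.children:
            walk(child, depth + 1)

    walk(model.root, 0)
    return mccs


def evaluate_holdout(dataset: Dataset, tree: SuperclusterNode,
                     fraction: float = 0.25, n_iter: int = 20,
                     node_kind: str = "dkopls", seed: int = 0,
                     node_config: dict | None = None) -> pd.DataFrame:
    """Refit + score ``n_iter`` stratified hold-out splits.

    Returns one row per iteration with end-to-end region accuracy, country
    accuracy (region-not-determined predictions credit their country), the
    RND fraction and the macro-mean per-node MCC.
    """
    rows = []
    cfg = dict(node_config or {})
    cfg["kind"] = node_kind
    for it in range(n_iter):
        it_seed = (seed * 1009 + it) % (2**31)
        train, test = stratified_holdout(dataset, fraction, seed=it_seed)
        cfg["seed"] = it_seed
        model = fit_tshc(train, tree, node_config=dict(cfg))
        preds = predict_dataset(model, test)
        true_region = test.regions.to_numpy()
        pred_label = np.array([p.label for p in preds], dtype=object)
        region_ok = pred_label == true_region
        rnd = np.array([lbl.endswith("-RND") or lbl == "unclassifiable"
                        for lbl in pred_label])
        true_country = np.array([country_of(r) for r in true_region])
        pred_country = np.array([
            lbl.split("-RND")[0] if lbl.endswith("-RND")
            else ("unknown" if lbl == "unclassifiable" else country_of(lbl))
            for lbl in pred_label])
        mccs = _per_node_mccs(model, test)
        rows.append({"iteration": it, "seed": it_seed, "fraction": fraction,
                     "kind": node_kind,
                     "region_accuracy": float(region_ok.mean()),
                     "country_accuracy": float((pred_country == true_country).mean()),
                     "rnd_fraction": float(rnd.mean()),
                     "mean_node_mcc": float(np.mean(mccs)) if mccs else np.nan})
    return pd.DataFrame(rows)


def monte_carlo_sweep(dataset: Dataset, fractions: Sequence[float] | None = None,
                      n_iter: int = 100, node_kinds: Sequence[str] = ("dkopls",),
                      seed: int = 0, tree: SuperclusterNode | None = None,
                      node_config: dict | None = None) -> pd.DataFrame:
    """Hold-out fraction sweep: one summary row per (fraction, kind).

    Defaults mirror the published design: hold-out fractions 0.05..0.95 in
    0.05 steps with 100 iterations each (scale ``fractions``/``n_iter``
    down for quick runs).  The supercluster topology is derived once from
    the full dataset.
    """
    if fractions is None:
        fractions = np.round(np.arange(0.05, 0.96, 0.05), 2)
    if tree is None:
        _, X = preprocess_features(dataset)
        tree = mbc_superclusters(X, dataset.regions.to_numpy(), seed=seed)
    rows = []
    for kind in node_kinds:
        for frac in fractions:
            sub_seed = (seed * 7919 + int(round(frac * 100))) % (2**31)
            per_iter = evaluate_holdout(dataset, tree, fraction=float(frac),
                                        n_iter=n_iter, node_kind=kind,
                                        seed=sub_seed, node_config=node_config)
            rows.append({
                "fraction": float(frac), "kind": kind,
                "accuracy": float(per_iter["region_accuracy"].mean()),
                "misclassification": 1.0 - float(per_iter["region_accuracy"].mean()),
                "mcc": float(per_iter["mean_node_mcc"].mean()),
                "n_iter": n_iter, "seed": sub_seed})
    return pd.DataFrame(rows)


def summarize_shares(predictions: Sequence, cutoff: float = 0.01) -> pd.Series:
    """Percent of samples per final label; labels under ``cutoff`` pooled.

    ``predictions`` may be PredictionResult objects or plain labels.
    Percentages sum to 100 up to rounding; the published seizure summaries
    pool classifications under 1%.
    """
    labels = [getattr(p, "label", p) for p in predictions]
    if not labels:
        raise DataError("no predictions to summarize")
    counts = pd.Series(labels).value_counts()
    pct = 100.0 * counts / counts.sum()
    pooled = pct[pct < cutoff * 100.0]
    kept = pct[pct >= cutoff * 100.0]
    if len(pooled):
        kept = pd.concat([kept, pd.Series({"other": pooled.sum()})])
    return kept.sort_values(ascending=False)
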