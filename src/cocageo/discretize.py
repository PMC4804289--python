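"""Supervised CAIM discretization.

Class-Attribute Interdependence Maximization picks interval boundaries for
one continuous variable so that each interval is dominated by a single
class.  With intervals r = 1..n, M_r samples in interval r and max_r the
largest single-class count in r, the criterion is

    CAIM = (1/n) * sum_r max_r**2 / M_r .

Boundaries are chosen greedily from the midpoints of consecutive distinct
sorted values.  Applied at the root of the hierarchical classifier,
discretization doubles as the remediation step: missing values map to a
reserved bin and out-of-range values clamp into the edge intervals, which
moderates outlier influence.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class VariableScheme:
    cuts: tuple[float, ...]       # strictly increasing interior cut points
    caim: float
    n_bins: int = 0
    missing_bin: int = 0

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError("cut points must be strictly increasing")
        self.n_bins = len(self.cuts) + 1
        self.missing_bin = self.n_bins


@dataclass
class DiscretizationScheme:
    per_variable: dict[str, VariableScheme] = field(default_factory=dict)

    def to_dict(self) -> list:
        # a list of pairs: the variable order is part of the model (it fixes
        # the column order of the discretized code matrix)
        return [[v, {"cuts": list(s.cuts), "caim": s.caim}]
                for v, s in self.per_variable.items()]

    @classmethod
    def from_dict(cls, d) -> "DiscretizationScheme":
        items = d.items() if isinstance(d, dict) else d
        return cls({v: VariableScheme(tuple(s["cuts"]), s["caim"]) for v, s in items})


def caim_value(values: np.ndarray, labels: np.ndarray, cuts) -> float:
    """Evaluate the CAIM criterion for a given interior cut set."""
    codes = np.searchsorted(np.asarray(cuts, float), values, side="left")
    classes, y = np.unique(labels, return_inverse=True)
    n_int = len(cuts) + 1
    table = np.zeros((len(classes), n_int))
    np.add.at(table, (y, codes), 1.0)
    M = table.sum(axis=0)
    occupied = M > 0
    return float(np.sum(table.max(axis=0)[occupied] ** 2 / M[occupied]) / n_int)


def fit_caim(values, class_labels) -> tuple[tuple[float, ...], float]:
    """Greedy CAIM: returns (interior cut points, achieved CAIM value).

    Candidates are midpoints of consecutive distinct sorted values.  A cut
    is accepted while it strictly improves CAIM, or while the interval
    count is below the class count provided it does not worsen CAIM.
    Missing values are excluded from fitting.
    """
    values = np.asarray(values, float)
    labels = np.asarray(class_labels)
    finite = np.isfinite(values)
    values, labels = values[finite], labels[finite]
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    order = np.argsort(values, kind="mergesort")
    v, y = values[order], y[order]
    distinct, start = np.unique(v, return_index=True)
    if len(distinct) < 2:
        warnings.warn("all values identical; single bin")
        return (), caim_value(values, labels, ())
    # prefix class counts at distinct-value boundaries: P[i] = counts of v < distinct[i]
    c = len(classes)
    onehot = np.zeros((len(v), c))
    onehot[np.arange(len(v)), y] = 1.0
    csum = np.vstack([np.zeros(c), np.cumsum(onehot, axis=0)])
    bounds = np.append(start, len(v))          # len(distinct)+1 prefix indices
    P = csum[bounds]                            # (m+1, c) counts below each boundary
    mid = (distinct[:-1] + distinct[1:]) / 2.0  # candidate cuts, index 1..m-1 boundaries

    def contrib(lo: int, hi: int) -> float:
        cnt = P[hi] - P[lo]
        tot = cnt.sum()
        return float(cnt.max() ** 2 / tot) if tot > 0 else 0.0

    # chosen boundary positions (indices into `distinct` boundary space).
    # While the interval count is below the class count, the best cut is
    # accepted whenever it strictly raises the total interdependence sum
    # sum_r max_r^2/M_r (superadditive under splits, so it stalls only when
    # no boundary is informative); afterwards the mean CAIM must improve.
    chosen: list[int] = []
    current_sum = contrib(0, len(distinct))
    current = current_sum
    remaining = set(range(1, len(distinct)))
    while remaining:
        edges = [0] + sorted(chosen) + [len(distinct)]
        best_sum, best_pos = -np.inf, None
        base_sum = sum(contrib(a, b) for a, b in zip(edges, edges[1:]))
        for a, b in zip(edges, edges[1:]):
            inner = [p for p in remaining if a < p < b]
            if not inner:
                continue
            c_ab = contrib(a, b)
            for p in inner:
                s = base_sum - c_ab + contrib(a, p) + contrib(p, b)
                if s > best_sum:
                    best_sum, best_pos = s, p
        if best_pos is None:
            break
        k = len(chosen) + 1  # current interval count
        best_mean = best_sum / (k + 1)
        if best_mean > current + 1e-12 or (k < len(classes)
                                           and best_sum > current_sum + 1e-12):
            chosen.append(best_pos)
            remaining.discard(best_pos)
            current, current_sum = best_mean, best_sum
        else:
            break
    cuts = tuple(float(mid[p - 1]) for p in sorted(chosen))
    return cuts, caim_value(values, labels, cuts)


def apply_bins(values, scheme: VariableScheme) -> np.ndarray:
    """Map values to integer interval codes; NaN to the reserved missing bin.

    Interval membership is left-open/right-closed (value <= cut goes to the
    lower bin); values beyond the training range clamp into the first/last
    interval — the outlier-moderation effect.
    """
    values = np.asarray(values, float)
    codes = np.searchsorted(np.asarray(scheme.cuts, float), values, side="left")
    codes = np.asarray(codes, int)
    codes[~np.isfinite(values)] = scheme.missing_bin
    return codes


def fit_scheme(values_df, labels, variables=None) -> DiscretizationScheme:
    """Fit a per-variable CAIM scheme on a matrix of training values."""
    import pandas as pd

    if variables is None:
        variables = list(values_df.columns)
    scheme = DiscretizationScheme()
    for v in variables:
        col = values_df[v] if isinstance(values_df, pd.DataFrame) else values_df[:, v]
        cuts, caim = fit_caim(np.asarray(col, float), labels)
        scheme.per_variable[v] = VariableScheme(cuts, caim)
    return scheme


def apply_scheme(values_df, scheme: DiscretizationScheme) -> np.ndarray:
    """Integer code matrix (columns ordered as in the scheme)."""
    cols = []
    for v, s in scheme.per_variable.items():
        cols.append(apply_bins(np.asarray(values_df[v], float), s))
    return np.column_stack(cols).astype(float)
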