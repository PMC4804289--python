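"""Region-labelled synthetic chemical profiles.

The authentic leaf collection is not public, but its per-region first and
second moments (mean, SD) and sample counts are printed for all seven
measured variables.  This module emulates that collection: stable-isotope
ratios are drawn from normal distributions; trace alkaloids from log-normal
distributions whose first two moments are matched to the printed mean/SD
(several regions print SD > mean, so a normal would produce impossible
negative alkaloid contents).  Cross-variable dependence defaults to the
identity (only marginal SDs are printed) but an arbitrary positive
semi-definite correlation matrix can be supplied (Gaussian copula).

Realism artifacts — left-censoring at the limit of detection, missing cells
and inflated-outlier rows — are injected by :func:`inject_artifacts` with
per-cell masks recording ground truth.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import (ALKALOIDS, COUNTRIES, REGISTRY, VARIABLES, DataError,
                     Dataset, normalize_region)

#: Printed country totals of the authentic collection.
COUNTRY_TOTALS = {"Bolivia": 58, "Colombia": 361, "Peru": 153}

#: Default limit of detection for the alkaloids (% relative to cocaine) —
#: the smallest value printed in the reference table.
DEFAULT_LOD = 0.01


@dataclass
class RegionParams:
    """Generative parameters of one region (means/SDs per variable)."""

    region_name: str
    country: str
    n_authentic: int
    means: dict[str, float]
    sds: dict[str, float]
    families: dict[str, str] = field(default_factory=dict)
    lods: dict[str, float] = field(default_factory=dict)
    correlation: np.ndarray | None = None

    def __post_init__(self):
        self.region_name = normalize_region(self.region_name)
        if REGISTRY[self.region_name].country != self.country:
            raise DataError(
                f"{self.region_name} registered to {REGISTRY[self.region_name].country}, "
                f"not {self.country}")
        for v in VARIABLES:
            if v not in self.means or v not in self.sds:
                raise DataError(f"{self.region_name}: missing mean/sd for {v}")
            if self.sds[v] < 0:
                raise DataError(f"{self.region_name}: negative SD for {v}")
        for v in ALKALOIDS:
            if self.means[v] <= 0:
                raise DataError(f"{self.region_name}: non-positive alkaloid mean for {v}")
        if not self.families:
            self.families = {v: ("lognormal" if v in ALKALOIDS else "normal")
                             for v in VARIABLES}
        if not self.lods:
            self.lods = {v: DEFAULT_LOD for v in ALKALOIDS}
        if self.correlation is not None:
            C = np.asarray(self.correlation, float)
            if C.shape != (7, 7) or not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
                raise DataError("correlation must be symmetric 7x7 with unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise DataError("correlation matrix is not positive semi-definite")


@dataclass
class ArtifactConfig:
    """Realism artifacts applied on top of clean draws."""

    apply_censoring: bool = True
    missing_fraction: float = 0.0
    outlier_fraction: float = 0.0
    outlier_inflation: float = 3.0
    seed: int = 0

    def __post_init__(self):
        for name in ("missing_fraction", "outlier_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must lie in [0, 1], got {v}")
        if self.outlier_inflation <= 1.0:
            raise DataError("outlier_inflation must exceed 1")


def load_region_params(path_or_buffer=None) -> list[RegionParams]:
    """Load the per-region parameter table (bundled default if no path).

    The table has one row per region with mean/SD pairs for all seven
    variables plus the authentic sample count.  Exactly the 19 registry
    regions must be present.
    """
    from .dataio import default_params_path

    src = path_or_buffer if path_or_buffer is not None else default_params_path()
    table = pd.read_csv(src)
    params: list[RegionParams] = []
    seen = set()
    for _, row in table.iterrows():
        try:
            name = normalize_region(row["region"])
        except DataError as exc:
            raise DataError(f"row {row['region']!r}: {exc}") from exc
        if name in seen:
            raise DataError(f"duplicate region row {name!r}")
        seen.add(name)
        means = {v: float(row[f"{v}_mean"]) for v in VARIABLES}
        sds = {v: float(row[f"{v}_sd"]) for v in VARIABLES}
        n = int(row["n"])
        if n <= 0:
            raise DataError(f"row {name!r}: non-positive count {n}")
        params.append(RegionParams(name, str(row["country"]), n, means, sds))
    missing = set(REGISTRY) - seen
    if missing:
        raise DataError(f"missing region rows: {sorted(missing)}")
    return params


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given arithmetic mean and SD.

    mu = ln(m^2 / sqrt(m^2 + s^2)),  sigma^2 = ln(1 + s^2/m^2).
    """
    if mean <= 0:
        raise ValueError("log-normal mean must be positive")
    m2, s2 = mean * mean, sd * sd
    mu = np.log(m2 / np.sqrt(m2 + s2))
    sigma = np.sqrt(np.log1p(s2 / m2))
    return float(mu), float(sigma)


def sample_region(params: RegionParams, n: int, seed=None, rng=None) -> pd.DataFrame:
    """Draw ``n`` clean seven-variable profiles for one region.

    Isotopes ~ normal(mean, sd); alkaloids ~ moment-matched log-normal
    (strictly positive).  ``sd == 0`` collapses to the constant mean.  A
    supplied correlation matrix couples variables through a Gaussian copula.
    """
    if n <= 0:
        raise DataError(f"n must be positive, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if params.correlation is None:
        z = rng.standard_normal((n, 7))
    else:
        L = np.linalg.cholesky(params.correlation + 1e-12 * np.eye(7))
        z = rng.standard_normal((n, 7)) @ L.T
    out = {}
    for j, v in enumerate(VARIABLES):
        m, s = params.means[v], params.sds[v]
        if params.families[v] == "lognormal":
            if s == 0:
                out[v] = np.full(n, m)
            else:
                mu, sigma = lognormal_from_moments(m, s)
                out[v] = np.exp(mu + sigma * z[:, j])
        else:
            out[v] = m + s * z[:, j]
    return pd.DataFrame(out)


@dataclass
class ArtifactResult:
    table: pd.DataFrame
    censor_mask: pd.DataFrame
    missing_mask: pd.DataFrame
    outlier_rows: pd.Series  # boolean per row


def inject_artifacts(table: pd.DataFrame, cfg: ArtifactConfig,
                     lods: Mapping[str, float] | None = None,
                     rng=None) -> ArtifactResult:
    """Apply LOD censoring, missingness and outlier inflation to clean draws.

    Censored cells are stored at the LOD; missing cells become NaN; outlier
    rows have 1–3 randomly chosen variables perturbed by inflating their
    deviation from the column median.  Masks partition cells: missing takes
    precedence over censored.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    table = table.copy().reset_index(drop=True)
    n = len(table)
    cols = list(VARIABLES)
    censor = pd.DataFrame(False, index=table.index, columns=cols)
    missing = pd.DataFrame(False, index=table.index, columns=cols)
    outlier = pd.Series(False, index=table.index)

    if cfg.outlier_fraction > 0:
        rows = rng.random(n) < cfg.outlier_fraction
        outlier[:] = rows
        med = table[cols].median()
        for i in np.flatnonzero(rows):
            k = rng.integers(1, 4)
            for v in rng.choice(cols, size=k, replace=False):
                x = table.at[i, v]
                table.at[i, v] = med[v] + cfg.outlier_inflation * (x - med[v])
                if v in ALKALOIDS:  # keep alkaloids physical
                    table.at[i, v] = abs(table.at[i, v])

    if cfg.apply_censoring and lods:
        for v, lod in lods.items():
            below = table[v] <= lod
            censor[v] = below
            table.loc[below, v] = lod

    if cfg.missing_fraction > 0:
        blank = rng.random((n, len(cols))) < cfg.missing_fraction
        for j, v in enumerate(cols):
            table.loc[blank[:, j], v] = np.nan
            missing[v] = blank[:, j]
        censor &= ~missing
    return ArtifactResult(table, censor, missing, outlier)


def default_region_counts(params_list: Sequence[RegionParams],
                          multiplier: int = 1) -> dict[str, int]:
    """Per-region counts honoring the printed country totals.

    The per-region authentic counts sum below the printed country totals;
    the shortfall is allocated proportionally within each country by largest
    remainder, then everything is scaled by ``multiplier``.
    """
    counts: dict[str, int] = {}
    for country in COUNTRIES:
        members = [p for p in params_list if p.country == country]
        base = np.array([p.n_authentic for p in members], float)
        target = COUNTRY_TOTALS[country]
        exact = base * target / base.sum()
        alloc = np.floor(exact).astype(int)
        rem = exact - alloc
        for i in np.argsort(-rem)[: target - alloc.sum()]:
            alloc[i] += 1
        for p, a in zip(members, alloc):
            counts[p.region_name] = int(a) * multiplier
    return counts


def simulate_dataset(params_list: Sequence[RegionParams] | None = None,
                     per_region_n: Mapping[str, int] | int | None = None,
                     cfg: ArtifactConfig | None = None,
                     seed: int = 0) -> Dataset:
    """Generate the full labelled synthetic collection.

    ``per_region_n`` may be an explicit per-region count mapping or an
    integer multiplier on the default counts (default 1, total N = 572 with
    the 58/361/153 country split).  Deterministic under ``seed``; ground
    truth outlier flags are exposed as ``dataset.outlier_truth``.
    """
    if params_list is None:
        params_list = load_region_params()
    if not params_list:
        raise DataError("empty params list")
    if cfg is None:
        cfg = ArtifactConfig()
    if per_region_n is None:
        counts = default_region_counts(params_list)
    elif isinstance(per_region_n, int):
        counts = default_region_counts(params_list, multiplier=per_region_n)
    else:
        counts = dict(per_region_n)

    master = np.random.SeedSequence(seed)
    streams = master.spawn(len(params_list) + 1)
    rows = []
    outlier_flags = []
    for p, ss in zip(params_list, streams[:-1]):
        n = counts.get(p.region_name, 0)
        if n <= 0:
            continue
        rng = np.random.default_rng(ss)
        clean = sample_region(p, n, rng=rng)
        art = inject_artifacts(clean, cfg, lods=p.lods if cfg.apply_censoring else None,
                               rng=rng)
        box = REGISTRY[p.region_name].bbox
        lon = rng.uniform(box[0], box[1], n)
        lat = rng.uniform(box[2], box[3], n)
        slug = "".join(ch for ch in p.region_name.upper() if ch.isalnum())[:6]
        frame = pd.DataFrame({
            "sample_id": [f"SYN-{slug}-{i:04d}" for i in range(n)],
            "region": p.region_name,
            "country": p.country,
            "lon": lon,
            "lat": lat,
        })
        for v in VARIABLES:
            frame[v] = art.table[v].to_numpy()
        frame["censored"] = [
            ";".join(v for v in VARIABLES if art.censor_mask.at[i, v])
            for i in art.table.index
        ]
        frame["source"] = "synthetic"
        rows.append(frame)
        outlier_flags.append(art.outlier_rows.to_numpy())
    dataset = Dataset(pd.concat(rows, ignore_index=True))
    dataset.outlier_truth = pd.Series(np.concatenate(outlier_flags),
                                      index=dataset.frame.index)
    return dataset


def dataset_to_csv_bytes(dataset: Dataset) -> bytes:
    """Byte-exact CSV serialization (determinism checks)."""
    from .dataio import write_dataset

    buf = io.StringIO()
    write_dataset(dataset, buf)
    return buf.getvalue().encode()
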