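"""Tabular sample I/O, the 19-region registry, and dataset validation.

The collection under study spans 19 coca-growing regions across Bolivia,
Colombia and Peru.  Every sample carries a seven-variable chemical profile:
three trace alkaloids (tropacocaine, trimethoxycocaine, total truxillines,
each as % relative to cocaine) and four stable-isotope ratios (d15N, d13C,
d2H, d18O, in per mil).  Datasets are plain CSV with a fixed column order;
missing measurements are empty cells and left-censored measurements (below
the limit of detection) are stored at the LOD and listed by variable name in
the ``censored`` column.
"""
from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

ALKALOIDS = ("tropacocaine", "trimethoxycocaine", "truxillines")
ISOTOPES = ("d15N", "d13C", "d2H", "d18O")
VARIABLES = ALKALOIDS + ISOTOPES
COUNTRIES = ("Bolivia", "Colombia", "Peru")

#: Fixed dataset CSV column order.
SCHEMA = ("sample_id", "region", "country", "lon", "lat") + VARIABLES + ("censored", "source")

SOURCES = ("synthetic", "authentic", "seizure")


class DataError(ValueError):
    """Raised for malformed datasets or unknown labels."""


@dataclass(frozen=True)
class Region:
    """One coca-growing region: name, country, and a coarse lon/lat box.

    The bounding boxes are illustrative only (read qualitatively off a small
    country map); they exist so synthetic samples can carry plausible WGS84
    coordinates, not for any geodetic analysis.
    """

    name: str
    country: str
    bbox: tuple[float, float, float, float]  # lon_min, lon_max, lat_min, lat_max


_REGIONS = (
    Region("Chapare", "Bolivia", (-66.5, -64.5, -17.5, -16.3)),
    Region("Amazonas", "Colombia", (-72.0, -69.5, -4.2, -1.0)),
    Region("Antioquia", "Colombia", (-77.0, -74.5, 5.5, 8.0)),
    Region("Arauca", "Colombia", (-72.0, -69.8, 6.0, 7.1)),
    Region("Caquetá", "Colombia", (-76.0, -72.0, 0.0, 2.5)),
    Region("Cauca", "Colombia", (-77.5, -75.5, 1.5, 3.2)),
    Region("Chocó", "Colombia", (-77.5, -76.0, 4.0, 7.0)),
    Region("Guaviare", "Colombia", (-73.5, -70.0, 1.5, 3.0)),
    Region("Meta", "Colombia", (-74.5, -71.5, 2.0, 4.0)),
    Region("Nariño", "Colombia", (-78.8, -77.0, 0.5, 2.0)),
    Region("Norte de Santander", "Colombia", (-73.5, -72.0, 7.0, 9.0)),
    Region("Putumayo", "Colombia", (-77.0, -74.0, -0.5, 1.2)),
    Region("San Lucas", "Colombia", (-74.5, -73.5, 7.0, 8.5)),
    Region("Santander", "Colombia", (-74.0, -72.5, 5.5, 7.5)),
    Region("Valle de Cauca", "Colombia", (-77.2, -75.8, 3.0, 4.8)),
    Region("Vaupés", "Colombia", (-71.5, -69.5, 0.0, 1.5)),
    Region("Vichada", "Colombia", (-70.5, -67.5, 4.0, 6.0)),
    Region("Cusco", "Peru", (-73.5, -71.5, -14.0, -12.5)),
    Region("UHV", "Peru", (-76.5, -74.0, -9.5, -6.0)),
)

REGISTRY: dict[str, Region] = {r.name: r for r in _REGIONS}
REGION_NAMES: tuple[str, ...] = tuple(r.name for r in _REGIONS)

_ALIASES = {
    "uhv": "UHV",
    "ucayali/huallaga": "UHV",
    "ucayali huallaga": "UHV",
    "huallaga": "UHV",
    "cusco": "Cusco",
    "cusco/apurimac": "Cusco",
    "apurimac": "Cusco",
    "norte santander": "Norte de Santander",
}


def _fold(label: str) -> str:
    """Case/diacritics-insensitive key for a region label."""
    s = unicodedata.normalize("NFKD", label).encode("ascii", "ignore").decode()
    return " ".join(s.lower().split())


_FOLDED = {_fold(name): name for name in REGION_NAMES}
_FOLDED.update({k: v for k, v in _ALIASES.items()})


def normalize_region(label: str) -> str:
    """Return the canonical registry name for ``label``.

    ``"unknown"`` passes through (used for seizure samples of undetermined
    origin).  Unknown labels raise :class:`DataError` listing valid names.
    """
    if label is None or (isinstance(label, float) and np.isnan(label)):
        raise DataError("region label is missing")
    key = _fold(str(label))
    if key == "unknown":
        return "unknown"
    if key in _FOLDED:
        return _FOLDED[key]
    raise DataError(
        f"unknown region {label!r}; allowed: {', '.join(REGION_NAMES)} or 'unknown'"
    )


def country_of(region: str) -> str:
    if region == "unknown":
        return "unknown"
    return REGISTRY[normalize_region(region)].country


class Dataset:
    """A labelled collection of sample records.

    Wraps a :class:`pandas.DataFrame` in the fixed :data:`SCHEMA` column
    order.  Missing measurements are NaN; censored measurements hold the LOD
    value and are named in the ``censored`` column (semicolon-separated).
    """

    def __init__(self, frame: pd.DataFrame):
        missing_cols = [c for c in SCHEMA if c not in frame.columns]
        if missing_cols:
            raise DataError(f"dataset missing columns: {missing_cols}")
        frame = frame.loc[:, list(SCHEMA)].reset_index(drop=True)
        frame["sample_id"] = frame["sample_id"].astype(str)
        if frame["sample_id"].duplicated().any():
            dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise DataError(f"duplicate sample_id {dup!r}")
        frame["region"] = frame["region"].map(normalize_region)
        frame["country"] = [country_of(r) for r in frame["region"]]
        for v in VARIABLES + ("lon", "lat"):
            frame[v] = pd.to_numeric(frame[v], errors="raise").astype(float)
        frame["censored"] = frame["censored"].fillna("").astype(str)
        self.frame = frame

    # -- views ----------------------------------------------------------
    @property
    def values(self) -> pd.DataFrame:
        """The 7 measurement columns (NaN = missing)."""
        return self.frame.loc[:, list(VARIABLES)]

    @property
    def regions(self) -> pd.Series:
        return self.frame["region"]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def censor_mask(self) -> pd.DataFrame:
        mask = pd.DataFrame(False, index=self.frame.index, columns=list(VARIABLES))
        for i, listed in enumerate(self.frame["censored"]):
            if listed:
                for v in listed.split(";"):
                    if v not in VARIABLES:
                        raise DataError(f"censored column names unknown variable {v!r}")
                    mask.iloc[i, mask.columns.get_loc(v)] = True
        # a cell is at most one of observed / missing / censored
        return mask & ~self.missing_mask

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:  # loss-free round-trip contract
        if not isinstance(other, Dataset):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.frame, other.frame, check_exact=False,
                                          rtol=0, atol=1e-12)
        except AssertionError:
            return False
        return True

    def subset(self, rows) -> "Dataset":
        return Dataset(self.frame.loc[rows].reset_index(drop=True))

    def sorted_by_id(self) -> "Dataset":
        return Dataset(self.frame.sort_values("sample_id", kind="mergesort").reset_index(drop=True))


def write_dataset(dataset: Dataset, path) -> None:
    """Serialize to CSV; doubles keep >= 12 significant digits."""
    frame = dataset.frame.copy()
    for v in VARIABLES + ("lon", "lat"):
        frame[v] = frame[v].map(lambda x: "" if pd.isna(x) else repr(float(x)))
    frame.to_csv(path, index=False, lineterminator="\n")


def read_dataset(path) -> Dataset:
    frame = pd.read_csv(path, dtype={"sample_id": str, "censored": str}, keep_default_na=True)
    return Dataset(frame)


def validate_dataset(dataset: Dataset) -> list[dict]:
    """Report-only consistency check; returns one dict per violation."""
    report: list[dict] = []
    f = dataset.frame

    def add(i, kind, detail):
        report.append({"sample_id": f.at[i, "sample_id"], "kind": kind, "detail": detail})

    for i in f.index:
        lon, lat = f.at[i, "lon"], f.at[i, "lat"]
        if not pd.isna(lat) and not (-90 <= lat <= 90):
            add(i, "coordinate", f"lat {lat} outside [-90, 90]")
        if not pd.isna(lon) and not (-180 <= lon <= 180):
            add(i, "coordinate", f"lon {lon} outside [-180, 180]")
        if f.at[i, "source"] not in SOURCES:
            add(i, "source", f"unknown source {f.at[i, 'source']!r}")
    values = dataset.values
    for v in ALKALOIDS:
        bad = values.index[values[v] < 0]
        for i in bad:
            add(i, "negativity", f"{v} = {values.at[i, v]} < 0")
    # censored cells must carry a value (they are stored at the LOD)
    cm = dataset.censor_mask
    for v in VARIABLES:
        for i in f.index[cm[v] & values[v].isna()]:
            add(i, "mask", f"{v} censored but value missing")
    return report


def default_params_path() -> Path:
    """Path of the bundled per-region parameter table."""
    return Path(__file__).parent / "data" / "region_params.csv"
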