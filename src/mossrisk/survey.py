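"""Survey container types and delimited-text / GeoJSON I/O.

A survey is a sites × elements table of concentrations in mg/kg dry weight
with per-site metadata (coordinates, elevation, moss species). Values must
be strictly positive and finite; missing values are rejected rather than
imputed (surveys with gaps should be filtered before analysis).
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import DEFAULT_TRF, canonical_element

META_COLUMNS = ("site_id", "latitude", "longitude", "elevation", "species")


class SurveyValidationError(ValueError):
    """A survey table violates the container invariants."""


@dataclass(frozen=True)
class SiteMeta:
    """Metadata for one sampling site."""

    site_id: str
    latitude: float
    longitude: float
    elevation: float
    species: str

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise SurveyValidationError(
                f"site {self.site_id!r}: latitude {self.latitude} outside [-90, 90]"
            )
        if not -180.0 <= self.longitude <= 180.0:
            raise SurveyValidationError(
                f"site {self.site_id!r}: longitude {self.longitude} outside [-180, 180]"
            )


class ConcentrationMatrix:
    """Sites × elements concentration table (mg/kg dry weight).

    Parameters
    ----------
    sites
        Per-site metadata, in row order.
    elements
        Element symbols, one per column, unique.
    values
        Array of shape ``(len(sites), len(elements))``; strictly positive
        and finite.
    """

    def __init__(
        self,
        sites: Iterable[SiteMeta],
        elements: Iterable[str],
        values: np.ndarray,
    ) -> None:
        self.sites: list[SiteMeta] = list(sites)
        self.elements: list[str] = [str(e) for e in elements]
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape != (len(self.sites), len(self.elements)):
            raise SurveyValidationError(
                f"values shape {values.shape} does not match "
                f"{len(self.sites)} sites x {len(self.elements)} elements"
            )
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SurveyValidationError(f"duplicate site_id(s): {dupes}")
        if len(set(self.elements)) != len(self.elements):
            raise SurveyValidationError("duplicate element symbols")
        bad = ~np.isfinite(values) | (values <= 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise SurveyValidationError(
                f"non-positive or non-finite concentration at site "
                f"{ids[i]!r}, element {self.elements[j]!r}: {values[i, j]!r}"
            )
        self.values: np.ndarray = values

    # -- accessors ---------------------------------------------------------

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_values(self, element: str) -> np.ndarray:
        """Concentration vector of one element, in site order."""
        try:
            j = self.elements.index(element)
        except ValueError:
            raise KeyError(f"element {element!r} not in survey") from None
        return self.values[:, j].copy()

    def to_frame(self) -> pd.DataFrame:
        """Concentrations as a DataFrame indexed by site_id."""
        return pd.DataFrame(
            self.values, index=pd.Index(self.site_ids, name="site_id"),
            columns=list(self.elements),
        )

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.sites]).set_index(
            "site_id"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConcentrationMatrix):
            return NotImplemented
        return (
            self.sites == other.sites
            and self.elements == other.elements
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return (
            f"<ConcentrationMatrix {self.n_sites} sites x "
            f"{self.n_elements} elements>"
        )


class BackgroundTable(Mapping):
    """Per-element background concentration C_b (mg/kg), strictly positive."""

    def __init__(self, values: Mapping[str, float]) -> None:
        data = {str(k): float(v) for k, v in values.items()}
        for element, value in data.items():
            if not np.isfinite(value) or value <= 0:
                raise SurveyValidationError(
                    f"background for {element!r} must be positive and finite, got {value!r}"
                )
        self._data = data

    def __getitem__(self, key: str) -> float:
        return self._data[key]

    def __iter__(self):
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def __repr__(self) -> str:
        return f"BackgroundTable({self._data!r})"


class ToxicResponseTable(Mapping):
    """Per-element toxic-response factors (dimensionless, >= 1)."""

    def __init__(self, values: Mapping[str, float] | None = None) -> None:
        data = {str(k): float(v) for k, v in (values or DEFAULT_TRF).items()}
        for element, value in data.items():
            if not np.isfinite(value) or value < 1:
                raise SurveyValidationError(
                    f"TRF for {element!r} must be >= 1, got {value!r}"
                )
        self._data = data

    def __getitem__(self, key: str) -> float:
        return self._data[key]

    def __iter__(self):
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def __repr__(self) -> str:
        return f"ToxicResponseTable({self._data!r})"


@dataclass
class SiteIndexReport:
    """All pollution and risk indices of one site, with class labels."""

    site_id: str
    cf: dict[str, float]
    cf_class: dict[str, str]
    pli: float
    pli_class: str
    peri: dict[str, float]
    peri_class: dict[str, str]
    eri: float
    eri_class: str


# -- delimited-text I/O ----------------------------------------------------


def _sniff_sep(path: Path) -> str:
    header = path.read_text(encoding="utf-8").splitlines()[0]
    return "\t" if header.count("\t") > header.count(",") else ","


def read_survey(path: str | Path, sep: str | None = None) -> ConcentrationMatrix:
    """Read a survey from delimited text (comma default, tab accepted).

    Expects one header row with the metadata columns
    ``site_id, latitude, longitude, elevation, species`` followed by one
    column per element; element names are matched case-insensitively
    against the registry. Row order is preserved.
    """
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    frame = pd.read_csv(
        path, sep=sep, dtype={"site_id": str}, encoding="utf-8",
        float_precision="round_trip",
    )
    frame.columns = [str(c).strip() for c in frame.columns]
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise SurveyValidationError(f"missing metadata column(s): {missing}")
    element_cols = [c for c in frame.columns if c not in META_COLUMNS]
    if not element_cols:
        raise SurveyValidationError("no element columns found")
    elements = [canonical_element(c) for c in element_cols]

    sites = [
        SiteMeta(
            site_id=str(row.site_id),
            latitude=float(row.latitude),
            longitude=float(row.longitude),
            elevation=float(row.elevation),
            species=str(row.species),
        )
        for row in frame.itertuples(index=False)
    ]
    raw = frame[element_cols]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | ~np.isfinite(numeric) | (numeric <= 0)
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise SurveyValidationError(
            f"invalid concentration at site {sites[i].site_id!r}, element "
            f"{elements[j]!r}: {raw.iloc[i, j]!r} (must be a positive number)"
        )
    return ConcentrationMatrix(sites, elements, numeric.to_numpy(dtype=float))


def write_survey(matrix: ConcentrationMatrix, path: str | Path, sep: str = ",") -> None:
    """Write a survey as delimited text; ``read_survey`` round-trips it."""
    path = Path(path)
    meta = pd.DataFrame(
        [dataclasses.asdict(s) for s in matrix.sites], columns=list(META_COLUMNS)
    )
    conc = pd.DataFrame(matrix.values, columns=list(matrix.elements))
    out = pd.concat([meta, conc], axis=1)
    # repr-roundtrip float formatting keeps read(write(m)) bit-exact
    out.to_csv(path, sep=sep, index=False, float_format=None, encoding="utf-8")


# -- GeoJSON export --------------------------------------------------------


def write_geojson(
    reports: Iterable[SiteIndexReport],
    sites: Iterable[SiteMeta],
    path: str | Path,
) -> None:
    """Export per-site PLI/ERI and their classes as RFC 7946 GeoJSON Points.

    Coordinates are WGS84 [longitude, latitude]. Raises if a report's site
    has no metadata (hence no coordinates).
    """
    by_id = {s.site_id: s for s in sites}
    features = []
    for report in reports:
        site = by_id.get(report.site_id)
        if site is None:
            raise SurveyValidationError(
                f"site {report.site_id!r} in report has no coordinates"
            )
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [site.longitude, site.latitude],
                },
                "properties": {
                    "site_id": site.site_id,
                    "species": site.species,
                    "elevation": site.elevation,
                    "pli": report.pli,
                    "pli_class": report.pli_class,
                    "eri": report.eri,
                    "eri_class": report.eri_class,
                },
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(collection, indent=2), encoding="utf-8")
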