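"""Core data containers for site-by-element dust geochemistry.

The study system is settled indoor dust sampled at a set of sites (schools
S1...S24) and analysed for a panel of metal(loid) elements by XRF, reported
in mg/kg dry dust.  Everything downstream — contamination indices, exposure
doses, receptor modelling — consumes the same site × element concentration
grid, so it gets a single validated container here, together with the
reference tables the indices and the health-risk model need.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Element panel of the study, in reporting order.
STUDY_ELEMENTS: tuple[str, ...] = (
    "As", "Cu", "Zn", "Zr", "Sr", "Rb", "Pb", "Cr", "V", "Fe", "Sc",
)

PATHWAYS: tuple[str, ...] = ("ingestion", "inhalation", "dermal")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


class FormatError(ValueError):
    """Raised when a file does not match the expected CSV dialect."""


# ---------------------------------------------------------------------------
# concentration matrix
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationMatrix:
    """Site × element concentrations in mg/kg dry dust.

    Wraps a :class:`pandas.DataFrame` (index = site ids, columns = element
    symbols) and enforces: unique site ids, unique element symbols, no empty
    dimension, and all values finite and >= 0.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).astype(float)
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError("concentration matrix has an empty dimension")
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate site ids: {dupes}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate element symbols: {dupes}")
        bad = ~np.isfinite(df.to_numpy()) | (df.to_numpy() < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid concentration at site {df.index[i]!r}, "
                f"element {df.columns[j]!r}: {df.iloc[i, j]!r} "
                "(must be finite and >= 0)"
            )
        self.data = df

    # -- views ------------------------------------------------------------
    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def element_symbols(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __getitem__(self, element: str) -> pd.Series:
        return self.data[element]

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "ConcentrationMatrix":
        return read_concentration_csv(path)

    def to_csv(self, path: str | Path) -> None:
        write_concentration_csv(self, path)


def read_concentration_csv(path: str | Path) -> ConcentrationMatrix:
    """Read a ``site,El1,El2,...`` CSV into a validated matrix.

    Row/column order of the file is preserved.  Errors name the offending
    site and element.
    """
    path = Path(path)
    with open(path) as fh:
        raw_header = fh.readline().strip().split(",")
    if len(set(raw_header)) != len(raw_header):
        raise FormatError(f"{path}: duplicate column headers: {raw_header}")
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.ParserError as exc:  # malformed CSV
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a site column plus element columns")
    header = list(df.columns)
    site_col = header[0]
    elements = header[1:]
    sites = df[site_col].astype(str).tolist()
    grid = pd.DataFrame(index=pd.Index(sites, name="site"), columns=elements, dtype=float)
    for el in elements:
        for site, raw in zip(sites, df[el]):
            try:
                val = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-numeric concentration for site {site!r}, "
                    f"element {el!r}: {raw!r}"
                ) from None
            if not np.isfinite(val) or val < 0:
                raise ValidationError(
                    f"{path}: invalid concentration for site {site!r}, "
                    f"element {el!r}: {val} (must be finite and >= 0)"
                )
            grid.loc[site, el] = val
    return ConcentrationMatrix(grid)


def write_concentration_csv(matrix: ConcentrationMatrix, path: str | Path) -> None:
    """Write the ``site,El1,...`` dialect, 12 significant digits."""
    df = matrix.data.copy()
    df.index.name = "site"
    df.to_csv(path, float_format="%.12g")


# ---------------------------------------------------------------------------
# background table
# ---------------------------------------------------------------------------

@dataclass
class BackgroundTable:
    """Per-element geochemical background concentration, mg/kg.

    Backgrounds are the denominator of every contamination index; they must
    be finite and strictly positive.
    """

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = {str(k): float(v) for k, v in dict(self.values).items()}
        for el, v in vals.items():
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"background for {el!r} must be finite and > 0, got {v}"
                )
        self.values = vals

    def __getitem__(self, element: str) -> float:
        try:
            return self.values[element]
        except KeyError:
            raise KeyError(
                f"element {element!r} missing from background table; "
                f"available: {sorted(self.values)}"
            ) from None

    def __contains__(self, element: str) -> bool:
        return element in self.values

    @property
    def elements(self) -> list[str]:
        return list(self.values)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BackgroundTable":
        df = pd.read_csv(path)
        expected = ["element", "background_mg_kg"]
        if list(df.columns)[:2] != expected:
            raise FormatError(
                f"{path}: expected header {','.join(expected)}, got {list(df.columns)}"
            )
        return cls(dict(zip(df["element"].astype(str), df["background_mg_kg"])))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"element": list(self.values), "background_mg_kg": list(self.values.values())}
        ).to_csv(path, index=False)


#: Non-study default backgrounds: world-soil median-type compilation values,
#: mg/kg.  These are generic reference soils, NOT values measured or printed
#: by the study; override them via config for any site-specific work.
WORLD_SOIL_BACKGROUND: dict[str, float] = {
    "As": 6.83,
    "Cu": 38.9,
    "Zn": 70.0,
    "Zr": 267.0,
    "Sr": 175.0,
    "Rb": 68.0,
    "Pb": 27.0,
    "Cr": 59.5,
    "V": 129.0,
    "Fe": 35000.0,
    "Sc": 11.7,
}


def default_background() -> BackgroundTable:
    return BackgroundTable(dict(WORLD_SOIL_BACKGROUND))


# ---------------------------------------------------------------------------
# exposure parameters
# ---------------------------------------------------------------------------

@dataclass
class ExposureParameters:
    """Receptor constants of the EPA-style dust exposure model.

    Units follow the standard exposure-dose formulation: ingestion_rate in
    mg dust/day, skin_area in cm², skin_adherence in mg/cm², inhalation_rate
    in m³/day, particle_emission_factor in m³/kg, exposure_frequency in
    days/year, exposure_duration in years, body_weight in kg, averaging
    times in days, conversion_factor in kg/mg.  The carcinogenic averaging
    time and the volatilization factor are stored because the parameter
    table lists them, but no operation consumes them (the model is
    non-carcinogenic only).
    """

    receptor: str
    ingestion_rate: float
    skin_area: float
    skin_adherence: float
    dermal_absorption: float
    inhalation_rate: float
    particle_emission_factor: float
    exposure_frequency: float
    exposure_duration: float
    body_weight: float
    averaging_time_noncarcinogenic: float
    averaging_time_carcinogenic: float = 25550.0
    conversion_factor: float = 1e-6
    volatilization_factor: float = 32675.6  # stored, unused

    def __post_init__(self) -> None:
        if self.receptor not in ("child", "adult"):
            raise ValidationError(f"receptor must be 'child' or 'adult', got {self.receptor!r}")
        for f in fields(self):
            if f.name == "receptor":
                continue
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{self.receptor}: {f.name} must be > 0, got {v}")
        expected_at = self.exposure_duration * 365.0
        if abs(self.averaging_time_noncarcinogenic - expected_at) > 1e-9 * expected_at:
            raise ValidationError(
                f"{self.receptor}: non-carcinogenic averaging time "
                f"{self.averaging_time_noncarcinogenic} != exposure_duration x 365 "
                f"= {expected_at}"
            )

    @classmethod
    def child_default(cls) -> "ExposureParameters":
        return cls(
            receptor="child",
            ingestion_rate=200.0,
            skin_area=2800.0,
            skin_adherence=0.2,
            dermal_absorption=0.001,
            inhalation_rate=7.6,
            particle_emission_factor=1.4e9,
            exposure_frequency=285.0,
            exposure_duration=6.0,
            body_weight=15.0,
            averaging_time_noncarcinogenic=2190.0,
        )

    @classmethod
    def adult_default(cls) -> "ExposureParameters":
        return cls(
            receptor="adult",
            ingestion_rate=100.0,
            skin_area=5700.0,
            skin_adherence=0.7,
            dermal_absorption=0.001,
            inhalation_rate=20.0,
            particle_emission_factor=1.4e9,
            exposure_frequency=285.0,
            exposure_duration=30.0,
            body_weight=70.0,
            averaging_time_noncarcinogenic=10950.0,
        )


# ---------------------------------------------------------------------------
# reference doses
# ---------------------------------------------------------------------------

@dataclass
class RfDTable:
    """Element → per-pathway reference doses, mg/(kg·day).

    Entries are optional per pathway (missing pathways contribute nothing to
    the hazard index); Zr carries only an ingestion dose, and Sc and Rb have
    no entries at all in the default table.
    """

    values: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        table: dict[str, dict[str, float]] = {}
        for el, paths in dict(self.values).items():
            entry: dict[str, float] = {}
            for pw, v in dict(paths).items():
                if pw not in PATHWAYS:
                    raise ValidationError(f"unknown pathway {pw!r} for {el!r}; valid: {PATHWAYS}")
                v = float(v)
                if not np.isfinite(v) or v <= 0:
                    raise ValidationError(f"RfD for {el}/{pw} must be > 0, got {v}")
                entry[pw] = v
            table[str(el)] = entry
        self.values = table

    def get(self, element: str, pathway: str) -> float | None:
        return self.values.get(element, {}).get(pathway)

    def pathways_for(self, element: str) -> list[str]:
        return [p for p in PATHWAYS if self.get(element, p) is not None]

    @property
    def elements(self) -> list[str]:
        return [el for el, paths in self.values.items() if paths]


#: Default reference doses, mg/(kg·day).  "None" marks pathways with no
#: published dose; Sc and Rb have no usable doses and are skipped in HI.
DEFAULT_RFD: dict[str, dict[str, float]] = {
    "As": {"ingestion": 0.0003, "dermal": 0.000123, "inhalation": 0.000301},
    "Cu": {"ingestion": 0.04, "dermal": 0.0402, "inhalation": 0.012},
    "Zn": {"ingestion": 0.3, "dermal": 0.3, "inhalation": 0.35},
    "Zr": {"ingestion": 0.00008},
    "Sr": {"ingestion": 0.6, "dermal": 0.12, "inhalation": 0.6},
    "Pb": {"ingestion": 0.0035, "dermal": 0.00053, "inhalation": 0.0035},
    "Cr": {"ingestion": 1.5, "dermal": 0.006, "inhalation": 0.00003},
    "V": {"ingestion": 0.007, "dermal": 0.007, "inhalation": 0.00007},
    "Fe": {"ingestion": 0.7, "dermal": 0.7, "inhalation": 0.8},
}


def default_rfd() -> RfDTable:
    return RfDTable({el: dict(p) for el, p in DEFAULT_RFD.items()})


# ---------------------------------------------------------------------------
# PM time series
# ---------------------------------------------------------------------------

@dataclass
class PMSeries:
    """Paired PM2.5 / PM10 observations, µg/m³, at strictly increasing times."""

    timestamps: pd.DatetimeIndex
    pm25: np.ndarray
    pm10: np.ndarray

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        pm25 = np.asarray(self.pm25, dtype=float)
        pm10 = np.asarray(self.pm10, dtype=float)
        if not (len(ts) == len(pm25) == len(pm10)):
            raise ValidationError("timestamps, pm25 and pm10 must have equal length")
        if len(ts) == 0:
            raise ValidationError("empty PM series")
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValidationError("timestamps must be strictly increasing")
        if (pm25 < 0).any() or (pm10 < 0).any():
            raise ValidationError("PM values must be >= 0")
        self.timestamps, self.pm25, self.pm10 = ts, pm25, pm10

    def __len__(self) -> int:
        return len(self.timestamps)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PMSeries":
        df = pd.read_csv(path)
        expected = ["timestamp", "pm25", "pm10"]
        if list(df.columns)[:3] != expected:
            raise FormatError(f"{path}: expected header {','.join(expected)}")
        return cls(pd.to_datetime(df["timestamp"]), df["pm25"].to_numpy(), df["pm10"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"timestamp": self.timestamps, "pm25": self.pm25, "pm10": self.pm10}
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# small shared helpers
# ---------------------------------------------------------------------------

def per_capita_rate(count: float, population: float, per: float = 1000.0) -> float:
    """Ownership/incidence rate per ``per`` inhabitants."""
    if population <= 0:
        raise ValidationError("population must be > 0")
    return count / population * per


def geometric_mean(values: Iterable[float]) -> float:
    """Geometric mean computed in log space (robust on long products)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("geometric mean of an empty set is undefined")
    if (arr <= 0).any():
        raise ValidationError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))
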