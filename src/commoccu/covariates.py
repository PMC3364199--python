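"""Site covariates: distance indices, prey-biomass CPUE, NDVI measures,
transformation/standardization, and collinearity screening.

Continuous covariates are normalised with a fourth-root transformation
where right-skewed (patrol effort, hunting CPUE, riverine distance, the
prey-biomass indices) and then standardized to zero mean and unit sample
variance (n-1 denominator).  The model layer consumes only standardized
columns and verifies that contract.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry

from .detection import DeploymentRecord, DetectionRecord

__all__ = [
    "SiteCovariateTable",
    "distance_to_feature",
    "read_geojson_geometry",
    "camera_prey_biomass",
    "ndvi_seasonal",
    "ndvi_integrated",
    "transform_standardize",
    "collinearity_report",
]

#: Seconds below which consecutive photos of one species at one station are
#: treated as the same individual (strict "< 5 minutes" chain rule).
DEDUP_SECONDS = 300.0


@dataclass
class SiteCovariateTable:
    """Standardized site covariates plus coordinates.

    ``table`` holds one row per station with standardized covariate columns
    and raw companions suffixed ``_raw``; ``covariates`` lists the
    standardized column names usable by the model.
    """

    table: pd.DataFrame
    covariates: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in self.covariates if c not in self.table.columns]
        if missing:
            raise ValueError(f"covariate columns missing from table: {missing}")
        for c in ("x_km", "y_km"):
            if c not in self.table.columns:
                raise ValueError(f"coordinate column {c!r} required")
        bad = self.table[self.covariates].isna().any()
        if bad.any():
            raise ValueError(f"missing values in covariates: {list(bad[bad].index)}")
        for c in self.covariates:
            col = self.table[c].to_numpy(dtype=float)
            if abs(col.mean()) > 1e-8 or abs(col.std(ddof=1) - 1.0) > 1e-6:
                raise ValueError(
                    f"column {c!r} is not standardized (mean {col.mean():.3g}, "
                    f"sd {col.std(ddof=1):.3g}); run transform_standardize first"
                )

    @property
    def n_sites(self) -> int:
        return len(self.table)

    @property
    def coords(self) -> np.ndarray:
        return self.table[["x_km", "y_km"]].to_numpy(dtype=float)

    def matrix(self, names: Sequence[str]) -> np.ndarray:
        """J x C standardized design matrix for the named covariates."""
        unknown = [n for n in names if n not in self.covariates]
        if unknown:
            raise KeyError(f"unknown covariates: {unknown}")
        return self.table[list(names)].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.attrs["covariates"] = self.covariates
        out.to_csv(path, index=False)
        meta = Path(path).with_suffix(".meta.json")
        meta.write_text(json.dumps({"covariates": self.covariates}))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SiteCovariateTable":
        table = pd.read_csv(path)
        meta = Path(path).with_suffix(".meta.json")
        if meta.exists():
            covs = json.loads(meta.read_text())["covariates"]
        else:
            covs = [
                c
                for c in table.columns
                if c not in ("site", "x_km", "y_km") and not c.endswith("_raw")
            ]
        return cls(table, covs)


# -- distance indices -------------------------------------------------------

def read_geojson_geometry(path: str | Path) -> BaseGeometry:
    """Load the union of all geometries in a GeoJSON file."""
    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in doc["features"]]
    elif doc.get("type") == "Feature":
        geoms = [shape(doc["geometry"])]
    else:
        geoms = [shape(doc)]
    from shapely.ops import unary_union

    return unary_union(geoms)


def distance_to_feature(site: tuple[float, float], feature: BaseGeometry) -> float:
    """Minimum Euclidean distance (km) from a site to a feature.

    Polygons are reduced to their boundary, so a site inside a park
    polygon still gets its distance to the park edge.
    """
    if feature is None or feature.is_empty:
        raise ValueError("empty geometry")
    geom = feature
    if geom.geom_type in ("Polygon", "MultiPolygon"):
        geom = geom.boundary
    return float(geom.distance(Point(site)))


# -- camera-trap prey biomass ----------------------------------------------

def _dedup_count(times: list[_dt.datetime]) -> int:
    """Count independent detections under the <5-min chain rule."""
    times = sorted(times)
    count = 1
    for prev, cur in zip(times, times[1:]):
        if (cur - prev).total_seconds() >= DEDUP_SECONDS:
            count += 1
    return count


def camera_prey_biomass(
    prey_detections: Sequence[DetectionRecord],
    deployments: Sequence[DeploymentRecord],
    body_mass: Mapping[str, float],
    mass_cutoff: float | None = None,
) -> pd.Series:
    """Per-station prey biomass index, kg per 100 trap-days.

    Deduplicated detection counts per prey species are weighted by average
    adult body mass and standardized by station effort.  With
    ``mass_cutoff`` (e.g. 18 kg) only lighter species contribute,
    producing the small-prey index.
    """
    missing = sorted({r.species for r in prey_detections} - set(body_mass))
    if missing:
        raise ValueError(f"body mass missing for prey species: {missing}")
    by_station_species: dict[tuple[str, str], list[_dt.datetime]] = {}
    for rec in prey_detections:
        by_station_species.setdefault((rec.station_id, rec.species), []).append(rec.timestamp)

    index = pd.Series(0.0, index=[d.station_id for d in deployments], name="prey_biomass")
    effort = {d.station_id: d.trap_days for d in deployments}
    for (station, species), times in by_station_species.items():
        if station not in effort:
            raise ValueError(f"prey detection at unknown station {station!r}")
        mass = body_mass[species]
        if mass_cutoff is not None and mass >= mass_cutoff:
            continue
        index[station] += _dedup_count(times) * mass / effort[station] * 100.0
    return index


# -- NDVI -------------------------------------------------------------------

COMPOSITE_DAYS = 16


def ndvi_seasonal(
    window: tuple[_dt.date, _dt.date],
    composites: pd.DataFrame,
) -> float:
    """Mean of the 16-day composite NDVI values overlapping a sampling window.

    ``composites`` needs columns ``composite_start_date`` and ``ndvi``;
    each composite covers [start, start + 15 days].
    """
    start, end = window
    if end < start:
        raise ValueError("window end precedes start")
    cs = pd.to_datetime(composites["composite_start_date"]).dt.date
    ce = cs + _dt.timedelta(days=COMPOSITE_DAYS - 1)
    overlap = (cs <= end) & (ce >= start)
    if not overlap.any():
        raise ValueError(f"no NDVI composite overlaps window [{start}, {end}]")
    return float(composites.loc[overlap.to_numpy(), "ndvi"].mean())


def ndvi_integrated(
    study_period: tuple[_dt.date, _dt.date],
    composites: pd.DataFrame,
) -> float:
    """Sum of all 16-day composite NDVI values across the study period.

    Requires a gap-free composite series: consecutive composite start
    dates 16 days apart covering the whole period.
    """
    start, end = study_period
    df = composites.copy()
    df["_start"] = pd.to_datetime(df["composite_start_date"]).dt.date
    df = df.sort_values("_start")
    in_period = df[(df["_start"] <= end) & (df["_start"] >= start - _dt.timedelta(days=COMPOSITE_DAYS - 1))]
    if in_period.empty:
        raise ValueError("no NDVI composites in the study period")
    starts = list(in_period["_start"])
    gaps = [
        (a, b)
        for a, b in zip(starts, starts[1:])
        if (b - a).days != COMPOSITE_DAYS
    ]
    if gaps:
        raise ValueError(f"gaps in the NDVI composite series: {gaps}")
    return float(in_period["ndvi"].sum())


# -- transformation and screening ------------------------------------------

def transform_standardize(column: np.ndarray, fourth_root: bool = False) -> np.ndarray:
    """Optionally fourth-root transform, then z-score (sample sd, n-1).

    Fourth roots require nonnegative input; constant columns cannot be
    standardized and raise.
    """
    x = np.asarray(column, dtype=float)
    if fourth_root:
        if np.any(x < 0):
            raise ValueError("fourth-root transform needs nonnegative values")
        x = x**0.25
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("constant column cannot be standardized")
    return (x - x.mean()) / sd


def collinearity_report(table: SiteCovariateTable) -> dict[str, pd.DataFrame | pd.Series]:
    """Pearson/Spearman correlation matrices and variance inflation factors.

    VIF_c = 1 / (1 - R^2) from regressing covariate c on the others; a
    singular fit is reported as infinite with a warning.
    """
    names = table.covariates
    if table.n_sites < 3:
        raise ValueError("need at least 3 sites for collinearity screening")
    X = table.matrix(names)
    pearson = pd.DataFrame(np.corrcoef(X, rowvar=False), index=names, columns=names)
    sp, _ = _stats.spearmanr(X)
    if np.ndim(sp) == 0:  # scipy collapses the 2-column case to a scalar
        sp = np.array([[1.0, float(sp)], [float(sp), 1.0]])
    spearman = pd.DataFrame(sp, index=names, columns=names)

    vif = {}
    for i, name in enumerate(names):
        others = np.delete(X, i, axis=1)
        if others.shape[1] == 0:
            vif[name] = 1.0
            continue
        A = np.column_stack([np.ones(len(X)), others])
        coef, *_ = np.linalg.lstsq(A, X[:, i], rcond=None)
        resid = X[:, i] - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((X[:, i] - X[:, i].mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        if 1.0 - r2 < 1e-12:
            warnings.warn(f"covariate {name!r} is perfectly collinear; VIF infinite", stacklevel=2)
            vif[name] = float("inf")
        else:
            vif[name] = 1.0 / (1.0 - r2)
    return {"pearson": pearson, "spearman": spearman, "vif": pd.Series(vif, name="vif")}
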