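"""Camera-trap detection histories.

Builds the response data for the community occupancy model: per-species,
per-station counts of detection days ``y[i, j]`` out of ``k[j]`` active
trap-days, together with the binary sampling-design covariates that enter
the detection model (road, paired cameras, set team, season).

Daily occasions are collapsed to a binomial count per station.  All
detection covariates are station-level constants, so the per-day Bernoulli
likelihood factorises into Binomial(k_j, p_ij) exactly; the collapsed form
is the same likelihood at a fraction of the cost.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DeploymentRecord",
    "DetectionRecord",
    "DetectionDataset",
    "build_detection_dataset",
    "naive_occupancy",
    "assign_season",
    "read_deployments_csv",
    "read_detections_csv",
]

DESIGN_COLUMNS = ("on_road", "paired", "team", "season")

#: Months whose median sampling date classifies a deployment as dry season.
DRY_MONTHS = frozenset({10, 11, 12, 1, 2, 3, 4})


@dataclass(frozen=True)
class DeploymentRecord:
    """One camera-station deployment.

    Coordinates are planar kilometres; reprojection from geographic
    coordinates is the caller's job.  ``team`` is 1 for the primary field
    team; ``season`` is 1 for dry (derived from the median sampling date
    when not supplied).
    """

    station_id: str
    x: float
    y: float
    start_date: _dt.date
    end_date: _dt.date
    on_road: int = 0
    paired: int = 0
    team: int = 1
    season: int | None = None

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError(
                f"deployment {self.station_id!r}: end_date {self.end_date} "
                f"precedes start_date {self.start_date}"
            )
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"deployment {self.station_id!r}: non-finite coordinates")
        for name in ("on_road", "paired", "team"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"deployment {self.station_id!r}: {name} must be 0/1, got {v!r}")
        if self.season is not None and self.season not in (0, 1):
            raise ValueError(f"deployment {self.station_id!r}: season must be 0/1 or None")

    @property
    def trap_days(self) -> int:
        """Number of active trap-days; partial first/last days count as days."""
        return (self.end_date - self.start_date).days + 1


@dataclass(frozen=True)
class DetectionRecord:
    """A single photographic detection of a species at a station."""

    station_id: str
    species: str
    timestamp: _dt.datetime


def assign_season(deployment: DeploymentRecord) -> int:
    """Classify a deployment as dry (1) or wet (0).

    The rule uses the median calendar date of the deployment window:
    dry when it falls in October–April, wet when in May–September.
    """
    n = deployment.trap_days
    median_date = deployment.start_date + _dt.timedelta(days=(n - 1) // 2)
    if n % 2 == 0:
        # even window: midpoint of the two central days
        upper = deployment.start_date + _dt.timedelta(days=n // 2)
        median_ord = (median_date.toordinal() + upper.toordinal()) / 2.0
        median_date = _dt.date.fromordinal(int(round(median_ord)))
    return 1 if median_date.month in DRY_MONTHS else 0


@dataclass
class DetectionDataset:
    """Detection-day counts with effort and design covariates.

    ``y`` is an N x J nonnegative integer matrix of days-with-detection,
    ``k`` the J-vector of trap-days, ``design`` a J x 4 binary matrix in
    the column order road, paired, team, season.  Every species in
    ``species`` must be detected at least once (closure: the modeled
    community is the detected community).
    """

    species: list[str]
    sites: list[str]
    y: np.ndarray
    k: np.ndarray
    design: np.ndarray
    coords: np.ndarray  # J x 2 planar km
    #: enforce the closure assumption (every species detected somewhere) at
    #: construction; the model build always enforces it, but raw containers
    #: may hold all-zero rows (declared-but-undetected species, simulator
    #: output)
    require_closure: bool = False

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        self.k = np.asarray(self.k, dtype=int)
        self.design = np.asarray(self.design, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n, j = self.y.shape
        if n != len(self.species) or j != len(self.sites):
            raise ValueError("y shape does not match species/site lists")
        if self.k.shape != (j,) or self.design.shape != (j, 4) or self.coords.shape != (j, 2):
            raise ValueError("k/design/coords shapes inconsistent with site list")
        if np.any(self.k < 1):
            raise ValueError("every site needs effort k >= 1 trap-day")
        if np.any(self.y < 0) or np.any(self.y > self.k[None, :]):
            raise ValueError("detection counts must satisfy 0 <= y[i, j] <= k[j]")
        if self.require_closure and n and np.any(self.y.sum(axis=1) == 0):
            never = [s for s, row in zip(self.species, self.y) if row.sum() == 0]
            raise ValueError(
                f"species never detected: {never}; the community model covers "
                "detected species only"
            )

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    # -- tabular interchange ------------------------------------------------

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (wide counts frame, site-attribute frame)."""
        counts = pd.DataFrame(self.y, index=self.species, columns=self.sites)
        counts.index.name = "species"
        attrs = pd.DataFrame(
            {
                "site": self.sites,
                "x_km": self.coords[:, 0],
                "y_km": self.coords[:, 1],
                "k": self.k,
                **{c: self.design[:, i] for i, c in enumerate(DESIGN_COLUMNS)},
            }
        )
        return counts, attrs

    def to_csv(self, counts_path: str | Path, sites_path: str | Path) -> None:
        counts, attrs = self.to_frames()
        counts.to_csv(counts_path)
        attrs.to_csv(sites_path, index=False)

    @classmethod
    def from_csv(cls, counts_path: str | Path, sites_path: str | Path) -> "DetectionDataset":
        counts = pd.read_csv(counts_path, index_col=0)
        attrs = pd.read_csv(sites_path)
        attrs = attrs.set_index("site").loc[[str(c) for c in counts.columns]].reset_index()
        return cls(
            species=[str(s) for s in counts.index],
            sites=[str(c) for c in counts.columns],
            y=counts.to_numpy(),
            k=attrs["k"].to_numpy(),
            design=attrs[list(DESIGN_COLUMNS)].to_numpy(),
            coords=attrs[["x_km", "y_km"]].to_numpy(),
        )


def build_detection_dataset(
    detections: Sequence[DetectionRecord],
    deployments: Sequence[DeploymentRecord],
    species_list: Sequence[str] | None = None,
) -> DetectionDataset:
    """Aggregate raw detections into per-station detection-day counts.

    ``y[i, j]`` counts the distinct calendar days within station *j*'s
    deployment window on which species *i* was photographed; within-day
    repeats collapse to one detection day.  Detections at unknown stations
    or outside the deployment window raise, naming the offending record.

    When ``species_list`` is given it fixes the species axis and any
    detected species missing from it is an error (no augmentation for
    undetected community members).
    """
    by_station = {d.station_id: d for d in deployments}
    if len(by_station) != len(deployments):
        raise ValueError("duplicate station_id in deployments")
    sites = [d.station_id for d in deployments]
    site_index = {s: i for i, s in enumerate(sites)}

    detected = sorted({r.species for r in detections})
    if species_list is not None:
        unknown = sorted(set(detected) - set(species_list))
        if unknown:
            raise ValueError(
                f"detected species absent from the declared species list: {unknown}"
            )
        species = list(species_list)
    else:
        species = detected
    sp_index = {s: i for i, s in enumerate(species)}

    seen: set[tuple[int, int, _dt.date]] = set()
    for rec in detections:
        dep = by_station.get(rec.station_id)
        if dep is None:
            raise ValueError(f"detection at unknown station: {rec!r}")
        day = rec.timestamp.date()
        if not (dep.start_date <= day <= dep.end_date):
            raise ValueError(
                f"detection outside deployment window "
                f"[{dep.start_date}, {dep.end_date}]: {rec!r}"
            )
        seen.add((sp_index[rec.species], site_index[rec.station_id], day))

    y = np.zeros((len(species), len(sites)), dtype=int)
    for i, j, _day in seen:
        y[i, j] += 1

    k = np.array([d.trap_days for d in deployments], dtype=int)
    design = np.array(
        [
            [
                d.on_road,
                d.paired,
                d.team,
                d.season if d.season is not None else assign_season(d),
            ]
            for d in deployments
        ],
        dtype=int,
    )
    coords = np.array([[d.x, d.y] for d in deployments], dtype=float)
    return DetectionDataset(species, sites, y, k, design, coords)


def naive_occupancy(data: DetectionDataset) -> pd.Series:
    """Fraction of sites with at least one detection, per species.

    This is the uncorrected occurrence measure; it is biased low whenever
    per-occasion detection probability is below one.
    """
    frac = (data.y >= 1).mean(axis=1)
    return pd.Series(frac, index=data.species, name="naive_occupancy")


# -- raw CSV readers --------------------------------------------------------

def read_deployments_csv(path: str | Path) -> list[DeploymentRecord]:
    """Read deployments from CSV (station_id, x_km, y_km, start_date,
    end_date, on_road, paired, team[, season])."""
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        season = getattr(row, "season", None)
        if season is not None and pd.isna(season):
            season = None
        out.append(
            DeploymentRecord(
                station_id=str(row.station_id),
                x=float(row.x_km),
                y=float(row.y_km),
                start_date=pd.Timestamp(row.start_date).date(),
                end_date=pd.Timestamp(row.end_date).date(),
                on_road=int(row.on_road),
                paired=int(row.paired),
                team=int(row.team),
                season=None if season is None else int(season),
            )
        )
    return out


def read_detections_csv(path: str | Path) -> list[DetectionRecord]:
    """Read detections from CSV (station_id, species, timestamp ISO-8601)."""
    df = pd.read_csv(path)
    return [
        DetectionRecord(
            station_id=str(r.station_id),
            species=str(r.species),
            timestamp=pd.Timestamp(r.timestamp).to_pydatetime(),
        )
        for r in df.itertuples(index=False)
    ]
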