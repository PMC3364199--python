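import datetime as dt

import numpy as np
import pandas as pd
import pytest

from commoccu import (
    DeploymentRecord,
    DetectionDataset,
    DetectionRecord,
    SiteCovariateTable,
    build_detection_dataset,
)


@pytest.fixture
def small_deployments():
    """Five stations, 10-day windows, mixed design covariates."""
    start = dt.date(2007, 1, 1)
    return [
        DeploymentRecord(
            station_id=f"st{j}",
            x=float(j),
            y=0.5 * j,
            start_date=start,
            end_date=start + dt.timedelta(days=9),
            on_road=j % 2,
            paired=0,
            team=1,
        )
        for j in range(5)
    ]


@pytest.fixture
def small_detections():
    base = dt.datetime(2007, 1, 2, 8, 0)
    return [
        DetectionRecord("st0", "civet", base),
        DetectionRecord("st0", "civet", base + dt.timedelta(minutes=30)),  # same day
        DetectionRecord("st0", "genet", base + dt.timedelta(days=1)),
        DetectionRecord("st2", "civet", base + dt.timedelta(days=3)),
        DetectionRecord("st2", "civet", base + dt.timedelta(days=4)),
        DetectionRecord("st4", "genet", base + dt.timedelta(days=6)),
    ]


@pytest.fixture
def small_dataset(small_detections, small_deployments):
    return build_detection_dataset(small_detections, small_deployments)


@pytest.fixture
def tiny_dataset():
    """2 species x 4 sites with k <= 3, used by oracle comparisons."""
    return DetectionDataset(
        species=["A", "B"],
        sites=[f"s{j}" for j in range(4)],
        y=np.array([[1, 0, 2, 0], [0, 0, 1, 3]]),
        k=np.array([2, 1, 3, 3]),
        design=np.zeros((4, 4), dtype=int),
        coords=np.arange(8.0).reshape(4, 2),
    )


def make_cov_table(rng: np.random.Generator, n_sites: int, names: list[str]) -> SiteCovariateTable:
    """Random standardized covariate table for sampler tests."""
    cols = {
        "site": [f"S{j}" for j in range(n_sites)],
        "x_km": rng.uniform(0, 10, n_sites),
        "y_km": rng.uniform(0, 10, n_sites),
    }
    for name in names:
        raw = rng.normal(size=n_sites)
        cols[name] = (raw - raw.mean()) / raw.std(ddof=1)
    return SiteCovariateTable(pd.DataFrame(cols), list(names))
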