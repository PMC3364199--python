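import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import LineString, Point, Polygon

from commoccu import (
    DeploymentRecord,
    DetectionRecord,
    SiteCovariateTable,
    camera_prey_biomass,
    collinearity_report,
    distance_to_feature,
    ndvi_integrated,
    ndvi_seasonal,
    transform_standardize,
)


class TestDistanceToFeature:
    def test_site_on_boundary_is_zero(self):
        park = Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])
        assert distance_to_feature((10.0, 5.0), park) == pytest.approx(0.0)

    def test_interior_site_measures_to_edge(self):
        park = Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])
        assert distance_to_feature((5.0, 4.0), park) == pytest.approx(4.0)

    def test_pythagorean_point(self):
        assert distance_to_feature((3.0, 4.0), Point(0, 0)) == pytest.approx(5.0)

    def test_point_segment_projection(self):
        seg = LineString([(0, 0), (2, 0)])
        assert distance_to_feature((1.0, 1.0), seg) == pytest.approx(1.0)

    def test_empty_geometry_rejected(self):
        with pytest.raises(ValueError, match="empty geometry"):
            distance_to_feature((0.0, 0.0), LineString())

    def test_consistent_with_densified_vertex_search(self):
        rng = np.random.default_rng(11)
        line = LineString([(0, 0), (4, 1), (7, 5), (9, 2)])
        dense = np.concatenate(
            [
                np.linspace(a, b, 2000)[:, None, :]
                for a, b in zip(
                    np.array(line.coords)[:-1, None, :], np.array(line.coords)[1:, None, :]
                )
            ]
        ).reshape(-1, 2)
        for _ in range(10):
            site = rng.uniform(-2, 11, 2)
            exact = distance_to_feature(tuple(site), line)
            brute = np.min(np.hypot(*(dense - site).T))
            assert exact == pytest.approx(brute, abs=2e-3)


class TestCameraPreyBiomass:
    START = dt.date(2007, 1, 1)

    def _deploy(self, days=50):
        return [
            DeploymentRecord(
                "st0", 0.0, 0.0, self.START, self.START + dt.timedelta(days=days - 1)
            )
        ]

    def test_definitional_arithmetic(self):
        t0 = dt.datetime(2007, 1, 2, 6)
        det = [
            DetectionRecord("st0", "duiker", t0),
            DetectionRecord("st0", "duiker", t0 + dt.timedelta(hours=5)),
        ]
        out = camera_prey_biomass(det, self._deploy(50), {"duiker": 10.0})
        # 2 independent detections x 10 kg / 50 trap-days x 100
        assert out["st0"] == pytest.approx(40.0)

    def test_photos_under_five_minutes_collapse(self):
        t0 = dt.datetime(2007, 1, 2, 6)
        det = [
            DetectionRecord("st0", "duiker", t0),
            DetectionRecord("st0", "duiker", t0 + dt.timedelta(minutes=3)),
        ]
        out = camera_prey_biomass(det, self._deploy(50), {"duiker": 10.0})
        assert out["st0"] == pytest.approx(20.0)

    def test_chain_rule_collapses_consecutive_bursts(self):
        t0 = dt.datetime(2007, 1, 2, 6)
        times = [t0, t0 + dt.timedelta(minutes=3), t0 + dt.timedelta(minutes=6)]
        det = [DetectionRecord("st0", "duiker", t) for t in times]
        out = camera_prey_biomass(det, self._deploy(50), {"duiker": 10.0})
        # gaps of 3 min chain into a single individual
        assert out["st0"] == pytest.approx(20.0)

    def test_mass_cutoff_excludes_large_prey(self):
        det = [DetectionRecord("st0", "kob", dt.datetime(2007, 1, 2, 6))]
        out = camera_prey_biomass(det, self._deploy(), {"kob": 30.0}, mass_cutoff=18.0)
        assert out["st0"] == 0.0

    def test_missing_body_mass_names_species(self):
        det = [DetectionRecord("st0", "oribi", dt.datetime(2007, 1, 2, 6))]
        with pytest.raises(ValueError, match="oribi"):
            camera_prey_biomass(det, self._deploy(), {})


class TestNdvi:
    def _composites(self, values, start=dt.date(2007, 1, 1)):
        return pd.DataFrame(
            {
                "composite_start_date": [
                    start + dt.timedelta(days=16 * i) for i in range(len(values))
                ],
                "ndvi": values,
            }
        )

    def test_seasonal_single_and_mean(self):
        comps = self._composites([3000, 5000])
        one = ndvi_seasonal((dt.date(2007, 1, 2), dt.date(2007, 1, 10)), comps)
        assert one == 3000.0
        both = ndvi_seasonal((dt.date(2007, 1, 10), dt.date(2007, 1, 20)), comps)
        assert both == 4000.0
        three = ndvi_seasonal(
            (dt.date(2007, 1, 2), dt.date(2007, 2, 10)), self._composites([1, 2, 6])
        )
        assert three == pytest.approx(3.0)

    def test_seasonal_no_overlap_rejected(self):
        comps = self._composites([3000])
        with pytest.raises(ValueError, match="no NDVI composite"):
            ndvi_seasonal((dt.date(2008, 1, 1), dt.date(2008, 1, 5)), comps)

    def test_integrated_sum_and_order_invariance(self):
        comps = self._composites([100.0] * 10)
        total = ndvi_integrated((dt.date(2007, 1, 1), dt.date(2007, 6, 30)), comps)
        assert total == pytest.approx(1000.0)
        shuffled = comps.sample(frac=1, random_state=1)
        assert ndvi_integrated((dt.date(2007, 1, 1), dt.date(2007, 6, 30)), shuffled) == total

    def test_integrated_reports_gaps(self):
        comps = self._composites([1.0, 2.0]).drop(index=[1]).reset_index(drop=True)
        comps.loc[1] = [dt.date(2007, 3, 1), 3.0]
        with pytest.raises(ValueError, match="gaps"):
            ndvi_integrated((dt.date(2007, 1, 1), dt.date(2007, 3, 20)), comps)


class TestTransformStandardize:
    def test_fourth_root_applied_before_scaling(self):
        out = transform_standardize(np.array([16.0, 0.0, 1.0]), fourth_root=True)
        roots = np.array([2.0, 0.0, 1.0])
        np.testing.assert_allclose(out, (roots - roots.mean()) / roots.std(ddof=1))

    def test_two_point_column_under_sample_sd(self):
        # (-1, 1) has sample sd sqrt(2), so standardizes to +-1/sqrt(2)
        out = transform_standardize(np.array([-1.0, 1.0]))
        np.testing.assert_allclose(out, [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_output_moments(self):
        rng = np.random.default_rng(2)
        out = transform_standardize(rng.gamma(2, 3, 100), fourth_root=True)
        assert abs(out.mean()) < 1e-8
        assert out.std(ddof=1) == pytest.approx(1.0)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant column"):
            transform_standardize(np.full(5, 3.3))

    def test_negative_input_rejected_for_fourth_root(self):
        with pytest.raises(ValueError, match="nonnegative"):
            transform_standardize(np.array([-1.0, 2.0]), fourth_root=True)

    @given(st.lists(st.floats(0.1, 1e6), min_size=3, max_size=30, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_rank_preserving_on_positive_input(self, values):
        from hypothesis import assume

        # drop near-duplicates whose fourth roots collapse to equal floats
        x = np.unique(np.asarray(sorted(values)) ** 0.25) ** 4
        assume(len(x) >= 3)
        out = transform_standardize(x, fourth_root=True)
        assert (np.diff(out) > 0).all()  # strictly increasing input stays ordered


def _table(columns: dict[str, np.ndarray]) -> SiteCovariateTable:
    n = len(next(iter(columns.values())))
    df = pd.DataFrame(
        {"site": [f"S{j}" for j in range(n)], "x_km": np.zeros(n), "y_km": np.zeros(n)}
    )
    for name, col in columns.items():
        df[name] = transform_standardize(np.asarray(col, float))
    return SiteCovariateTable(df, list(columns))


class TestCollinearity:
    def test_orthogonal_columns(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        rep = collinearity_report(_table({"a": a, "b": b}))
        assert rep["pearson"].loc["a", "b"] == pytest.approx(0.0, abs=1e-12)
        assert rep["vif"]["a"] == pytest.approx(1.0)
        assert rep["vif"]["b"] == pytest.approx(1.0)

    def test_duplicated_column_infinite_vif(self):
        a = np.array([1.0, 2.0, 4.0, 7.0])
        with pytest.warns(UserWarning, match="perfectly collinear"):
            rep = collinearity_report(_table({"a": a, "b": a * 2.0}))
        assert np.isinf(rep["vif"]).all()

    def test_two_predictor_closed_form(self):
        # columns with exact Pearson r = 0.8: VIF = 1/(1-0.64) = 2.7778
        z1 = np.array([1.0, -1.0, 1.0, -1.0])
        z2 = np.array([1.0, 1.0, -1.0, -1.0])
        rep = collinearity_report(_table({"a": z1, "b": 0.8 * z1 + 0.6 * z2}))
        assert rep["pearson"].loc["a", "b"] == pytest.approx(0.8)
        assert rep["vif"]["a"] == pytest.approx(1.0 / (1.0 - 0.64))
        assert rep["vif"]["b"] == pytest.approx(1.0 / (1.0 - 0.64))


class TestSiteCovariateTable:
    def test_unstandardized_column_refused(self):
        df = pd.DataFrame(
            {"site": ["a", "b", "c"], "x_km": [0.0] * 3, "y_km": [0.0] * 3,
             "raw": [1.0, 5.0, 9.0]}
        )
        with pytest.raises(ValueError, match="not standardized"):
            SiteCovariateTable(df, ["raw"])

    def test_round_trip(self, tmp_path):
        tab = _table({"a": np.array([1.0, 2.0, 4.0, 9.0])})
        path = tmp_path / "cov.csv"
        tab.to_csv(path)
        back = SiteCovariateTable.from_csv(path)
        assert back.covariates == ["a"]
        np.testing.assert_allclose(back.matrix(["a"]), tab.matrix(["a"]))
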