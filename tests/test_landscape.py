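import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import LineString

from pigmove.landscape import (
    CLASS_CODES,
    EmptyExtractionError,
    Landscape,
    Raster,
    TargetAbsentError,
    distance_raster,
    extract,
    pearson_screen,
    read_geojson,
    standardize,
    write_geojson,
)


def _tiny_landscape(class_values, cell=30.0, streams=None):
    class_values = np.asarray(class_values)
    canopy = np.zeros_like(class_values, dtype=float)
    return Landscape(
        classes=Raster(class_values, 0.0, 0.0, cell),
        canopy=Raster(canopy, 0.0, 0.0, cell),
        streams=streams if streams is not None else LineString([(0, 0), (1, 1)]),
        primary_roads=LineString([(0, 0), (1, 0)]),
        secondary_roads=LineString([(0, 1), (1, 1)]),
    )


class TestDistanceRaster:
    def test_adjacency_distances(self):
        vals = np.full((5, 5), CLASS_CODES["upland_pine"])
        vals[2, 2] = CLASS_CODES["bottomland_hardwood"]
        scape = _tiny_landscape(vals)
        d = distance_raster(scape, "bottomland_hardwood")
        assert d.values[2, 2] == 0.0
        assert d.values[2, 3] == pytest.approx(30.0)  # 4-neighbour
        assert d.values[1, 1] == pytest.approx(30.0 * np.sqrt(2))  # diagonal
        assert d.values[2, 4] == pytest.approx(60.0)

    def test_absent_target_raises(self):
        scape = _tiny_landscape(np.full((3, 3), CLASS_CODES["upland_pine"]))
        with pytest.raises(TargetAbsentError, match="shrub_herb"):
            distance_raster(scape, "shrub_herb")

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            vals = np.where(
                rng.random((20, 20)) < 0.1,
                CLASS_CODES["shrub_herb"], CLASS_CODES["upland_pine"],
            )
            if not (vals == CLASS_CODES["shrub_herb"]).any():
                vals[3, 7] = CLASS_CODES["shrub_herb"]
            scape = _tiny_landscape(vals)
            d = distance_raster(scape, "shrub_herb")
            rs, cs = np.nonzero(vals == CLASS_CODES["shrub_herb"])
            for r in range(20):
                for c in range(20):
                    brute = np.min(np.hypot(rs - r, cs - c)) * 30.0
                    assert d.values[r, c] == pytest.approx(brute, abs=1e-9)

    def test_lipschitz_property(self, rng):
        vals = np.where(
            rng.random((30, 30)) < 0.05,
            CLASS_CODES["developed"], CLASS_CODES["other"],
        )
        vals[10, 10] = CLASS_CODES["developed"]
        d = distance_raster(_tiny_landscape(vals), "developed").values
        bound = 30.0 * np.sqrt(2) + 1e-9
        assert np.all(np.abs(np.diff(d, axis=0)) <= bound)
        assert np.all(np.abs(np.diff(d, axis=1)) <= bound)

    def test_polyline_distance_is_point_to_segment(self):
        stream = LineString([(0.0, 45.0), (150.0, 45.0)])
        scape = _tiny_landscape(
            np.full((5, 5), CLASS_CODES["upland_pine"]), streams=stream
        )
        d = distance_raster(scape, "stream")
        # row 3 cell centres sit at y = 45 -> on the line
        assert d.values[3, 0] == pytest.approx(0.0)
        # row 0 centres at y = 135 -> 90 m above
        assert d.values[0, 2] == pytest.approx(90.0)


class TestExtract:
    def test_cell_centre_lookup_is_exact(self):
        vals = np.arange(9.0).reshape(3, 3)
        rast = Raster(vals, 0.0, 0.0, 30.0)
        pts = pd.DataFrame({"x": [45.0], "y": [45.0]})  # centre of middle cell
        out = extract(pts, {"v": rast})
        assert out["v"].iloc[0] == vals[1, 1]

    def test_out_of_extent_dropped(self):
        rast = Raster(np.zeros((3, 3)), 0.0, 0.0, 30.0)
        pts = pd.DataFrame({"x": [10.0, -1.0], "y": [10.0, 10.0]})
        out = extract(pts, {"v": rast})
        assert len(out) == 1
        assert out.attrs["n_dropped"] == 1

    def test_all_outside_raises(self):
        rast = Raster(np.zeros((3, 3)), 0.0, 0.0, 30.0)
        with pytest.raises(EmptyExtractionError):
            extract(pd.DataFrame({"x": [-5.0], "y": [500.0]}), {"v": rast})

    def test_permutation_equivariance(self, rng):
        rast = Raster(rng.random((10, 10)), 0.0, 0.0, 30.0)
        pts = pd.DataFrame(rng.uniform(0, 300, (50, 2)), columns=["x", "y"])
        out = extract(pts, {"v": rast})
        perm = rng.permutation(50)
        out2 = extract(pts.iloc[perm].reset_index(drop=True), {"v": rast})
        np.testing.assert_allclose(
            out2["v"].to_numpy(), out["v"].to_numpy()[perm]
        )


class TestStandardize:
    def test_basic_example(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z, stats = standardize(table)
        np.testing.assert_allclose(z["a"], [-1.0, 0.0, 1.0])
        assert stats.mean["a"] == 2.0
        assert stats.sd["a"] == 1.0

    def test_zero_mean_unit_sd(self, rng):
        table = pd.DataFrame(rng.normal(5, 3, (200, 2)), columns=["a", "b"])
        z, _ = standardize(table)
        assert abs(z["a"].mean()) < 1e-12
        assert z["b"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_column_raises(self):
        with pytest.raises(ValueError, match="c"):
            standardize(pd.DataFrame({"c": [2.0, 2.0, 2.0]}))

    def test_round_trip(self, rng):
        table = pd.DataFrame(rng.normal(0, 10, (50, 3)), columns=list("abc"))
        z, stats = standardize(table)
        back = stats.inverse(z)
        np.testing.assert_allclose(back.to_numpy(), table.to_numpy(), atol=1e-10)


class TestPearsonScreen:
    def test_correlated_pair_drops_lower_priority(self, rng):
        n = 2000
        a = rng.normal(0, 1, n)
        b = 0.75 * a + np.sqrt(1 - 0.75**2) * rng.normal(0, 1, n)
        c = rng.normal(0, 1, n)
        table = pd.DataFrame({"d_primary_rd": a, "d_developed": b, "canopy": c})
        retained, corr = pearson_screen(
            table, priority=["d_primary_rd", "canopy", "d_developed"]
        )
        assert "d_primary_rd" in retained
        assert "d_developed" not in retained
        assert "canopy" in retained
        assert abs(corr.loc["d_primary_rd", "d_developed"]) > 0.6

    def test_orthogonal_columns_all_retained(self, rng):
        table = pd.DataFrame(rng.normal(0, 1, (500, 4)), columns=list("abcd"))
        retained, _ = pearson_screen(table, priority=list("abcd"))
        assert retained == list("abcd")

    def test_duplicate_column_dropped(self, rng):
        x = rng.normal(0, 1, 100)
        table = pd.DataFrame({"a": x, "b": x.copy()})
        retained, corr = pearson_screen(table, priority=["a", "b"])
        assert retained == ["a"]
        assert corr.loc["a", "b"] == pytest.approx(1.0)


class TestIO:
    def test_ascii_grid_round_trip(self, tmp_path, rng):
        rast = Raster(rng.normal(0, 1, (7, 5)), 123.0, -456.0, 30.0)
        path = tmp_path / "layer.asc"
        rast.write_ascii(path)
        back = Raster.read_ascii(path)
        assert back.same_grid(rast)
        np.testing.assert_allclose(back.values, rast.values, rtol=1e-6)

    def test_geojson_round_trip(self, tmp_path):
        geoms = [
            LineString([(0, 0), (100, 50), (200, 10)]),
            shapely.box(0, 0, 50, 50),
        ]
        path = tmp_path / "features.geojson"
        write_geojson(path, geoms, [{"kind": "stream"}, {"kind": "area"}])
        back = read_geojson(path)
        assert len(back) == 2
        assert back[0].equals(geoms[0])
        assert back[1].equals(geoms[1])
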