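"""Quality filtering, temporal grouping, cell handling and clustering."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Polygon

import clusternet as cn
from clusternet.exceptions import EmptyResultError, PreconditionError
from clusternet.preprocess import (ClusteringConfig, assign_cells,
                                   cells_from_label_mask, cluster, filter_cells,
                                   filter_localizations, temporal_group)


def _quality_table(rows: list[dict]) -> cn.LocalizationTable:
    defaults = {"x": 0.0, "y": 0.0, "photons": 5000.0, "psf_sigma": 100.0,
                "psf_pvalue": 0.005, "precision": 10.0}
    return cn.LocalizationTable(pd.DataFrame([{**defaults, **r} for r in rows]))


class TestQualityFilter:
    def test_each_threshold_removes_offender(self):
        table = _quality_table([
            {},  # clean
            {"precision": 30.0},  # > 25 nm
            {"photons": 40_000.0},  # > 30000
            {"psf_sigma": 60.0},  # < 75 nm
            {"psf_sigma": 250.0},  # > 200 nm
            {"psf_pvalue": 0.02},  # > 0.01
        ])
        out = filter_localizations(table)
        assert len(out) == 1

    def test_row_meeting_all_thresholds_retained(self):
        out = filter_localizations(_quality_table([{"psf_sigma": 100.0,
                                                    "precision": 10.0,
                                                    "psf_pvalue": 0.005,
                                                    "photons": 5000.0}]))
        assert len(out) == 1

    def test_absent_columns_skipped_with_warning(self, caplog):
        table = cn.LocalizationTable(pd.DataFrame({"x": [1.0], "y": [2.0]}))
        with caplog.at_level("WARNING"):
            out = filter_localizations(table)
        assert len(out) == 1
        assert "skipped" in caplog.text

    def test_everything_removed_raises(self):
        with pytest.raises(EmptyResultError):
            filter_localizations(_quality_table([{"precision": 99.0}]))

    def test_idempotent(self):
        table = _quality_table([{}, {"precision": 30.0}, {}])
        once = filter_localizations(table)
        twice = filter_localizations(once)
        pd.testing.assert_frame_equal(once.data, twice.data)


def _frames_table(points):  # [(x, y, frame)]
    df = pd.DataFrame(points, columns=["x", "y", "frame"])
    return cn.LocalizationTable(df)


class TestTemporalGrouping:
    def test_nearby_adjacent_frames_merge_to_midpoint(self):
        table = _frames_table([(0.0, 0.0, 1), (30.0, 0.0, 2)])
        out = temporal_group(table)
        assert len(out) == 1
        assert out.data.iloc[0]["x"] == pytest.approx(15.0)
        assert out.data.iloc[0]["frame"] == 1

    def test_gap_beyond_two_frames_not_linked(self):
        table = _frames_table([(0.0, 0.0, 1), (30.0, 0.0, 4)])
        assert len(temporal_group(table)) == 2

    def test_far_apart_not_linked(self):
        table = _frames_table([(0.0, 0.0, 1), (100.0, 0.0, 2)])
        assert len(temporal_group(table)) == 2

    def test_track_spanning_six_frames_removed(self):
        pts = [(float(i), 0.0, i) for i in range(1, 7)]  # frames 1..6
        assert len(temporal_group(_frames_table(pts))) == 0

    def test_track_spanning_five_frames_kept(self):
        pts = [(float(i), 0.0, i) for i in range(1, 6)]  # frames 1..5
        out = temporal_group(_frames_table(pts))
        assert len(out) == 1
        assert out.data.iloc[0]["x"] == pytest.approx(3.0)

    def test_missing_frame_column_is_precondition_error(self):
        table = cn.LocalizationTable(pd.DataFrame({"x": [0.0], "y": [0.0]}))
        with pytest.raises(PreconditionError):
            temporal_group(table)


class TestCells:
    def _fov(self):
        rng = np.random.default_rng(0)
        inside = rng.uniform(100, 900, size=(100, 2))
        outside = rng.uniform(2000, 3000, size=(10, 2))
        xy = np.vstack([inside, outside])
        return cn.LocalizationTable(pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]}),
                                    source_id="fov")

    def test_point_in_polygon_assignment(self):
        cell = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
        cells = assign_cells(self._fov(), [cell])
        assert len(cells) == 1
        assert len(cells[0]) == 100

    def test_membrane_band_labeling(self):
        cell = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
        membrane = LineString([(0, 0), (1000, 0)])  # bottom edge
        table = cn.LocalizationTable(pd.DataFrame(
            {"x": [500.0, 500.0], "y": [20.0, 600.0]}))
        (cell_table,) = assign_cells(table, [cell], [membrane], membrane_width=100.0)
        assert list(cell_table.data["region"]) == ["membrane", "interior"]

    def test_empty_cell_emitted_then_filtered(self):
        far_cell = Polygon([(5000, 5000), (6000, 5000), (6000, 6000), (5000, 6000)])
        cells = assign_cells(self._fov(), [far_cell])
        assert len(cells) == 1 and len(cells[0]) == 0
        assert filter_cells(cells) == []

    def test_label_mask_to_polygons(self):
        mask = np.zeros((40, 40), np.uint16)
        mask[5:20, 5:20] = 1
        mask[25:38, 22:38] = 2
        polys = cells_from_label_mask(mask, nm_per_pixel=100.0)
        assert len(polys) == 2
        # a localization at the centre of cell 1 (pixel (12, 12) -> nm)
        table = cn.LocalizationTable(pd.DataFrame(
            {"x": [1200.0, 3000.0], "y": [1200.0, 3100.0]}))
        cells = assign_cells(table, polys)
        assert len(cells[0]) == 1 and len(cells[1]) == 1

    def test_no_cells_is_precondition_error(self):
        with pytest.raises(PreconditionError):
            assign_cells(self._fov(), [])

    @pytest.mark.parametrize(
        "n_total, n_membrane, kept",
        [(499, 250, False), (600, 4, False), (600, 10, True)],
    )
    def test_cell_filters(self, n_total, n_membrane, kept):
        regions = ["membrane"] * n_membrane + ["interior"] * (n_total - n_membrane)
        df = pd.DataFrame({"x": np.zeros(n_total), "y": np.zeros(n_total),
                           "region": regions})
        cell = cn.LocalizationTable(df)
        assert (filter_cells([cell]) == [cell]) is kept


class TestClustering:
    def test_kmeans_on_grid_roi_yields_12_clusters(self):
        lib = cn.make_default_templates()
        params = cn.SimulationParams(locs_per_site_mean=30, background_rate=0,
                                     misfold_prob=0, rotation=False, seed=4)
        table = cn.sample_roi(lib.layout("grid"), params)
        cs = cluster(table, ClusteringConfig(method="kmeans", k=12, seed=0))
        assert len(cs.surviving_ids) == 12
        assert all(n >= 3 for n in cs.sizes().values())

    def test_small_cluster_filter_on_perfect_partition(self):
        # blobs of sizes 2, 3, 10 separated by 500 nm; DBSCAN recovers them
        rng = np.random.default_rng(1)
        blobs = [rng.normal((0, 0), 5, (2, 2)), rng.normal((500, 0), 5, (3, 2)),
                 rng.normal((0, 500), 5, (10, 2))]
        xy = np.vstack(blobs)
        table = cn.LocalizationTable(pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]}))
        cs = cluster(table, ClusteringConfig(method="dbscan", eps=50, min_pts=2))
        assert sorted(cs.sizes().values()) == [3, 10]

    def test_dbscan_drops_isolated_point_as_noise(self):
        rng = np.random.default_rng(2)
        blobs = [rng.normal((0, 0), 5, (8, 2)), rng.normal((500, 0), 5, (8, 2)),
                 rng.normal((0, 500), 5, (8, 2))]
        xy = np.vstack(blobs + [np.array([[250.0, 250.0]])])
        table = cn.LocalizationTable(pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]}))
        cs = cluster(table, ClusteringConfig(method="dbscan", eps=50, min_pts=3))
        assert len(cs.surviving_ids) == 3
        assert cs.assignment[-1] == -1

    def test_fewer_points_than_k_is_precondition_error(self):
        table = cn.LocalizationTable(
            pd.DataFrame({"x": np.arange(5.0), "y": np.arange(5.0)}))
        with pytest.raises(PreconditionError):
            cluster(table, ClusteringConfig(method="kmeans", k=12))

    def test_no_survivors_is_empty_result(self):
        xy = np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0], [1000.0, 1000.0]])
        table = cn.LocalizationTable(pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]}))
        with pytest.raises(EmptyResultError):
            cluster(table, ClusteringConfig(method="dbscan", eps=10, min_pts=2))

    def test_partition_invariant_to_row_order(self):
        lib = cn.make_default_templates()
        params = cn.SimulationParams(background_rate=0, misfold_prob=0,
                                     rotation=False, seed=6)
        table = cn.sample_roi(lib.layout("grid"), params)
        cs1 = cluster(table, ClusteringConfig(seed=0))
        perm = np.random.default_rng(0).permutation(len(table))
        shuffled = table.replace(table.data.iloc[perm])
        cs2 = cluster(shuffled, ClusteringConfig(seed=0))

        def partition(cs):
            xy = cs.parent.xy
            groups = set()
            for cid in cs.surviving_ids:
                pts = xy[cs.assignment == cid]
                groups.add(frozenset(map(tuple, np.round(pts, 6))))
            return groups

        assert partition(cs1) == partition(cs2)

    def test_min_cluster_size_below_3_rejected(self):
        with pytest.raises(PreconditionError):
            ClusteringConfig(min_cluster_size=2)
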