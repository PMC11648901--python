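"""Cell mapping, counting, 2D→3D calibration, detection evaluation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from histoatlas.cellatlas import (
    DEFAULT_CALIBRATION,
    CalibrationFactor,
    EvalConfig,
    apply_calibration,
    assign_and_count,
    compute_density_ratios,
    estimate_calibration,
    evaluate_detections,
    map_cells_to_reference,
)
from histoatlas.cellatlas import aggregate_counts
from histoatlas.ontology import default_ontology
from histoatlas.reconstruct import RigidTransform2D, SliceAlignment
from histoatlas.volume3d import LabelVolume


def _cells(n=50, seed=0, slices=(0, 1)):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "marker": rng.choice(["total", "neuron", "PV"], n),
            "slice_index": rng.choice(slices, n),
            "x_px": rng.uniform(5, 60, n),
            "y_px": rng.uniform(5, 60, n),
        }
    )


class TestMapCells:
    def test_identity_alignment(self):
        cells = _cells()
        als = [SliceAlignment(k, [RigidTransform2D()]) for k in (0, 1)]
        out = map_cells_to_reference(cells, als, {0: 0.0, 1: 100.0}, pixel_size_um=2.0)
        assert np.allclose(out.x_um, cells.x_px * 2.0)
        assert np.allclose(out.loc[out.slice_index == 1, "z_um"], 100.0)
        assert len(out) == len(cells)

    def test_known_rigid_matches_closed_form(self):
        cells = _cells(slices=(0,))
        tf = RigidTransform2D(11.0, (4.0, -2.0), "none", (32.0, 32.0))
        out = map_cells_to_reference(
            cells, [SliceAlignment(0, [tf])], {0: 0.0}, pixel_size_um=1.0
        )
        expect = tf.apply_points(cells[["x_px", "y_px"]].to_numpy())
        assert np.abs(out[["x_um", "y_um"]].to_numpy() - expect).max() <= 0.5

    def test_missing_alignment_rejected(self):
        with pytest.raises(KeyError, match="no alignment"):
            map_cells_to_reference(_cells(), [SliceAlignment(0, [RigidTransform2D()])],
                                   {0: 0.0, 1: 1.0})


def _two_region_volume():
    labels = np.zeros((4, 10, 10), np.int32)
    labels[:, :, :5] = 1
    labels[:, :, 5:] = 2
    return LabelVolume(labels, (10.0, 10.0, 10.0))


class TestAssignAndCount:
    def test_single_region_collects_all(self):
        vol = _two_region_volume()
        cells = pd.DataFrame(
            {"marker": ["total"] * 5, "x_um": [10.0] * 5, "y_um": [10.0] * 5,
             "z_um": [5.0] * 5}
        )
        summary = assign_and_count(cells, vol)
        row = summary[summary.region_id == 1]
        assert int(row.count2d_total.iloc[0]) == 5

    def test_conservation_per_marker(self):
        vol = _two_region_volume()
        rng = np.random.default_rng(1)
        cells = pd.DataFrame(
            {
                "marker": rng.choice(["total", "neuron", "PV"], 200),
                "x_um": rng.uniform(-20, 120, 200),
                "y_um": rng.uniform(-20, 120, 200),
                "z_um": rng.uniform(0, 40, 200),
            }
        )
        summary = assign_and_count(cells, vol)
        for marker in ("total", "neuron", "PV"):
            assert summary[f"count2d_{marker}"].sum() == (cells.marker == marker).sum()

    def test_border_cell_clamped_and_flagged(self):
        vol = _two_region_volume()
        cells = pd.DataFrame(
            {"marker": ["total"], "x_um": [100.0], "y_um": [50.0], "z_um": [5.0]}
        )
        summary = assign_and_count(cells, vol)
        assigned = summary.attrs["assigned_cells"]
        assert assigned.border_clamped.iloc[0]
        assert assigned.region_id.iloc[0] == 2


class TestCalibration:
    def test_constant_ratio(self):
        f = estimate_calibration([(20, 10), (40, 20), (80, 40)], "total")
        assert f.ratio == 2.0 and f.sem == 0.0

    def test_two_patch_sem(self):
        f = estimate_calibration([(15, 10), (25, 10)], "total")
        assert np.isclose(f.ratio, 2.0)
        assert np.isclose(f.sem, 0.5)  # sd([1.5, 2.5])/√2

    def test_reference_defaults(self):
        assert estimate_calibration([], "total").ratio == 1.730
        assert estimate_calibration([], "neuron").ratio == 1.864

    def test_zero_2d_patch_excluded(self):
        with pytest.warns(UserWarning, match="zero 2D count"):
            f = estimate_calibration([(20, 10), (5, 0)], "total")
        assert f.ratio == 2.0 and f.n_patches == 1

    def test_apply_identity_and_scaling(self):
        summary = pd.DataFrame(
            {"region_id": [1], "count2d_total": [100], "count2d_neuron": [50],
             "count2d_PV": [5]}
        )
        unit = {m: CalibrationFactor(m, 1.0) for m in ("total", "neuron", "PV")}
        out = apply_calibration(summary, unit)
        assert out.calibrated_total.iloc[0] == 100
        out = apply_calibration(summary, DEFAULT_CALIBRATION)
        assert np.isclose(out.calibrated_total.iloc[0], 173.0)
        assert out.calibrated_total_display.iloc[0] == 173

    def test_calibration_preserves_ordering(self):
        summary = pd.DataFrame(
            {"region_id": [1, 2, 3], "count2d_total": [10, 30, 20],
             "count2d_neuron": [1, 2, 3], "count2d_PV": [0, 0, 0]}
        )
        out = apply_calibration(summary, DEFAULT_CALIBRATION)
        assert list(out.calibrated_total.rank()) == list(out.count2d_total.rank())

    def test_missing_marker_rejected(self):
        summary = pd.DataFrame({"region_id": [1], "count2d_total": [1],
                                "count2d_neuron": [0], "count2d_PV": [0]})
        with pytest.raises(KeyError):
            apply_calibration(summary, {"total": CalibrationFactor("total", 1.0)})


class TestDensityRatios:
    def test_density_in_unit_cube(self):
        """150 calibrated neurons in a (100 µm)³ region: density 150."""
        labels = np.zeros((10, 10, 10), np.int32)
        labels[:, :, :] = 1
        vol = LabelVolume(labels, (10.0, 10.0, 10.0))
        summary = pd.DataFrame(
            {"region_id": [1], "calibrated_total": [300.0],
             "calibrated_neuron": [150.0], "calibrated_PV": [15.0]}
        )
        out = compute_density_ratios(summary, vol)
        assert np.isclose(out.density_neuron.iloc[0], 150.0)
        assert np.isclose(out.neuron_total_ratio.iloc[0], 0.5)
        assert np.isclose(out.pv_neuron_ratio.iloc[0], 0.1)

    def test_zero_counts_zero_ratios(self):
        vol = _two_region_volume()
        summary = pd.DataFrame(
            {"region_id": [1], "calibrated_total": [0.0],
             "calibrated_neuron": [0.0], "calibrated_PV": [0.0]}
        )
        out = compute_density_ratios(summary, vol)
        assert out.neuron_total_ratio.iloc[0] == 0.0

    def test_ratio_above_one_warns_unclipped(self):
        vol = _two_region_volume()
        summary = pd.DataFrame(
            {"region_id": [1], "calibrated_total": [10.0],
             "calibrated_neuron": [15.0], "calibrated_PV": [0.0]}
        )
        with pytest.warns(UserWarning, match="ratio above 1"):
            out = compute_density_ratios(summary, vol)
        assert out.neuron_total_ratio.iloc[0] == 1.5
        assert out.ratio_warning.iloc[0]

    def test_phantom_blob_volume_matches_analytic(self, blob_phantom):
        """Voxel count × spacing³ agrees with the analytic ellipsoid
        volume of a blob region within 2%."""
        rid, _, semi = blob_phantom.blobs[0]
        voxel = blob_phantom.label_volume.region_volumes()[rid]
        spacing = blob_phantom.label_volume.spacing[0]
        analytic = 4 / 3 * np.pi * np.prod(np.asarray(semi) * spacing)
        assert abs(voxel - analytic) <= 0.02 * analytic


class TestAggregateCounts:
    @pytest.mark.parametrize("level", [0, 1, 2, 3])
    def test_totals_conserved_up_the_tree(self, level):
        """Counts assigned to ontology leaves sum unchanged at any cut."""
        ont = default_ontology()
        rng = np.random.default_rng(0)
        leaves = ont.leaves()
        summary = pd.DataFrame(
            {
                "region_id": [n.id for n in leaves],
                "count2d_total": rng.integers(0, 50, len(leaves)),
                "count2d_neuron": rng.integers(0, 25, len(leaves)),
                "count2d_PV": rng.integers(0, 5, len(leaves)),
            }
        )
        agg = aggregate_counts(summary, ont, level)
        for col in ("count2d_total", "count2d_neuron", "count2d_PV"):
            assert agg[col].sum() == summary[col].sum()


def _disk_mask(shape, cx, cy, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def exhaustive_best_matching(pred, gt, thr):
    """Brute force: maximum number of one-to-one pairs with IoU >= thr."""
    ious = np.zeros((len(pred), len(gt)))
    for i, p in enumerate(pred):
        for j, g in enumerate(gt):
            inter = (p & g).sum()
            union = p.sum() + g.sum() - inter
            ious[i, j] = inter / union if union else 0.0
    allowed = [(i, j) for i in range(len(pred)) for j in range(len(gt))
               if ious[i, j] >= thr]
    best = 0
    for k in range(min(len(pred), len(gt)), 0, -1):
        for combo in itertools.combinations(allowed, k):
            ps = [c[0] for c in combo]
            gs = [c[1] for c in combo]
            if len(set(ps)) == k and len(set(gs)) == k:
                best = k
                break
        if best:
            break
    return best


class TestEvaluateDetections:
    def test_perfect_detection(self):
        masks = [_disk_mask((32, 32), 10, 10, 4), _disk_mask((32, 32), 22, 20, 5)]
        m = evaluate_detections(masks, masks)
        assert m["precision"] == m["recall"] == m["f1"] == 1.0

    def test_disjoint_sets(self):
        pred = [_disk_mask((32, 32), 8, 8, 3)]
        gt = [_disk_mask((32, 32), 24, 24, 3)]
        m = evaluate_detections(pred, gt)
        assert m["precision"] == m["recall"] == m["f1"] == 0.0

    def test_partial_match_counts(self):
        """3 predictions vs 4 ground truths with exactly 2 matched pairs:
        P = 2/3, R = 1/2, F1 = 4/7."""
        gt = [
            _disk_mask((48, 48), 8, 8, 4),
            _disk_mask((48, 48), 24, 8, 4),
            _disk_mask((48, 48), 8, 24, 4),
            _disk_mask((48, 48), 24, 24, 4),
        ]
        pred = [
            _disk_mask((48, 48), 8, 8, 4),       # matches gt 0
            _disk_mask((48, 48), 24, 9, 4),      # matches gt 1
            _disk_mask((48, 48), 40, 40, 4),     # matches nothing
        ]
        m = evaluate_detections(pred, gt)
        assert m["tp"] == 2 and m["fp"] == 1 and m["fn"] == 2
        assert np.isclose(m["precision"], 2 / 3)
        assert np.isclose(m["recall"], 1 / 2)
        assert np.isclose(m["f1"], 4 / 7)

    def test_matches_exhaustive_oracle_on_random_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_p, n_g = rng.integers(1, 7, 2)
            pred = [_disk_mask((64, 64), *rng.integers(6, 58, 2), rng.integers(3, 6))
                    for _ in range(n_p)]
            gt = [_disk_mask((64, 64), *rng.integers(6, 58, 2), rng.integers(3, 6))
                  for _ in range(n_g)]
            m = evaluate_detections(pred, gt)
            assert m["tp"] == exhaustive_best_matching(pred, gt, 0.5)

    def test_precision_recall_asymmetry(self):
        gt = [_disk_mask((32, 32), 10, 10, 4), _disk_mask((32, 32), 22, 22, 4)]
        pred = [_disk_mask((32, 32), 10, 10, 4)]
        a = evaluate_detections(pred, gt)
        b = evaluate_detections(gt, pred)
        assert a["precision"] == 1.0 and a["recall"] == 0.5
        assert b["precision"] == 0.5 and b["recall"] == 1.0
        assert np.isclose(a["f1"], b["f1"])  # F1 symmetric under swap

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            EvalConfig(iou_threshold=0.0)
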