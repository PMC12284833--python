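import json

import numpy as np
import pytest

from lungparc.grid import ImageGrid, LabelVolume
from lungparc.metrics import (
    dice,
    evaluate,
    hd95_assd,
    inclusion_rate,
    surface_distances,
)
from lungparc.tree import AirwayTree, CenterlineNode


def vol(arr, spacing=(1.0, 1.0, 1.0)):
    arr = np.asarray(arr, dtype=np.int32)
    return LabelVolume(ImageGrid(arr.shape, spacing), arr)


def oracle_surface_distances(a, b, spacing):
    """All-pairs oracle: explicit 6-neighbor surface check + exhaustive distances."""
    sp = np.asarray(spacing, dtype=float)

    def surface(mask):
        out = []
        for v in np.argwhere(mask):
            on_border = np.any(v == 0) or np.any(v == np.array(mask.shape) - 1)
            exposed = on_border
            for ax in range(3):
                for d in (-1, 1):
                    w = v.copy()
                    w[ax] += d
                    if 0 <= w[ax] < mask.shape[ax] and not mask[tuple(w)]:
                        exposed = True
            if exposed:
                out.append(v)
        return np.array(out) * sp

    sa, sb = surface(a), surface(b)
    d_ab = [min(np.linalg.norm(p - q) for q in sb) for p in sa]
    d_ba = [min(np.linalg.norm(p - q) for q in sa) for p in sb]
    return np.array(d_ab + d_ba)


# -- dice ---------------------------------------------------------------------


def test_dice_closed_forms():
    a = np.zeros((6, 6, 6), dtype=int)
    b = np.zeros((6, 6, 6), dtype=int)
    a[1:3, 1:3, 1] = 1  # 4 voxels
    b[2:4, 1:3, 1] = 1  # 4 voxels, overlap 2
    assert dice(vol(a), vol(b), 1) == pytest.approx(0.5)
    assert dice(vol(a), vol(a), 1) == 1.0
    b2 = np.zeros_like(b)
    b2[4:, 4:, 4:] = 1
    assert dice(vol(a), vol(b2), 1) == 0.0
    assert dice(vol(a), vol(b), 99) is None  # absent from both -> missing
    assert dice(vol(a), vol(b), 1) == dice(vol(b), vol(a), 1)  # symmetric


def test_dice_grid_mismatch_errors():
    a = vol(np.zeros((4, 4, 4), dtype=int))
    b = vol(np.zeros((4, 4, 4), dtype=int), spacing=(2, 2, 2))
    with pytest.raises(ValueError, match="grid mismatch"):
        dice(a, b, 1)


# -- surface distances --------------------------------------------------------


def test_identical_sets_zero_distance():
    m = np.zeros((8, 8, 8), dtype=bool)
    m[2:6, 2:6, 2:6] = True
    h, a = hd95_assd(m, m, (1, 1, 1))
    assert h == 0.0 and a == 0.0


def test_two_unit_voxels_three_mm_apart():
    a = np.zeros((8, 8, 8), dtype=bool)
    b = np.zeros((8, 8, 8), dtype=bool)
    a[2, 2, 2] = True
    b[5, 2, 2] = True
    h, s = hd95_assd(a, b, (1, 1, 1))
    assert h == pytest.approx(3.0)
    assert s == pytest.approx(3.0)


def test_empty_set_rejected():
    a = np.zeros((4, 4, 4), dtype=bool)
    b = np.zeros((4, 4, 4), dtype=bool)
    b[1, 1, 1] = True
    with pytest.raises(ValueError, match="non-empty"):
        surface_distances(a, b, (1, 1, 1))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_random_blobs_match_allpairs_oracle(seed):
    rng = np.random.default_rng(seed)
    a = np.zeros((15, 15, 15), dtype=bool)
    b = np.zeros((15, 15, 15), dtype=bool)
    ca, cb = rng.integers(4, 11, 3), rng.integers(4, 11, 3)
    grid = np.indices((15, 15, 15)).reshape(3, -1).T
    a.ravel()[np.linalg.norm(grid - ca, axis=1) <= rng.uniform(2, 4)] = True
    b.ravel()[np.linalg.norm(grid - cb, axis=1) <= rng.uniform(2, 4)] = True
    spacing = (1.0, 1.0, 2.0)
    got = np.sort(surface_distances(a, b, spacing))
    want = np.sort(oracle_surface_distances(a, b, spacing))
    np.testing.assert_allclose(got, want, atol=1e-9)
    h, s = hd95_assd(a, b, spacing)
    assert h == pytest.approx(np.percentile(want, 95))
    assert s == pytest.approx(want.mean())
    assert h <= want.max() + 1e-12
    assert s <= want.max() + 1e-12


# -- inclusion rate -----------------------------------------------------------


def line_tree(code, x0, x1, y=5, z=5):
    return AirwayTree(
        [
            CenterlineNode(1, (x0, y, z), segment_label=code),
            CenterlineNode(2, (x1, y, z), parent_id=1, segment_label=code),
        ]
    )


def test_inclusion_rate_extremes():
    pred = np.zeros((12, 12, 12), dtype=int)
    pred[:, :, :] = 4
    tree = line_tree(4, 2, 9)
    assert inclusion_rate(vol(pred), tree, 4) == 1.0
    pred[:] = 5  # wholly relabeled to a different segment
    assert inclusion_rate(vol(pred), tree, 4) == 0.0


def test_inclusion_rate_partial_fraction():
    # some of the segment's points fall in a neighboring segment after a
    # boundary shift; the rate equals a direct point-in-mask count
    pred = np.zeros((16, 12, 12), dtype=int)
    pred[:, :, :] = 7
    pred[11:14, :, :] = 8  # boundary pushed into segment 7's territory
    tree = line_tree(7, 2.0, 13.0)
    got = inclusion_rate(vol(pred), tree, 7)
    # oracle: enumerate the 0.5 mm samples and count voxel labels directly
    xs = np.arange(2.0, 13.0 + 1e-9, 0.5)
    labels = pred[np.rint(xs).astype(int), 5, 5]
    assert got == pytest.approx(np.mean(labels == 7))
    assert 0.0 < got < 1.0


def test_inclusion_rate_missing_cases():
    pred = np.zeros((8, 8, 8), dtype=int)
    tree = line_tree(3, 2, 5)
    assert inclusion_rate(vol(pred), tree, 9) is None  # segment not in tree
    assert inclusion_rate(vol(pred), tree, 3) is None  # no in-lung points


def test_inclusion_rate_all_points_denominator():
    pred = np.zeros((12, 12, 12), dtype=int)
    pred[0:6, :, :] = 4  # half the lung detected
    tree = line_tree(4, 2, 9)
    in_lung = inclusion_rate(vol(pred), tree, 4)
    all_pts = inclusion_rate(vol(pred), tree, 4, in_lung_denominator=False)
    assert in_lung == 1.0
    assert all_pts < 1.0


# -- evaluate -----------------------------------------------------------------


def test_evaluate_identity_on_phantom(bundle96, tax):
    rep = evaluate(bundle96.segments_gt, bundle96.segments_gt, bundle96.tree, tax)
    assert len(rep.per_segment) == 18
    assert rep.aggregate["dice"] == {"mean": 1.0, "sd": 0.0, "n": 18}
    assert rep.aggregate["hd95"]["mean"] == 0.0
    assert rep.aggregate["assd"]["mean"] == 0.0
    assert rep.aggregate["inclusion_rate"]["mean"] == 1.0


def test_aggregate_mean_and_sample_sd():
    per = {
        1: {"dice": 1.0, "hd95": None, "assd": None,
            "inclusion_rate": None, "inclusion_rate_all_points": None},
        2: {"dice": 0.5, "hd95": None, "assd": None,
            "inclusion_rate": None, "inclusion_rate_all_points": None},
    }
    from lungparc.metrics import MetricsReport

    rep = MetricsReport(per)
    rep.compute_aggregates()
    assert rep.aggregate["dice"]["mean"] == pytest.approx(0.75)
    assert rep.aggregate["dice"]["sd"] == pytest.approx(0.353553, abs=1e-6)
    assert rep.aggregate["hd95"]["mean"] is None


def test_report_serialization(tmp_path, bundle48, tax):
    rep = evaluate(bundle48.segments_gt, bundle48.segments_gt, bundle48.tree, tax)
    jpath = tmp_path / "m.json"
    cpath = tmp_path / "m.csv"
    rep.to_json(jpath)
    rep.to_csv(cpath)
    data = json.loads(jpath.read_text())
    assert set(data["per_segment"]) == {str(k) for k in range(1, 19)}
    df = rep.to_dataframe()
    assert len(df) == 18 and "dice" in df.columns


def test_metrics_invariant_to_other_segments(bundle48, tax):
    pred = LabelVolume(
        bundle48.segments_gt.grid, bundle48.segments_gt.labels.copy()
    )
    # relabeling segment 18 must not change segment 1's metrics
    moved = pred.labels.copy()
    moved[moved == 18] = 17
    moved_v = LabelVolume(pred.grid, moved)
    assert dice(pred, bundle48.segments_gt, 1) == dice(
        moved_v, bundle48.segments_gt, 1
    )
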