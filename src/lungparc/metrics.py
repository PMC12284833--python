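"""Segmentation evaluation: Dice, HD95, ASSD, and the inclusion rate.

Per-segment metrics between a predicted and a reference label volume:

* Dice = 2|A∩B| / (|A|+|B|) (0-1; conventionally printed ×100).
* Surface distances: surface voxels are set members with a 6-connected face
  neighbor outside the set (volume-border voxels count as surface); the
  symmetric multiset pools distances from each surface voxel of A to the
  nearest surface voxel of B and vice versa, in mm.  HD95 is its 95th
  percentile (linear interpolation between order statistics), ASSD its mean.
* Inclusion rate: the fraction of a segment's detected bronchial centerline
  points that land inside the predicted mask of that same segment.  The
  denominator counts labeled points falling on predicted-lung voxels
  (pred != 0), so gross lung under-segmentation is reported separately
  rather than silently diluting the rate; the all-points variant is also
  emitted in the JSON for transparency.

Aggregates are mean and sample (n-1) standard deviation across the segments
where a metric is defined.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import LabelVolume, check_same_grid
from .taxonomy import SegmentTaxonomy, build_taxonomy
from .tree import AirwayTree, labeled_point_sets

__all__ = [
    "MetricsReport",
    "dice",
    "surface_distances",
    "hd95_assd",
    "inclusion_rate",
    "evaluate",
]

logger = logging.getLogger(__name__)

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def dice(A: LabelVolume, B: LabelVolume, k: int) -> float | None:
    """Dice overlap of label k between two volumes; None when absent from both."""
    check_same_grid(A, B)
    a = A.labels == k
    b = B.labels == k
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return None
    return 2.0 * int((a & b).sum()) / (na + nb)


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Voxel indices of the 6-connected surface (border voxels included)."""
    interior = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    return np.argwhere(mask & ~interior)


def surface_distances(
    mask_a: np.ndarray, mask_b: np.ndarray, spacing
) -> np.ndarray:
    """Pooled symmetric surface-to-surface distances in mm.

    Both masks must be non-empty boolean arrays on the same lattice.
    """
    if not mask_a.any() or not mask_b.any():
        raise ValueError("surface distances require two non-empty masks")
    sp = np.asarray(spacing, dtype=float)
    sa = _surface_voxels(mask_a) * sp
    sb = _surface_voxels(mask_b) * sp
    d_ab, _ = cKDTree(sb).query(sa)
    d_ba, _ = cKDTree(sa).query(sb)
    return np.concatenate([d_ab, d_ba])


def hd95_assd(mask_a: np.ndarray, mask_b: np.ndarray, spacing) -> tuple[float, float]:
    """95th-percentile Hausdorff distance and ASSD (mm) of two masks."""
    d = surface_distances(mask_a, mask_b, spacing)
    return float(np.percentile(d, 95)), float(d.mean())


def inclusion_rate(
    pred: LabelVolume,
    tree: AirwayTree,
    k: int,
    *,
    in_lung_denominator: bool = True,
) -> float | None:
    """Fraction of segment k's centerline points covered by the correct segment.

    Points are the propagated labeled centerline of k, densely resampled as in
    the parcellation.  With ``in_lung_denominator`` (default) only points on
    predicted-lung voxels (pred != 0) count; returns None when the denominator
    is empty or the tree carries no points for k.
    """
    sets = labeled_point_sets(tree, 0.5 * min(pred.grid.spacing))
    if k not in sets:
        logger.warning("segment %d absent from tree; inclusion rate undefined", k)
        return None
    idx = pred.grid.round_to_voxel(sets[k])
    inside = pred.grid.contains_index(idx)
    idx = idx[inside]
    if len(idx) == 0:
        return None
    vals = pred.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
    if in_lung_denominator:
        vals = vals[vals != 0]
        if len(vals) == 0:
            return None
    return float(np.mean(vals == k))


@dataclass
class MetricsReport:
    """Per-segment and aggregate Dice / HD95 / ASSD / inclusion-rate values."""

    per_segment: dict[int, dict[str, float | None]]
    aggregate: dict[str, dict[str, float | None]] = field(default_factory=dict)
    schema_version: str = "1"

    _METRICS = ("dice", "hd95", "assd", "inclusion_rate", "inclusion_rate_all_points")

    def compute_aggregates(self) -> None:
        self.aggregate = {}
        for m in self._METRICS:
            vals = [
                row[m]
                for row in self.per_segment.values()
                if row.get(m) is not None and not math.isnan(row[m])
            ]
            if vals:
                mean = float(np.mean(vals))
                sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            else:
                mean = sd = None
            self.aggregate[m] = {"mean": mean, "sd": sd, "n": len(vals)}

    def to_json(self, path=None) -> str:
        payload = {
            "schema_version": self.schema_version,
            "per_segment": {str(k): v for k, v in self.per_segment.items()},
            "aggregate": self.aggregate,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"segment": k, **v} for k, v in sorted(self.per_segment.items())]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def evaluate(
    pred: LabelVolume,
    ref: LabelVolume,
    tree: AirwayTree | None = None,
    tax: SegmentTaxonomy | None = None,
) -> MetricsReport:
    """Per-segment metrics over all 18 codes plus mean/SD aggregates.

    Metrics are missing (None) where undefined: Dice when the segment is in
    neither mask, surface distances when it is absent from either, inclusion
    rate when no tree is given or the segment has no usable points.
    """
    check_same_grid(pred, ref)
    tax = tax or build_taxonomy()
    spacing = pred.grid.spacing
    per_segment: dict[int, dict[str, float | None]] = {}
    for k in tax.segments:
        a = pred.labels == k
        b = ref.labels == k
        row: dict[str, float | None] = {
            "dice": dice(pred, ref, k),
            "hd95": None,
            "assd": None,
            "inclusion_rate": None,
            "inclusion_rate_all_points": None,
        }
        if a.any() and b.any():
            row["hd95"], row["assd"] = hd95_assd(a, b, spacing)
        elif a.any() != b.any():
            logger.warning(
                "segment %d empty in one mask; surface distances undefined", k
            )
        if tree is not None:
            row["inclusion_rate"] = inclusion_rate(pred, tree, k)
            row["inclusion_rate_all_points"] = inclusion_rate(
                pred, tree, k, in_lung_denominator=False
            )
        per_segment[k] = row
    report = MetricsReport(per_segment)
    report.compute_aggregates()
    return report
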