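"""Synthetic thoracic phantoms.

Real bronchopulmonary-segment ground truth needs expert annotation; the
phantom generator replaces it with a fully synthetic but structurally
faithful scene so that every operation of the toolkit can be exercised and
cross-checked without patient data:

* two ellipsoidal "lungs" on a voxel grid;
* a rooted airway tree — trachea, left/right main bronchi, lobar bronchi
  (3 right, 2 left), then exactly 18 segmental bronchi distributed 3/2/5/4/4
  across the lobes, each with a further generation of sub-branches;
* lobe masks derived by nearest-lobar-subtree assignment inside each lung
  (the same argmin machinery as segment parcellation, one level up);
* one clicked annotation per segmental bronchus and the propagated labels;
* the centerline probability map; and
* a ground-truth segment mask computed by an **exhaustive scan** over
  (voxel, labeled point) pairs — deliberately not the production
  parcellation, so production vs. ground truth is a genuine cross-check.

Geometry is expressed in fractions of the grid's physical size and scales
down to small grids (32^3) for cheap randomized testing.  All randomness
comes from one seeded generator drawn in a fixed traversal order, so a spec
reproduces bit-identical bundles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import ImageGrid, LabelVolume, ScalarVolume
from .probmap import centerline_probability
from .parcellate import segment_feature_voxels, squared_index_distance
from .taxonomy import SegmentTaxonomy, build_taxonomy
from .tree import (
    AirwayTree,
    CenterlineNode,
    SegmentalAnnotation,
    branch_decomposition,
    propagate_labels,
    resample_edges,
)

__all__ = ["PhantomSpec", "PhantomBundle", "generate", "inject_gap", "exhaustive_parcellation"]

logger = logging.getLogger(__name__)


class _SeparationError(ValueError):
    """Segmental bronchi could not be spaced apart; caller may regenerate."""

# lobar bronchus targets in lung-local units of the semi-axes
# (lateral, anteroposterior, craniocaudal); lateral sign is resolved per side
_LOBE_TARGETS = {
    "RUL": (0.15, -0.05, 0.52),
    "RML": (0.10, 0.55, 0.02),
    "RLL": (0.05, -0.30, -0.55),
    "LUL": (0.15, 0.05, 0.52),
    "LLL": (0.05, -0.25, -0.55),
}
_RIGHT_LOBES = ("RUL", "RML", "RLL")
_LEFT_LOBES = ("LUL", "LLL")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic thoracic phantom.

    ``lung_semiaxes_mm`` and ``branch_length_mm`` (per-generation means:
    trachea, main, lobar, segmental, subsegmental) default to fractions of
    the grid's physical size so the same spec shape works from 32^3 to 96^3.
    ``gap_injection`` is a list of (branch index, gap mm) applied to the
    probability map for tracer gap-bridging tests.
    """

    seed: int = 0
    grid: ImageGrid = field(default_factory=lambda: ImageGrid((96, 96, 96)))
    lung_semiaxes_mm: tuple[float, float, float] | None = None
    branch_angle_deg: tuple[float, float] = (35.0, 8.0)
    branch_length_mm: tuple[float, float, float, float, float] | None = None
    length_jitter: float = 0.12
    sigma_mm: float = 1.0
    subsegmental_children: int = 2
    gap_injection: tuple[tuple[int, float], ...] = ()

    def physical_size(self) -> np.ndarray:
        return (np.asarray(self.grid.dims) - 1) * np.asarray(self.grid.spacing)

    def resolved_semiaxes(self) -> np.ndarray:
        if self.lung_semiaxes_mm is not None:
            return np.asarray(self.lung_semiaxes_mm, dtype=float)
        return self.physical_size() * np.array([0.19, 0.27, 0.38])

    def resolved_lengths(self) -> np.ndarray:
        if self.branch_length_mm is not None:
            return np.asarray(self.branch_length_mm, dtype=float)
        scale = float(self.physical_size().min()) / 95.0
        return np.array([18.0, 13.0, 13.0, 12.0, 9.0]) * scale


@dataclass
class PhantomBundle:
    """Everything a phantom provides: masks, labeled tree, prob map, ground truth."""

    spec: PhantomSpec
    lungs: LabelVolume
    lobes: LabelVolume
    tree: AirwayTree
    annotations: SegmentalAnnotation
    prob: ScalarVolume
    segments_gt: LabelVolume


class _TreeBuilder:
    def __init__(self) -> None:
        self.nodes: list[CenterlineNode] = []
        self.next_id = 1

    def add_chain(self, parent: int, positions: np.ndarray, radius: float) -> list[int]:
        ids = []
        for p in positions:
            self.nodes.append(
                CenterlineNode(
                    id=self.next_id,
                    position=tuple(p),
                    radius=radius,
                    parent_id=parent,
                )
            )
            ids.append(self.next_id)
            parent = self.next_id
            self.next_id += 1
        return ids


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction")
    return v / n


def _basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(u, helper))
    e2 = np.cross(u, e1)
    return e1, e2


def _chain_points(
    start: np.ndarray, direction: np.ndarray, length: float, step: float,
    first_offset: float | None = None,
) -> np.ndarray:
    """Points along a straight branch, excluding the start junction itself."""
    offs = first_offset if first_offset is not None else step
    offs = min(offs, length)
    arcs = [offs]
    while arcs[-1] + step < length - 1e-9:
        arcs.append(arcs[-1] + step)
    if arcs[-1] < length - 1e-9:
        arcs.append(length)
    return start[None, :] + np.asarray(arcs)[:, None] * direction[None, :]


def _inside(p: np.ndarray, center: np.ndarray, semi: np.ndarray, margin: float) -> bool:
    q = (np.atleast_2d(p) - center) / semi
    return bool(np.all(np.sum(q**2, axis=1) <= margin**2))


def _steer_inside(
    points_fn, direction: np.ndarray, center: np.ndarray, start: np.ndarray,
    semi: np.ndarray, margin: float, rng: np.random.Generator, attempts: int = 50
) -> tuple[np.ndarray, np.ndarray] | None:
    """Jitter/pull a branch direction until its chain fits in the ellipsoid."""
    d = direction.copy()
    for i in range(attempts):
        pts = points_fn(d)
        if _inside(pts, center, semi, margin):
            return d, pts
        # pull toward the lung center and re-jitter slightly
        to_center = _unit(center - start)
        d = _unit(d + 0.35 * to_center + rng.normal(0.0, 0.05, 3))
    return None


def _build_airway_tree(
    spec: PhantomSpec, tax: SegmentTaxonomy, rng: np.random.Generator,
    strict_separation: bool = True,
) -> tuple[AirwayTree, SegmentalAnnotation, dict[str, int]]:
    """Unlabeled tree + annotations + (lobe -> first node id of its lobar branch)."""
    S = spec.physical_size()
    origin = np.asarray(spec.grid.origin)
    semi = spec.resolved_semiaxes()
    lengths = spec.resolved_lengths()
    step = max(1.2 * float(min(S)) / 95.0, 1.01 * float(min(spec.grid.spacing)))
    centers = {
        "right": origin + S * np.array([0.30, 0.50, 0.48]),
        "left": origin + S * np.array([0.70, 0.50, 0.48]),
    }
    angle_mean, angle_jit = spec.branch_angle_deg
    sep_min = 1.2 * np.sqrt(3.0) * float(max(spec.grid.spacing))

    b = _TreeBuilder()
    top = origin + S * np.array([0.50, 0.48, 0.92])
    root_id = b.add_chain(-1, top[None, :], 4.0)[0]
    trachea_ids = b.add_chain(
        root_id, _chain_points(top, np.array([0.0, 0.0, -1.0]), lengths[0], step), 4.0
    )
    carina_id = trachea_ids[-1]
    carina = np.asarray(b.nodes[carina_id - 1].position)

    annotations: dict[int, int] = {}
    lobar_first_node: dict[str, int] = {}

    for side, lobe_names in (("right", _RIGHT_LOBES), ("left", _LEFT_LOBES)):
        center = centers[side]
        lat_sign = -1.0 if side == "right" else 1.0
        # main bronchus
        target = center + np.array([0.0, 0.0, 0.55 * semi[2]])
        d_main = _unit(target - carina)
        main_pts = _chain_points(carina, d_main, lengths[1], step)
        main_ids = b.add_chain(carina_id, main_pts, 3.2)
        main_end = main_pts[-1]
        main_end_id = main_ids[-1]

        for lobe in lobe_names:
            frac = np.array(_LOBE_TARGETS[lobe])
            tgt = center + semi * np.array([lat_sign * frac[0], frac[1], frac[2]])
            d0 = _unit(tgt - main_end + rng.normal(0.0, 0.03, 3))
            res = _steer_inside(
                lambda d: _chain_points(main_end, d, lengths[2], step),
                d0, center, main_end, semi, 0.88, rng,
            )
            if res is None:
                raise ValueError(
                    f"lobar branch for {lobe} escapes the lung after 50 attempts; "
                    "use larger lungs or shorter branches"
                )
            d_lobar, lobar_pts = res
            lobar_ids = b.add_chain(main_end_id, lobar_pts, 2.5)
            lobar_first_node[lobe] = lobar_ids[0]
            lobar_end = lobar_pts[-1]
            lobar_end_id = lobar_ids[-1]

            codes = tax.segments_for_lobe(lobe)
            n = len(codes)
            e1, e2 = _basis(d_lobar)
            seg_layout = None
            for _attempt in range(60):
                phi0 = rng.uniform(0.0, 2.0 * np.pi)
                chains = []
                ok = True
                for i in range(n):
                    theta = np.deg2rad(
                        float(np.clip(rng.normal(angle_mean, angle_jit), 26.0, 55.0))
                    )
                    phi = phi0 + 2.0 * np.pi * i / n + rng.normal(0.0, 0.12)
                    d_i = (
                        np.cos(theta) * d_lobar
                        + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2)
                    )
                    length = lengths[3] * float(
                        1.0 + np.clip(rng.normal(0.0, spec.length_jitter), -0.3, 0.3)
                    )
                    # shorten before redirecting, so sibling divergence survives
                    res = None
                    for shrink in (1.0, 0.85, 0.7, 0.55):
                        L = length * shrink
                        res = _steer_inside(
                            lambda d, L=L: _chain_points(
                                lobar_end, d, L, step, first_offset=0.35 * L
                            ),
                            d_i, center, lobar_end, semi, 0.92, rng, attempts=12,
                        )
                        if res is not None:
                            break
                    if res is None:
                        ok = False
                        break
                    chains.append(res)
                if not ok:
                    continue
                firsts = np.array([pts[0] for _, pts in chains])
                dmat = np.linalg.norm(firsts[:, None] - firsts[None, :], axis=-1)
                np.fill_diagonal(dmat, np.inf)
                if dmat.min() >= sep_min:
                    seg_layout = chains
                    break
            if seg_layout is None:
                if strict_separation:
                    raise _SeparationError(
                        f"could not separate segmental bronchi of {lobe} "
                        f"by {sep_min:.1f} mm"
                    )
                logger.warning(
                    "could not separate segmental bronchi of %s by %.1f mm; "
                    "accepting last layout (expected on very small grids)",
                    lobe, sep_min,
                )
                seg_layout = chains
            for code, (d_seg, seg_pts) in zip(codes, seg_layout):
                seg_ids = b.add_chain(lobar_end_id, seg_pts, 1.8)
                annotations[seg_ids[0]] = code
                seg_end = seg_pts[-1]
                seg_end_id = seg_ids[-1]
                es1, es2 = _basis(d_seg)
                # daughter branches diverge: evenly spaced azimuths around the
                # parent direction, as at the segmental level
                phi_base = rng.uniform(0.0, 2.0 * np.pi)
                for _j in range(spec.subsegmental_children):
                    theta = np.deg2rad(
                        float(np.clip(rng.normal(angle_mean, angle_jit), 26.0, 55.0))
                    )
                    phi = (
                        phi_base
                        + 2.0 * np.pi * _j / spec.subsegmental_children
                        + rng.normal(0.0, 0.25)
                    )
                    d_s = (
                        np.cos(theta) * d_seg
                        + np.sin(theta) * (np.cos(phi) * es1 + np.sin(phi) * es2)
                    )
                    length = lengths[4] * float(
                        1.0 + np.clip(rng.normal(0.0, spec.length_jitter), -0.15, 0.3)
                    )
                    res = _steer_inside(
                        lambda d, L=length: _chain_points(seg_end, d, L, step),
                        d_s, center, seg_end, semi, 0.95, rng, attempts=25,
                    )
                    if res is None:
                        raise ValueError(
                            "subsegmental branch escapes the lung after 50 attempts; "
                            "use larger lungs or shorter branches"
                        )
                    b.add_chain(seg_end_id, res[1], 1.2)

    tree = AirwayTree(b.nodes)
    return tree, SegmentalAnnotation(annotations), lobar_first_node


def _lung_masks(spec: PhantomSpec) -> LabelVolume:
    S = spec.physical_size()
    origin = np.asarray(spec.grid.origin)
    semi = spec.resolved_semiaxes()
    centers_mm = spec.grid.voxel_centers_mm().reshape(*spec.grid.dims, 3)
    labels = np.zeros(spec.grid.dims, dtype=np.int32)
    for code, fx in ((1, 0.30), (2, 0.70)):
        c = origin + S * np.array([fx, 0.50, 0.48])
        q = (centers_mm - c) / semi
        labels[np.sum(q**2, axis=-1) <= 1.0] = code
    return LabelVolume(spec.grid, labels)


def _subtree_node_ids(tree: AirwayTree, start: int) -> set[int]:
    ch = tree.children_map()
    out: set[int] = set()
    stack = [start]
    while stack:
        nid = stack.pop()
        out.add(nid)
        stack.extend(ch[nid])
    return out


def _voxels_of_nodes(tree: AirwayTree, node_ids: set[int], grid: ImageGrid) -> np.ndarray:
    """Rasterized voxels of the sub-forest induced by ``node_ids``."""
    sub_nodes = []
    for nid in node_ids:
        n = tree.nodes[nid]
        parent = n.parent_id if n.parent_id in node_ids else -1
        sub_nodes.append(CenterlineNode(n.id, n.position, n.radius, parent))
    sub = AirwayTree(sub_nodes)
    pts, _ = resample_edges(sub, 0.5 * min(grid.spacing))
    idx = grid.round_to_voxel(pts)
    idx = idx[grid.contains_index(idx)]
    return np.unique(idx, axis=0)


def _nearest_label_from_voxel_sets(
    grid: ImageGrid,
    region: np.ndarray,
    candidates: list[tuple[int, np.ndarray]],
) -> np.ndarray:
    """Argmin-distance labels over ``region`` given (code, feature voxels) sets."""
    out = np.zeros(grid.dims, dtype=np.int32)
    all_idx = np.indices(grid.dims).reshape(3, -1).T
    vox = all_idx[region.ravel()]
    d2 = np.empty((len(vox), len(candidates)))
    for j, (_, feats) in enumerate(candidates):
        mask = np.zeros(grid.dims, dtype=bool)
        mask[feats[:, 0], feats[:, 1], feats[:, 2]] = True
        _, indices = ndimage.distance_transform_edt(
            ~mask, sampling=grid.spacing, return_indices=True
        )
        nn = np.stack(indices, axis=-1)[region]
        d2[:, j] = squared_index_distance(vox, nn, grid.spacing)
    winner = np.argmin(d2, axis=1)
    out[region] = np.asarray([c for c, _ in candidates], dtype=np.int32)[winner]
    return out


def exhaustive_parcellation(
    lobes: LabelVolume, tree: AirwayTree, tax: SegmentTaxonomy,
    chunk: int = 8192,
) -> LabelVolume:
    """Segment parcellation by brute-force scan over (voxel, labeled voxel) pairs.

    Independent of the production feature-transform path: for every lobe voxel
    the squared distance to *every* rasterized labeled-centerline voxel of
    every candidate segment is evaluated explicitly, then minimized (ties to
    the smallest code).  Used for phantom ground truth and as a cross-check.
    """
    grid = lobes.grid
    features = segment_feature_voxels(tree, grid)
    out = np.zeros(grid.dims, dtype=np.int32)
    all_idx = np.indices(grid.dims).reshape(3, -1).T
    for lc in sorted(lobes.label_set()):
        lobe_id = tax.lobe_from_code(lc)
        cands = [k for k in tax.segments_for_lobe(lobe_id) if k in features]
        if not cands:
            raise ValueError(f"lobe {lobe_id} has voxels but no labeled bronchus")
        sel = lobes.labels == lc
        vox = all_idx[sel.ravel()]
        labels_here = np.empty(len(vox), dtype=np.int32)
        for lo in range(0, len(vox), chunk):
            v = vox[lo : lo + chunk]
            d2 = np.empty((len(v), len(cands)))
            for j, k in enumerate(cands):
                pair = squared_index_distance(
                    v[:, None, :], features[k][None, :, :], grid.spacing
                )
                d2[:, j] = pair.min(axis=1)
            labels_here[lo : lo + chunk] = np.asarray(cands, dtype=np.int32)[
                np.argmin(d2, axis=1)
            ]
        out[sel] = labels_here
    return LabelVolume(grid, out)


def generate(spec: PhantomSpec) -> PhantomBundle:
    """Generate a complete phantom bundle from a spec (deterministic in seed)."""
    tax = build_taxonomy()
    rng = np.random.default_rng(spec.seed)
    lungs = _lung_masks(spec)

    labeled = annotations = lobar_first = None
    for attempt in range(8):
        try:
            tree, annotations, lobar_first = _build_airway_tree(
                spec, tax, rng, strict_separation=attempt < 7
            )
        except _SeparationError as exc:
            logger.info("phantom seed %d: %s; regenerating (attempt %d)",
                        spec.seed, exc, attempt + 1)
            continue
        labeled = propagate_labels(tree, annotations)
        features = segment_feature_voxels(labeled, spec.grid)
        claimed: dict[tuple[int, int, int], int] = {}
        collision = False
        for code in sorted(features):
            for v in map(tuple, features[code]):
                other = claimed.setdefault(v, code)
                if other != code:
                    collision = True
                    break
            if collision:
                break
        if not collision:
            break
        logger.info("phantom seed %d: segment rasterization collision, retrying "
                    "(attempt %d)", spec.seed, attempt + 1)
    else:
        logger.warning(
            "phantom seed %d: accepting tree with overlapping segment voxels "
            "(grid likely too small for full separation)", spec.seed
        )

    # lobes: nearest lobar subtree within each lung (one level above segments)
    lobe_voxel_sets = {
        lobe: _voxels_of_nodes(labeled, _subtree_node_ids(labeled, nid), spec.grid)
        for lobe, nid in lobar_first.items()
    }
    lobe_labels = np.zeros(spec.grid.dims, dtype=np.int32)
    for lung_code, lobe_names in ((1, _RIGHT_LOBES), (2, _LEFT_LOBES)):
        region = lungs.labels == lung_code
        cands = [(tax.lobe_code(lb), lobe_voxel_sets[lb]) for lb in lobe_names]
        lobe_labels += _nearest_label_from_voxel_sets(spec.grid, region, cands)
    lobes = LabelVolume(spec.grid, lobe_labels)

    prob = centerline_probability(labeled, spec.grid, sigma=spec.sigma_mm)
    for branch_index, gap_mm in spec.gap_injection:
        prob = inject_gap(prob, labeled, branch_index, gap_mm)

    segments_gt = exhaustive_parcellation(lobes, labeled, tax)
    return PhantomBundle(
        spec=spec,
        lungs=lungs,
        lobes=lobes,
        tree=labeled,
        annotations=annotations,
        prob=prob,
        segments_gt=segments_gt,
    )


def inject_gap(
    prob: ScalarVolume,
    tree: AirwayTree,
    branch_index: int,
    gap_mm: float,
    lateral_radius_mm: float = 4.0,
) -> ScalarVolume:
    """Zero the probability in a slab of ``gap_mm`` centered mid-branch.

    The slab is perpendicular to the branch direction at its arc-length
    midpoint and laterally limited to ``lateral_radius_mm`` so other branches
    are untouched.  ``gap_mm = 0`` is the identity.
    """
    branches = branch_decomposition(tree)
    if not 0 <= branch_index < len(branches):
        raise ValueError(f"branch index {branch_index} out of range 0..{len(branches)-1}")
    br = branches[branch_index]
    pts = tree.positions(br.node_ids)
    seglens = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seglens.sum())
    if gap_mm >= total:
        raise ValueError(f"gap {gap_mm} mm >= branch length {total:.2f} mm")
    if gap_mm <= 0:
        return ScalarVolume(prob.grid, prob.values.copy())
    arc = np.concatenate([[0.0], np.cumsum(seglens)])
    mid = total / 2.0
    i = int(np.searchsorted(arc, mid)) - 1
    i = max(0, min(i, len(seglens) - 1))
    t = (mid - arc[i]) / seglens[i]
    mid_pt = pts[i] * (1 - t) + pts[i + 1] * t
    axis = _unit(pts[i + 1] - pts[i])

    centers = prob.grid.voxel_centers_mm().reshape(*prob.grid.dims, 3)
    rel = centers - mid_pt
    axial = np.abs(np.tensordot(rel, axis, axes=([-1], [0])))
    lat2 = np.sum(rel**2, axis=-1) - np.tensordot(rel, axis, axes=([-1], [0])) ** 2
    slab = (axial <= gap_mm / 2.0) & (lat2 <= lateral_radius_mm**2)
    vals = prob.values.copy()
    vals[slab] = 0.0
    return ScalarVolume(prob.grid, vals)
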