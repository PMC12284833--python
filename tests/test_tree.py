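import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungparc.tree import (
    AirwayTree,
    CenterlineNode,
    SegmentalAnnotation,
    branch_decomposition,
    count_bifurcations,
    propagate_labels,
    read_annotations,
    read_swc,
    resample_edges,
    segmental_candidates,
    validate_tree,
    write_annotations,
    write_swc,
)


def chain(ids, start_parent=-1, offset=(0.0, 0.0, 0.0)):
    nodes = []
    parent = start_parent
    for i, nid in enumerate(ids):
        nodes.append(
            CenterlineNode(
                id=nid,
                position=(offset[0] + i, offset[1], offset[2]),
                parent_id=parent,
            )
        )
        parent = nid
    return nodes


def binary_tree_on_chain(chain_len=5, depth=3):
    """Root chain then a perfect binary tree of the given depth below it."""
    nodes = chain(range(1, chain_len + 1))
    next_id = chain_len + 1
    frontier = [chain_len]
    for level in range(1, depth + 1):
        new_frontier = []
        for parent in frontier:
            for side in (-1, 1):
                p = nodes[parent - 1].position
                nodes.append(
                    CenterlineNode(
                        id=next_id,
                        position=(p[0] + 1, p[1] + side * 2.0 ** (depth - level), p[2]),
                        parent_id=parent,
                    )
                )
                new_frontier.append(next_id)
                next_id += 1
        frontier = new_frontier
    return AirwayTree(nodes)


# -- validation ----------------------------------------------------------------


def test_single_node_is_valid():
    assert validate_tree(AirwayTree([CenterlineNode(1, (0, 0, 0))])) == []


def test_multiple_roots_detected():
    t = AirwayTree([CenterlineNode(1, (0, 0, 0)), CenterlineNode(2, (1, 0, 0))])
    assert any("multiple roots" in v for v in validate_tree(t))


def test_cycle_detected():
    t = AirwayTree(
        [
            CenterlineNode(1, (0, 0, 0)),
            CenterlineNode(2, (1, 0, 0), parent_id=3),
            CenterlineNode(3, (2, 0, 0), parent_id=2),
        ]
    )
    assert any("cycle" in v or "reachable" in v for v in validate_tree(t))


def test_dangling_parent_detected():
    t = AirwayTree(
        [CenterlineNode(1, (0, 0, 0)), CenterlineNode(2, (1, 0, 0), parent_id=99)]
    )
    assert any("dangling parent 99" in v for v in validate_tree(t))


# -- branch decomposition ------------------------------------------------------


def test_chain_is_one_generation0_branch():
    t = AirwayTree(chain(range(1, 8)))
    branches = branch_decomposition(t)
    assert len(branches) == 1
    assert branches[0].generation == 0
    assert branches[0].node_ids == tuple(range(1, 8))


def test_binary_tree_branch_count_and_generations():
    # enumeration oracle: 1 chain + 2 + 4 + 8 child branches
    t = binary_tree_on_chain(chain_len=5, depth=3)
    branches = branch_decomposition(t)
    assert len(branches) == 15
    by_gen = {}
    for b in branches:
        by_gen[b.generation] = by_gen.get(b.generation, 0) + 1
    assert by_gen == {0: 1, 1: 2, 2: 4, 3: 8}


def test_main_bronchi_are_generation_one(bundle96):
    branches = branch_decomposition(bundle96.tree)
    gen1 = [b for b in branches if b.generation == 1]
    assert len(gen1) == 2  # left and right main bronchi


def test_trifurcation_children_all_next_generation():
    nodes = chain([1, 2])
    for nid, dy in ((3, -1), (4, 0), (5, 1)):
        nodes.append(CenterlineNode(nid, (2.0, dy, 0.0), parent_id=2))
    branches = branch_decomposition(AirwayTree(nodes))
    gens = sorted(b.generation for b in branches)
    assert gens == [0, 1, 1, 1]


def test_branch_partition_on_phantom(bundle48):
    branches = branch_decomposition(bundle48.tree)
    seen = [nid for b in branches for nid in b.node_ids]
    assert len(seen) == len(set(seen)) == len(bundle48.tree)


def test_segmental_candidates_counts(bundle96):
    assert len(segmental_candidates(binary_tree_on_chain())) == 8
    assert segmental_candidates(AirwayTree(chain(range(1, 5)))) == []
    assert len(segmental_candidates(bundle96.tree)) == 18


def test_count_bifurcations_conventions():
    nodes = chain([1, 2])
    for nid, dy in ((3, -1), (4, 0), (5, 1)):
        nodes.append(CenterlineNode(nid, (2.0, dy, 0.0), parent_id=2))
    t = AirwayTree(nodes)
    assert count_bifurcations(t) == 2  # trifurcation = 2 bifurcations
    assert count_bifurcations(t, split_multifurcations=False) == 1


# -- propagation ---------------------------------------------------------------


def test_propagation_labels_branch_and_subtree():
    t = binary_tree_on_chain(chain_len=5, depth=3)
    branches = branch_decomposition(t)
    gen1 = [b for b in branches if b.generation == 1][0]
    labeled = propagate_labels(t, SegmentalAnnotation({gen1.node_ids[0]: 7}))
    expect = set(gen1.node_ids)
    # downstream subtree by traversal oracle
    ch = t.children_map()
    stack = list(ch[gen1.node_ids[-1]])
    while stack:
        nid = stack.pop()
        expect.add(nid)
        stack.extend(ch[nid])
    got = {nid for nid, n in labeled.nodes.items() if n.segment_label == 7}
    assert got == expect
    unlabeled = {nid for nid, n in labeled.nodes.items() if n.segment_label is None}
    assert unlabeled == set(t.nodes) - expect


def test_propagation_conflict_is_error():
    t = binary_tree_on_chain(chain_len=5, depth=3)
    branches = branch_decomposition(t)
    gen1 = [b for b in branches if b.generation == 1][0]
    gen2 = [
        b
        for b in branches
        if b.generation == 2 and b.node_ids[0] in _subtree(t, gen1.node_ids[-1])
    ][0]
    ann = SegmentalAnnotation({gen1.node_ids[0]: 1, gen2.node_ids[0]: 2})
    with pytest.raises(ValueError, match="conflicting annotation"):
        propagate_labels(t, ann)


def _subtree(t, start):
    ch = t.children_map()
    out, stack = set(), [start]
    while stack:
        nid = stack.pop()
        out.add(nid)
        stack.extend(ch[nid])
    return out


def test_propagation_missing_node_is_error():
    t = AirwayTree(chain(range(1, 5)))
    with pytest.raises(ValueError, match="not in tree"):
        propagate_labels(t, SegmentalAnnotation({99: 1}))


def test_propagation_warns_off_generation(caplog):
    t = AirwayTree(chain(range(1, 5)))
    with caplog.at_level("WARNING"):
        propagate_labels(t, SegmentalAnnotation({2: 3}))
    assert any("generation" in r.message for r in caplog.records)


def test_propagation_idempotent_and_codomain(bundle48):
    ann = bundle48.annotations
    # bundle trees are already propagated; re-propagating changes nothing
    again = propagate_labels(bundle48.tree, ann)
    labels_a = {nid: n.segment_label for nid, n in bundle48.tree.nodes.items()}
    labels_b = {nid: n.segment_label for nid, n in again.nodes.items()}
    assert labels_a == labels_b
    assert {v for v in labels_a.values() if v} == set(ann.entries.values())


def test_phantom_annotations_cover_all_18(bundle96):
    labeled_gens = {
        b.generation
        for b in branch_decomposition(bundle96.tree)
        if bundle96.tree.nodes[b.node_ids[-1]].segment_label
    }
    assert labeled_gens == {3, 4}
    labels = {n.segment_label for n in bundle96.tree.nodes.values() if n.segment_label}
    assert labels == set(range(1, 19))


# -- SWC and annotation I/O ----------------------------------------------------


def test_swc_roundtrip(tmp_path, bundle48):
    path = tmp_path / "t.swc"
    write_swc(bundle48.tree, path)
    back = read_swc(path)
    assert set(back.nodes) == set(bundle48.tree.nodes)
    for nid, n in bundle48.tree.nodes.items():
        m = back.nodes[nid]
        assert np.allclose(m.position, n.position, atol=1e-6)
        assert m.parent_id == n.parent_id
        assert m.segment_label == n.segment_label
        assert abs(m.radius - n.radius) < 1e-6


def test_swc_forward_parent_reference(tmp_path):
    path = tmp_path / "f.swc"
    path.write_text("2 1 1 0 0 1 1\n1 1 0 0 0 1 -1\n")
    t = read_swc(path)
    assert t.root_id == 1 and t.nodes[2].parent_id == 1


def test_swc_two_roots_rejected(tmp_path):
    path = tmp_path / "r.swc"
    path.write_text("1 1 0 0 0 1 -1\n2 1 1 0 0 1 -1\n")
    with pytest.raises(ValueError, match="roots"):
        read_swc(path)


def test_swc_malformed_line_reports_lineno(tmp_path):
    path = tmp_path / "m.swc"
    path.write_text("1 1 0 0 0 1 -1\n2 1 oops 0 0 1 1\n")
    with pytest.raises(ValueError, match=":2"):
        read_swc(path)


def test_annotation_json_roundtrip(tmp_path, bundle48):
    path = tmp_path / "ann.json"
    write_annotations(bundle48.annotations, path)
    assert read_annotations(path).entries == bundle48.annotations.entries


def test_duplicate_segment_codes_rejected():
    with pytest.raises(ValueError, match="more than once"):
        SegmentalAnnotation({1: 4, 2: 4})


# -- edge resampling -----------------------------------------------------------


def test_resample_edges_density_and_labels():
    nodes = [
        CenterlineNode(1, (0, 0, 0)),
        CenterlineNode(2, (3.0, 0, 0), parent_id=1, segment_label=5),
        CenterlineNode(3, (6.0, 0, 0), parent_id=2, segment_label=5),
    ]
    pts, labs = resample_edges(AirwayTree(nodes), 0.5)
    gaps = np.diff(np.sort(pts[:, 0]))
    assert gaps.max() <= 0.5 + 1e-9
    # interior samples of the mixed-label junction edge carry no label
    junction = (pts[:, 0] > 0) & (pts[:, 0] < 3)
    assert np.all(labs[junction] == 0)
    interior = (pts[:, 0] > 3) & (pts[:, 0] < 6)
    assert np.all(labs[interior] == 5)


# -- property tests ------------------------------------------------------------


@st.composite
def random_trees(draw):
    n = draw(st.integers(min_value=1, max_value=40))
    nodes = [CenterlineNode(1, (0.0, 0.0, 0.0))]
    for i in range(2, n + 1):
        parent = draw(st.integers(min_value=1, max_value=i - 1))
        nodes.append(
            CenterlineNode(i, (float(i), float(parent % 5), 0.0), parent_id=parent)
        )
    return AirwayTree(nodes)


@settings(max_examples=40, derandomize=True)
@given(random_trees())
def test_branch_decomposition_partitions_any_tree(t):
    branches = branch_decomposition(t)
    seen = [nid for b in branches for nid in b.node_ids]
    assert sorted(seen) == sorted(t.nodes)
    for b in branches:
        ch = t.children_map()
        for nid in b.node_ids[:-1]:
            assert len(ch[nid]) == 1


@settings(max_examples=25, derandomize=True)
@given(random_trees(), st.integers(min_value=1, max_value=18))
def test_propagation_idempotent_any_tree(t, code):
    leaves = [nid for nid, c in t.children_map().items() if not c]
    ann = SegmentalAnnotation({leaves[0]: code})
    once = propagate_labels(t, ann)
    twice = propagate_labels(once, ann)
    assert {n.segment_label for n in once.nodes.values()} == {
        n.segment_label for n in twice.nodes.values()
    }
    labels = {n.segment_label for n in once.nodes.values() if n.segment_label}
    assert labels == {code}
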